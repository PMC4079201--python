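"""Satellite density versus recombination rate.

Chromosomes are split into non-overlapping windows (default 250 kb); per
window the number of satellite hits, the covered bp, and the length-weighted
mean recombination rate (cM/Mb) are recorded.  Satellite density is then
modelled as an exponential function of the local recombination rate,

    E[response] = exp(a + b * rate),

fitted as a Poisson regression with log link (the coverage response uses
covered bp as counts with window length as exposure, so exp(a) is a
per-bp rate).  A log-of-(y+1) least-squares mode is provided for
sensitivity comparison.

The fitted slope predicts the focal/background coverage ratio from the
median recombination rates of the two chromosome groups.  Because the X
chromosome's effective population size is 3/4 of the autosomal one, its
rate is multiplied by 4/3 before the comparison:

    predicted ratio = exp(b * (correction * median_focal - median_background))

The intercept cancels and is unused.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import spearmanr

from .genome import GenomeSet, RecombMap
from .mapping import SatelliteHit

DEFAULT_WINDOW = 250_000
DEFAULT_CORRECTION = 4.0 / 3.0


class DegenerateFitError(ValueError):
    """The exponential model cannot be identified from these windows."""


@dataclass
class RecombWindow:
    """One analysis window with its satellite load and recombination rate."""

    chrom: str
    start: int
    end: int
    rate: float | None  # None when the map does not cover the window
    hit_count: int
    covered_bp: int
    truncated: bool = False  # last window of a chromosome may be shorter

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(
    genome: GenomeSet,
    hits: list[SatelliteHit],
    rmap: RecombMap | None,
    window: int = DEFAULT_WINDOW,
) -> list[RecombWindow]:
    """Window every chromosome and tally hits, coverage and mean rate.

    A hit is counted in the window containing its start; its covered bp is
    clipped to each window it overlaps, so counts are never double-assigned
    while coverage conserves bp.  Windows on chromosomes absent from the
    map carry ``rate=None`` and are excluded from fits.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list[SatelliteHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)

    out: list[RecombWindow] = []
    for chrom in genome.chromosomes:
        n_windows = max(1, math.ceil(chrom.length / window))
        starts = [i * window for i in range(n_windows)]
        chrom_hits = by_chrom.get(chrom.name, [])
        for s in starts:
            e = min(s + window, chrom.length)
            count = sum(1 for h in chrom_hits if s <= h.start < e)
            clipped = [
                (max(h.start, s), min(h.end, e))
                for h in chrom_hits
                if h.start < e and h.end > s
            ]
            covered = _union_bp(clipped)
            rate = rmap.mean_rate(chrom.name, s, e) if rmap is not None else None
            out.append(
                RecombWindow(chrom.name, s, e, rate, count, covered,
                             truncated=(e - s < window))
            )
    return out


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, cs, ce = 0, intervals[0][0], intervals[0][1]
    for s, e in intervals[1:]:
        if s > ce:
            total += ce - cs
            cs, ce = s, e
        else:
            ce = max(ce, e)
    return total + (ce - cs)


@dataclass
class ExponentialFit:
    """Fitted exponential density model exp(a + b * rate)."""

    response: str  # "hits" | "coverage"
    intercept: float
    slope: float
    intercept_se: float
    slope_se: float
    n_windows: int
    fit_method: str

    def predict(self, rate: float) -> float:
        return math.exp(self.intercept + self.slope * rate)


def fit_exponential(
    windows: list[RecombWindow],
    response: str = "hits",
    method: str = "poisson",
) -> ExponentialFit:
    """Fit E[response] = exp(a + b*rate) over windows with a defined rate.

    ``method='poisson'`` (default) is a Poisson GLM with log link; the
    coverage response uses window length as exposure.  ``method='lstsq'``
    fits log(y+1) by ordinary least squares, for sensitivity checks.
    """
    usable = [w for w in windows if w.rate is not None]
    if len(usable) < 3:
        raise DegenerateFitError("need >= 3 windows with a defined rate")
    rates = np.array([w.rate for w in usable], dtype=float)
    if np.ptp(rates) == 0:
        raise DegenerateFitError("all rates equal; slope unidentifiable")
    if response == "hits":
        y = np.array([w.hit_count for w in usable], dtype=float)
        exposure = None
    elif response == "coverage":
        y = np.array([w.covered_bp for w in usable], dtype=float)
        exposure = np.array([w.length for w in usable], dtype=float)
    else:
        raise ValueError(f"unknown response {response!r}")
    if not np.any(y > 0):
        raise DegenerateFitError("all responses are zero")

    X = sm.add_constant(rates)
    if method == "poisson":
        model = sm.GLM(
            y, X, family=sm.families.Poisson(), exposure=exposure
        )
        res = model.fit()
        a, b = res.params
        a_se, b_se = res.bse
    elif method == "lstsq":
        target = np.log(y + 1.0)
        if exposure is not None:
            target = target - np.log(exposure)
        res = sm.OLS(target, X).fit()
        a, b = res.params
        a_se, b_se = res.bse
    else:
        raise ValueError(f"unknown method {method!r}")
    return ExponentialFit(
        response=response, intercept=float(a), slope=float(b),
        intercept_se=float(a_se), slope_se=float(b_se),
        n_windows=len(usable), fit_method=method,
    )


@dataclass
class RecombSummary:
    """Median rates, the Ne correction, and the predicted coverage ratio."""

    median_focal: float
    median_background: float
    correction: float
    slope: float
    predicted_ratio: float


def median_rates(
    windows: list[RecombWindow], genome: GenomeSet
) -> tuple[float, float]:
    """Median window rate for the focal and background groups (unweighted,
    one value per window)."""
    focal = [w.rate for w in windows
             if w.rate is not None and genome.group_of(w.chrom) == "focal"]
    background = [w.rate for w in windows
                  if w.rate is not None and genome.group_of(w.chrom) == "background"]
    if not focal or not background:
        raise ValueError("need rated windows in both groups")
    return float(np.median(focal)), float(np.median(background))


def predict_ratio(
    fit: ExponentialFit,
    median_focal_rate: float,
    median_background_rate: float,
    correction: float = DEFAULT_CORRECTION,
) -> RecombSummary:
    """Predicted focal/background coverage ratio from the fitted slope.

    ratio = exp(b * (correction * median_focal - median_background)); the
    intercept cancels.
    """
    ratio = math.exp(
        fit.slope * (correction * median_focal_rate - median_background_rate)
    )
    return RecombSummary(
        median_focal=median_focal_rate,
        median_background=median_background_rate,
        correction=correction, slope=fit.slope, predicted_ratio=ratio,
    )


@dataclass
class CorrelationReport:
    rho: float | None
    p_value: float | None
    n: int
    response: str
    note: str = ""


def correlation_report(
    windows: list[RecombWindow], response: str = "hits"
) -> CorrelationReport:
    """Spearman rank correlation of the window response against the rate."""
    usable = [w for w in windows if w.rate is not None]
    if len(usable) < 5:
        raise ValueError("need >= 5 windows with a defined rate")
    rates = np.array([w.rate for w in usable], dtype=float)
    if response == "hits":
        y = np.array([w.hit_count for w in usable], dtype=float)
    else:
        y = np.array([w.covered_bp / w.length for w in usable], dtype=float)
    if np.ptp(y) == 0:
        return CorrelationReport(None, None, len(usable), response,
                                 note="constant response; correlation undefined")
    rho, p = spearmanr(rates, y)
    return CorrelationReport(float(rho), float(p), len(usable), response)
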