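"""Concerted-evolution analysis of satellite copies.

Concerted evolution homogenizes repeat copies within a genomic region, so
copies of the same locus should be more similar to each other than to
copies elsewhere.  The test here: align every copy to the family consensus
(a star alignment, which places all copies in a common coordinate system),
compute pairwise Hamming distances on the shared columns, and compare
within-locus against between-locus distances with a one-sided Wilcoxon
rank-sum test (alternative: within < between, the directional claim).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.stats import mannwhitneyu

from .monomer import Monomer

logger = logging.getLogger(__name__)

GAP = "-"
LENGTH_BOUNDS = (0.5, 2.0)  # copy length relative to the consensus


@dataclass
class AlignedCopy:
    """A satellite copy projected onto consensus coordinates.

    ``aligned`` has exactly the consensus length; deleted consensus columns
    hold '-', insertions relative to the consensus are dropped.
    """

    copy_id: str
    locus_id: str
    aligned: str


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def align_to_consensus(
    copy: str, consensus: Monomer | str, copy_id: str = "", locus_id: str = ""
) -> AlignedCopy | None:
    """Globally align a copy to the consensus and project it onto its columns.

    Copies outside [0.5, 2] x consensus length are filtered (None, with a
    logged reason).
    """
    ref = consensus.consensus if isinstance(consensus, Monomer) else consensus
    lo, hi = LENGTH_BOUNDS
    if not (lo * len(ref) <= len(copy) <= hi * len(ref)):
        logger.info(
            "copy %s filtered: length %d outside [%g, %g] x consensus %d",
            copy_id, len(copy), lo, hi, len(ref),
        )
        return None
    alignment = _ALIGNER.align(ref, copy)[0]
    projected = [GAP] * len(ref)
    for (r0, r1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(r1 - r0):
            projected[r0 + offset] = copy[q0 + offset]
    return AlignedCopy(copy_id=copy_id, locus_id=locus_id,
                       aligned="".join(projected))


@dataclass(frozen=True)
class DistanceRecord:
    """Hamming distance between two aligned copies (gap columns excluded)."""

    copy_a: str
    copy_b: str
    same_locus: bool
    distance: float
    compared_sites: int


def hamming(a: str, b: str) -> tuple[float, int]:
    """(distance, compared sites) over columns where both carry a base."""
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    if len(aa) != len(bb):
        raise ValueError("aligned lengths differ")
    both = (aa != ord(GAP)) & (bb != ord(GAP))
    n = int(both.sum())
    if n == 0:
        return 0.0, 0
    return float(np.mean(aa[both] != bb[both])), n


def pairwise_distances(copies: list[AlignedCopy]) -> list[DistanceRecord]:
    """All pairwise distance records; empty (with warning) for < 2 copies."""
    if len(copies) < 2:
        logger.warning("fewer than 2 aligned copies; no distances computed")
        return []
    records = []
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            a, b = copies[i], copies[j]
            d, n = hamming(a.aligned, b.aligned)
            records.append(
                DistanceRecord(a.copy_id, b.copy_id,
                               a.locus_id == b.locus_id, d, n)
            )
    return records


@dataclass
class ConcertedTestReport:
    """Within- vs between-locus distance comparison."""

    n_within: int
    n_between: int
    median_within: float | None
    median_between: float | None
    statistic: float | None
    p_value: float | None
    method: str
    note: str = ""


def within_between_test(records: list[DistanceRecord]) -> ConcertedTestReport:
    """One-sided Wilcoxon rank-sum test of within < between distances.

    Uses exact enumeration for small untied samples (both groups <= 20) and
    the tie-corrected normal approximation otherwise.  If either class is
    empty the p-value is undefined and the report is flagged.
    """
    within = np.array([r.distance for r in records if r.same_locus])
    between = np.array([r.distance for r in records if not r.same_locus])
    if len(within) == 0 or len(between) == 0:
        missing = "within" if len(within) == 0 else "between"
        return ConcertedTestReport(
            len(within), len(between),
            float(np.median(within)) if len(within) else None,
            float(np.median(between)) if len(between) else None,
            None, None, "undefined", note=f"no {missing}-locus pairs",
        )
    pooled = np.concatenate([within, between])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = len(within) <= 20 and len(between) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    stat, p = mannwhitneyu(within, between, alternative="less", method=method)
    return ConcertedTestReport(
        n_within=len(within), n_between=len(between),
        median_within=float(np.median(within)),
        median_between=float(np.median(between)),
        statistic=float(stat), p_value=float(p), method=method,
    )
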