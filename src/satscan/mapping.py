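"""Genome-wide satellite mapping: seed-and-extend homology search, coverage
statistics, and grouping of hits into loci.

The search is an ungapped nucleotide seed-and-extend in the BLASTN family:
exact seed matches (default 11 bp) on both strands are extended in both
directions with match +1 / mismatch -2 under an X-drop of 12, overlapping
extensions on a strand keep the highest-scoring one, and significance is
assessed with the Karlin-Altschul expectation

    E = K * m * n * exp(-lambda * S)

with lambda solved from the scoring distribution at uniform base
composition and K = 0.621 (the standard value for the +1/-2 pair); n counts
both strands.  Hits with E below the reporting threshold (default 1e-4)
are kept.  Divergent satellite copies are found through the modest seed
length and the mismatch tolerance of extension; gapped alignment is out of
scope.

Coverage percentages are computed on the union of hit intervals per
chromosome, and the focal/background coverage ratio is the mean over
background chromosomes of (focal percent / background-chromosome percent).
Hits whose consecutive members lie within 1 kb of each other form a locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _seq
from .genome import Chromosome, ConfigurationError, GenomeSet
from .monomer import Monomer

DEFAULT_SEED_LEN = 11
DEFAULT_EVALUE = 1e-4
DEFAULT_LOCUS_GAP = 1000
MATCH, MISMATCH, XDROP = 1, -2, 12
KA_K = 0.621  # Karlin-Altschul K for +1/-2, uniform composition


def karlin_lambda(match: int = MATCH, mismatch: int = MISMATCH) -> float:
    """Solve sum_ij p_i p_j exp(lambda*s_ij) = 1 at uniform composition."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


_LAMBDA = karlin_lambda()


@dataclass
class SatelliteHit:
    """One significant match of a monomer in the genome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    identity: float
    score: int
    evalue: float
    id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def _xdrop_extend(scores: np.ndarray, xdrop: int) -> tuple[int, int]:
    """Best (length, score) prefix of a score array under the X-drop rule.

    Extension stops at the first position where the running score falls
    more than ``xdrop`` below its running maximum; the returned prefix ends
    at that maximum.
    """
    if len(scores) == 0:
        return 0, 0
    cs = np.cumsum(scores)
    running_max = np.maximum.accumulate(cs)
    dropped = np.nonzero(running_max - cs > xdrop)[0]
    stop = dropped[0] if len(dropped) else len(cs)
    if stop == 0:
        return 0, 0
    best = int(np.argmax(cs[:stop]))
    if cs[best] <= 0:
        return 0, 0
    return best + 1, int(cs[best])


def _extend_seed(
    garr: np.ndarray, qarr: np.ndarray, g: int, q: int, seed_len: int
) -> tuple[int, int, int, float]:
    """Extend an exact seed at (genome g, query q) ungapped both ways.

    Returns (gstart, gend, score, identity).
    """
    # right of the seed
    nr = min(len(garr) - (g + seed_len), len(qarr) - (q + seed_len))
    gr = garr[g + seed_len : g + seed_len + nr]
    qr = qarr[q + seed_len : q + seed_len + nr]
    eq_r = (gr == qr) & (gr >= 0)
    len_r, score_r = _xdrop_extend(np.where(eq_r, MATCH, MISMATCH), XDROP)
    # left of the seed (scanning outward)
    nl = min(g, q)
    gl = garr[g - nl : g][::-1]
    ql = qarr[q - nl : q][::-1]
    eq_l = (gl == ql) & (gl >= 0)
    len_l, score_l = _xdrop_extend(np.where(eq_l, MATCH, MISMATCH), XDROP)

    score = seed_len * MATCH + score_r + score_l
    matches = seed_len + int(eq_r[:len_r].sum()) + int(eq_l[:len_l].sum())
    total = seed_len + len_r + len_l
    return g - len_l, g + seed_len + len_r, score, matches / total


def evalue(score: int, query_len: int, db_len: int) -> float:
    """Karlin-Altschul expectation for an ungapped score; db_len counts one
    strand and is doubled internally (both strands are searched)."""
    return KA_K * query_len * (2 * db_len) * math.exp(-_LAMBDA * score)


def search(
    monomer: Monomer,
    genome: GenomeSet,
    evalue_threshold: float = DEFAULT_EVALUE,
    seed_len: int = DEFAULT_SEED_LEN,
) -> list[SatelliteHit]:
    """Map ``monomer`` over every chromosome of ``genome`` on both strands."""
    query = monomer.consensus
    if len(query) < seed_len:
        raise ConfigurationError(
            f"monomer length {len(query)} is shorter than the seed ({seed_len})"
        )
    db_len = sum(c.length for c in genome.chromosomes)
    hits: list[SatelliteHit] = []
    for chrom in genome.chromosomes:
        hits.extend(
            _search_chromosome(
                query, chrom, db_len, evalue_threshold, seed_len
            )
        )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    for i, h in enumerate(hits, 1):
        h.id = f"hit_{i}"
    return hits


def _search_chromosome(
    query: str,
    chrom: Chromosome,
    db_len: int,
    evalue_threshold: float,
    seed_len: int,
) -> list[SatelliteHit]:
    garr = _seq.encode(chrom.sequence)
    gcodes, gvalid = _seq.kmer_codes(garr, seed_len)
    raw: list[SatelliteHit] = []
    for strand, qseq in (("+", query), ("-", _seq.revcomp(query))):
        qarr = _seq.encode(qseq)
        qcodes, qvalid = _seq.kmer_codes(qarr, seed_len)
        index: dict[int, list[int]] = {}
        for qpos in np.nonzero(qvalid)[0]:
            index.setdefault(int(qcodes[qpos]), []).append(int(qpos))
        if not index:
            continue
        member = np.isin(gcodes, np.fromiter(index, dtype=np.int64)) & gvalid
        covered: dict[int, int] = {}  # diagonal -> genome end already extended
        for g in np.nonzero(member)[0]:
            for q in index[int(gcodes[g])]:
                diag = int(g) - q
                if covered.get(diag, -1) > g:
                    continue
                gstart, gend, score, ident = _extend_seed(
                    garr, qarr, int(g), q, seed_len
                )
                covered[diag] = gend
                e = evalue(score, len(qseq), db_len)
                if e < evalue_threshold:
                    raw.append(
                        SatelliteHit(chrom.name, gstart, gend, strand,
                                     ident, score, e)
                    )
    # overlapping extensions on the same strand: keep the highest-scoring
    kept: list[SatelliteHit] = []
    for strand in ("+", "-"):
        strand_hits = sorted(
            (h for h in raw if h.strand == strand),
            key=lambda h: (-h.score, h.start),
        )
        accepted: list[SatelliteHit] = []
        for h in strand_hits:
            if all(h.end <= a.start or h.start >= a.end for a in accepted):
                accepted.append(h)
        kept.extend(accepted)
    return kept


def _union_bp(intervals: list[tuple[int, int]]) -> int:
    """Total bp covered by the union of (start, end) intervals."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total, cur_start, cur_end = 0, intervals[0][0], intervals[0][1]
    for s, e in intervals[1:]:
        if s > cur_end:
            total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    return total + (cur_end - cur_start)


@dataclass
class CoverageTable:
    """Per-chromosome hit counts and coverage, plus the focal/background ratio.

    ``ratio`` follows the averaged-comparison rule: the pooled focal percent
    divided by each background chromosome's percent, averaged over the
    background chromosomes (those with zero coverage are skipped and
    flagged in ``skipped_background``).
    """

    rows: pd.DataFrame
    focal_percent: float
    ratio: float | None
    skipped_background: list[str] = field(default_factory=list)


def coverage(hits: list[SatelliteHit], genome: GenomeSet) -> CoverageTable:
    """Coverage statistics of a hit set over a grouped genome."""
    by_chrom: dict[str, list[SatelliteHit]] = {}
    for h in hits:
        genome.get(h.chrom)  # raises KeyError for unknown chromosomes
        by_chrom.setdefault(h.chrom, []).append(h)

    records = []
    for chrom in genome.chromosomes:
        chrom_hits = by_chrom.get(chrom.name, [])
        for h in chrom_hits:
            if h.end > chrom.length:
                raise ValueError(
                    f"hit {h.chrom}:{h.start}-{h.end} beyond chromosome end"
                )
        covered = _union_bp([(h.start, h.end) for h in chrom_hits])
        records.append(
            {
                "chrom": chrom.name,
                "group": genome.group_of(chrom.name),
                "length": chrom.length,
                "n_hits": len(chrom_hits),
                "covered_bp": covered,
                "percent": 100.0 * covered / chrom.length,
            }
        )
    rows = pd.DataFrame(records)
    focal_bp = int(rows.loc[rows.group == "focal", "covered_bp"].sum())
    focal_len = int(rows.loc[rows.group == "focal", "length"].sum())
    focal_percent = 100.0 * focal_bp / focal_len if focal_len else 0.0

    ratios, skipped = [], []
    for _, r in rows[rows.group == "background"].iterrows():
        if r.percent > 0:
            ratios.append(focal_percent / r.percent)
        else:
            skipped.append(r.chrom)
    ratio = float(np.mean(ratios)) if ratios else None
    return CoverageTable(rows, focal_percent, ratio, skipped)


def averaged_coverage_ratio(
    focal_percent: float, background_percents: list[float]
) -> float:
    """The averaged-comparison ratio from already-computed percents."""
    return float(np.mean([focal_percent / p for p in background_percents]))


@dataclass
class Locus:
    """A maximal group of hits whose consecutive members are within the gap."""

    id: str
    chrom: str
    members: list[str]
    span_start: int
    span_end: int


def group_loci(
    hits: list[SatelliteHit], max_gap: int = DEFAULT_LOCUS_GAP
) -> list[Locus]:
    """Group hits into loci: copies within ``max_gap`` bp share a locus.

    Per chromosome, hits are sorted by start and a new locus begins when the
    gap between the next hit's start and the running span end exceeds
    ``max_gap``.  Strand is ignored; the result is independent of input
    order and translation-invariant.
    """
    loci: list[Locus] = []
    by_chrom: dict[str, list[SatelliteHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    counter = 0
    for chrom in sorted(by_chrom):
        chrom_hits = sorted(by_chrom[chrom], key=lambda h: (h.start, h.end, h.id))
        current: list[SatelliteHit] = []
        span_end = None
        for h in chrom_hits:
            if current and h.start - span_end > max_gap:
                counter += 1
                loci.append(
                    Locus(f"locus_{counter}", chrom, [m.id for m in current],
                          current[0].start, span_end)
                )
                current, span_end = [], None
            current.append(h)
            span_end = h.end if span_end is None else max(span_end, h.end)
        if current:
            counter += 1
            loci.append(
                Locus(f"locus_{counter}", chrom, [m.id for m in current],
                      current[0].start, span_end)
            )
    return loci
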