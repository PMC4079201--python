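"""Tandem-monomer inference and family grouping.

A satellite cluster is an array of a repeating unit (monomer).  The unit
length (period) is estimated from the self-similarity of the cluster
sequence: the score of a candidate period p is the fraction of positions i
whose seed k-mer (k = 8) recurs exactly p bases downstream.  A true tandem
period scores high; sub-multiple artefacts (reporting a dimer of the unit)
are resolved by preferring the smallest period whose score is within 90% of
the best.  The consensus monomer is then a per-column majority vote over
the period-length frames of the array, and monomers are grouped into
families by single-linkage clustering on pairwise identity, allowing
reverse complement and circular rotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from . import _seq

SEED_K = 8
MIN_PERIOD_SCORE = 0.2  # below this the sequence is reported non-periodic
DEFAULT_MIN_PERIOD = 20
DEFAULT_IDENTITY_THRESHOLD = 0.7


@dataclass
class Monomer:
    """The elementary repeating unit extracted from a satellite array."""

    id: str
    consensus: str
    copy_number_in_source: float
    source_cluster: str = ""
    family: str = ""

    @property
    def period(self) -> int:
        return len(self.consensus)


class DegenerateInputError(ValueError):
    """Input too short or too few copies to characterize a monomer."""


def estimate_period(
    sequence: str,
    min_period: int = DEFAULT_MIN_PERIOD,
    max_period: int = 2000,
) -> list[tuple[int, float]]:
    """Rank candidate tandem periods of ``sequence`` by seed-recurrence score.

    Returns (period, score) pairs sorted so the elected period comes first:
    the smallest period whose score is >= 0.9 x the best score, then the
    remaining candidates by descending score.  Empty list if the sequence is
    shorter than ``2 * min_period`` or nothing scores above the noise floor
    (best score < 0.2, the empirical null for non-repetitive sequence).
    """
    n = len(sequence)
    if n < 2 * min_period:
        return []
    max_period = min(max_period, n // 2)
    if max_period < min_period:
        return []
    arr = _seq.encode(sequence)
    codes, valid = _seq.kmer_codes(arr, SEED_K)
    if valid.sum() < min_period:
        return []

    scores = np.zeros(max_period + 1)
    for p in range(min_period, max_period + 1):
        m = len(codes) - p
        if m < 10:
            break
        both = valid[:m] & valid[p : p + m]
        if both.sum() == 0:
            continue
        scores[p] = float(np.mean(codes[:m][both] == codes[p : p + m][both]))

    best = float(scores.max())
    if best < MIN_PERIOD_SCORE:
        return []
    candidates = [
        (p, float(scores[p]))
        for p in range(min_period, max_period + 1)
        if scores[p] >= MIN_PERIOD_SCORE
    ]
    elected = min(p for p, s in candidates if s >= 0.9 * best)
    candidates.sort(key=lambda ps: (ps[0] != elected, -ps[1], ps[0]))
    return candidates


def top_period(sequence: str, min_period: int = DEFAULT_MIN_PERIOD,
               max_period: int = 2000) -> int | None:
    """The elected period, or None for non-periodic input."""
    ranking = estimate_period(sequence, min_period, max_period)
    return ranking[0][0] if ranking else None


def build_consensus(
    sequence: str, period: int, monomer_id: str = "monomer",
    source_cluster: str = "",
) -> Monomer:
    """Majority-vote consensus of the period-length frames of ``sequence``.

    The sequence is cut into frames of ``period`` bases anchored at its
    start (the consensus is defined up to circular rotation, so the anchor
    fixes the phase deterministically); each consensus column is the
    majority base with ties broken lexicographically.  Requires at least
    two full copies.
    """
    n = len(sequence)
    if period < 1 or n < 2 * period:
        raise DegenerateInputError(
            f"need >= 2 copies of period {period} in a {n}-bp sequence"
        )
    arr = _seq.encode(sequence)
    usable = n // period
    frames = arr[: usable * period].reshape(usable, period)
    # counts[b, col] over bases 0..3; N (-1) excluded from the vote
    counts = np.zeros((4, period), dtype=np.int64)
    for b in range(4):
        counts[b] = (frames == b).sum(axis=0)
    consensus_codes = counts.argmax(axis=0)  # smallest index wins ties
    consensus = _seq.decode(consensus_codes)
    return Monomer(
        id=monomer_id,
        consensus=consensus,
        copy_number_in_source=n / period,
        source_cluster=source_cluster,
    )


def _pair_identity(a: str, b: str) -> float:
    """Best alignment identity of monomer a vs b, allowing reverse
    complement and circular rotation (b is doubled and searched infix)."""
    best = 0.0
    for target in (b + b, _seq.revcomp(b) + _seq.revcomp(b)):
        res = edlib.align(a, target, mode="HW", task="distance")
        if res["editDistance"] >= 0:
            ident = 1.0 - res["editDistance"] / len(a)
            best = max(best, ident)
    return best


def group_families(
    monomers: list[Monomer],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> dict[str, str]:
    """Single-linkage family assignment on pairwise identity.

    Two monomers join one family when their best identity (forward or
    reverse complement, any circular rotation) exceeds the threshold.
    Each family is named after its longest member (the representative);
    the mapping monomer id -> family id is returned and written back onto
    the monomers.  Invariant to input order.
    """
    if not monomers:
        return {}
    order = sorted(range(len(monomers)), key=lambda i: monomers[i].id)
    parent = list(range(len(monomers)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ai in range(len(order)):
        for bi in range(ai + 1, len(order)):
            i, j = order[ai], order[bi]
            a, b = monomers[i].consensus, monomers[j].consensus
            ident = max(_pair_identity(a, b), _pair_identity(b, a))
            if ident > identity_threshold:
                parent[find(i)] = find(j)

    assignment: dict[str, str] = {}
    for root in {find(i) for i in range(len(monomers))}:
        members = [m for i, m in enumerate(monomers) if find(i) == root]
        rep = max(members, key=lambda m: (m.period, m.id))
        for m in members:
            m.family = rep.id
            assignment[m.id] = rep.id
    return assignment


def representative(monomers: list[Monomer], family: str) -> Monomer:
    """The longest member of a family (maximum-length rule)."""
    members = [m for m in monomers if m.family == family]
    if not members:
        raise KeyError(family)
    return max(members, key=lambda m: (m.period, m.id))
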