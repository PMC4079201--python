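"""Detection of overrepresented k-mer clusters along a profile.

A satellite array shows up in the relative-frequency profile as a run of
positions whose ratio exceeds a detection threshold (default: strictly
greater than 20).  Runs separated by small gaps — N stretches inside an
array, or isolated diverged sites whose k-mers fall below threshold — are
merged, and merged runs shorter than a minimum length are discarded as
single-k-mer spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Chromosome
from .kmers import KmerProfile

DEFAULT_THRESHOLD = 20.0
DEFAULT_MERGE_GAP = 200
DEFAULT_MIN_LEN = 500


@dataclass
class SatelliteCluster:
    """A contiguous interval of overrepresented k-mers (0-based half-open)."""

    chrom: str
    start: int
    end: int
    peak_ratio: float
    mean_ratio: float
    sequence: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def call_clusters(
    profile: KmerProfile,
    threshold: float = DEFAULT_THRESHOLD,
    merge_gap: int = DEFAULT_MERGE_GAP,
    min_len: int = DEFAULT_MIN_LEN,
    chromosome: Chromosome | None = None,
) -> list[SatelliteCluster]:
    """Call maximal runs of profile positions with ratio strictly > threshold.

    Runs whose start-position gap is <= ``merge_gap`` are merged (N gaps
    inside an array do not break a run unless they exceed the gap); merged
    runs spanning less than ``min_len`` bp are discarded.  A cluster covers
    ``[first_position, last_position + k)`` so the final k-mer is included.
    If ``chromosome`` is given, cluster sequences are extracted from it.

    The threshold comparison is strict: ties at exactly ``threshold`` are
    excluded.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if chromosome is not None and chromosome.name != profile.chrom:
        raise ValueError(
            f"profile chromosome {profile.chrom!r} does not match "
            f"sequence {chromosome.name!r}"
        )
    above = profile.ratio > threshold
    pos = profile.positions[above]
    ratios = profile.ratio[above]
    if len(pos) == 0:
        return []

    # split where consecutive above-threshold positions are > merge_gap apart
    breaks = np.nonzero(np.diff(pos) > merge_gap)[0] + 1
    clusters: list[SatelliteCluster] = []
    for seg_pos, seg_ratio in zip(
        np.split(pos, breaks), np.split(ratios, breaks)
    ):
        start = int(seg_pos[0])
        end = int(seg_pos[-1]) + profile.k
        if end - start < min_len:
            continue
        cluster = SatelliteCluster(
            chrom=profile.chrom,
            start=start,
            end=end,
            peak_ratio=float(seg_ratio.max()),
            mean_ratio=float(seg_ratio.mean()),
        )
        if chromosome is not None:
            cluster.sequence = chromosome.sequence[start:end]
        clusters.append(cluster)
    clusters.sort(key=lambda c: (c.chrom, c.start))
    return clusters


def clustered_bp(clusters: list[SatelliteCluster]) -> int:
    return sum(c.length for c in clusters)
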