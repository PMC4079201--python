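"""Exact k-mer counting and chromosome-vs-background relative-frequency profiles.

For a k-mer w at position p of a focal chromosome the relative frequency is

    ratio(p) = (k_focal(w) * L_background) / (k_background(w) * L_focal)

where k_focal / k_background are occurrence counts of w in the focal and
pooled background chromosome sets and L_* are total group lengths.  A ratio
of i means the k-mer is i-times more frequent on the focal chromosome than
in the background, after length normalization.  Profiles computed this way
(X/A, F/A, A/A) are the raw material for satellite-cluster detection.

k = 13 is the default word size: long enough to detect chromosome-specific
sequence at Drosophila genome scale, and prime, so profiles are less
dominated by di-/trinucleotide simple repeats.

Counting includes overlapping occurrences; windows containing N are skipped
entirely (neither counted nor profiled), so assembly gaps cannot create
artifactual ratios.  In the default ``both`` strand mode a k-mer and its
reverse complement share one canonical key, since satellite arrays occur in
either orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _seq
from .genome import Chromosome, ConfigurationError

logger = logging.getLogger(__name__)

DEFAULT_K = 13


@dataclass
class KmerCountTable:
    """Occurrence counts of every k-mer in a chromosome set.

    Keys are stored as integer codes (base-4 encoding of the canonical
    k-mer) in sorted order for vectorized lookup; ``count_of`` accepts a
    k-mer string.  ``total_length`` is the summed bp of the counted
    chromosomes.
    """

    k: int
    strand_mode: str  # "given" | "both"
    keys: np.ndarray  # sorted int64 codes
    values: np.ndarray  # int64 counts, aligned with keys
    total_length: int

    def lookup(self, codes: np.ndarray) -> np.ndarray:
        """Counts for an array of k-mer codes (0 where absent)."""
        idx = np.searchsorted(self.keys, codes)
        idx_clipped = np.minimum(idx, len(self.keys) - 1) if len(self.keys) else idx
        out = np.zeros(len(codes), dtype=np.int64)
        if len(self.keys):
            hit = self.keys[idx_clipped] == codes
            out[hit] = self.values[idx_clipped[hit]]
        return out

    def count_of(self, kmer: str) -> int:
        code = _seq.kmer_to_code(kmer)
        if self.strand_mode == "both":
            code = min(code, _seq.kmer_to_code(_seq.revcomp(kmer)))
        return int(self.lookup(np.array([code], dtype=np.int64))[0])

    def as_dict(self) -> dict[str, int]:
        """Decode the table to {k-mer string: count}; for small tables only."""
        return {
            _seq.code_to_kmer(int(c), self.k): int(v)
            for c, v in zip(self.keys, self.values)
        }

    @property
    def n_distinct(self) -> int:
        return len(self.keys)


def count_kmers(
    chroms: list[Chromosome], k: int = DEFAULT_K, strand_mode: str = "both"
) -> KmerCountTable:
    """Count every overlapping k-mer (N-free windows) across ``chroms``.

    Streams one chromosome at a time; in ``both`` mode a k-mer and its
    reverse complement are collapsed onto one canonical key.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if not chroms:
        raise ConfigurationError("no chromosomes to count")
    if strand_mode not in ("given", "both"):
        raise ConfigurationError(f"unknown strand_mode {strand_mode!r}")

    keys = np.empty(0, dtype=np.int64)
    values = np.empty(0, dtype=np.int64)
    total_length = 0
    any_counted = False
    for chrom in chroms:
        total_length += chrom.length
        arr = _seq.encode(chrom.sequence)
        if strand_mode == "both":
            codes, valid = _seq.canonical_codes(arr, k)
        else:
            codes, valid = _seq.kmer_codes(arr, k)
        codes = codes[valid]
        if len(codes) == 0:
            continue
        any_counted = True
        new_keys, new_counts = np.unique(codes, return_counts=True)
        # merge into the running sorted table
        all_keys = np.concatenate([keys, new_keys])
        all_vals = np.concatenate([values, new_counts])
        order = np.argsort(all_keys, kind="stable")
        all_keys, all_vals = all_keys[order], all_vals[order]
        uniq, inverse = np.unique(all_keys, return_inverse=True)
        merged = np.zeros(len(uniq), dtype=np.int64)
        np.add.at(merged, inverse, all_vals)
        keys, values = uniq, merged
    if not any_counted:
        logger.warning("k=%d exceeds every chromosome length; empty table", k)
    return KmerCountTable(
        k=k, strand_mode=strand_mode, keys=keys, values=values,
        total_length=total_length,
    )


@dataclass
class KmerProfile:
    """Per-position relative-frequency profile of one focal chromosome.

    Arrays are aligned: entry i describes the k-mer starting at
    ``positions[i]`` (N-free windows only; positions strictly increasing).
    ``background_absent`` flags positions where the background count was 0
    and the ratio was computed with a denominator count of 1 — these are the
    most focal-specific signals and are kept, never dropped.
    """

    chrom: str
    k: int
    strand_mode: str
    L_focal: int
    L_background: int
    positions: np.ndarray
    codes: np.ndarray
    k_focal: np.ndarray
    k_background: np.ndarray
    ratio: np.ndarray
    background_absent: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions,
                "kmer": [_seq.code_to_kmer(int(c), self.k) for c in self.codes],
                "k_focal": self.k_focal,
                "k_background": self.k_background,
                "ratio": self.ratio,
                "background_absent": self.background_absent.astype(int),
            }
        )

    def restrict(self, start: int, end: int) -> "KmerProfile":
        """Sub-profile of positions in [start, end)."""
        m = (self.positions >= start) & (self.positions < end)
        return KmerProfile(
            self.chrom, self.k, self.strand_mode, self.L_focal, self.L_background,
            self.positions[m], self.codes[m], self.k_focal[m],
            self.k_background[m], self.ratio[m], self.background_absent[m],
        )


def relative_profile(
    focal: Chromosome,
    focal_table: KmerCountTable,
    background_table: KmerCountTable,
) -> KmerProfile:
    """Per-position ratio profile of ``focal`` against the background table.

    Both tables must share k and strand mode.  Positions whose k-mer is
    absent from the background use a denominator count of 1 and are flagged.
    """
    if focal_table.k != background_table.k:
        raise ConfigurationError(
            f"table k mismatch: {focal_table.k} vs {background_table.k}"
        )
    if focal_table.strand_mode != background_table.strand_mode:
        raise ConfigurationError("table strand_mode mismatch")
    L_f, L_b = focal_table.total_length, background_table.total_length
    if L_f <= 0 or L_b <= 0:
        raise ConfigurationError("table total_length must be positive")

    k = focal_table.k
    arr = _seq.encode(focal.sequence)
    if focal_table.strand_mode == "both":
        codes, valid = _seq.canonical_codes(arr, k)
    else:
        codes, valid = _seq.kmer_codes(arr, k)
    positions = np.nonzero(valid)[0]
    codes = codes[valid]
    kf = focal_table.lookup(codes)
    kb = background_table.lookup(codes)
    absent = kb == 0
    denom_counts = np.where(absent, 1, kb)
    ratio = (kf.astype(float) * L_b) / (denom_counts.astype(float) * L_f)
    return KmerProfile(
        chrom=focal.name, k=k, strand_mode=focal_table.strand_mode,
        L_focal=L_f, L_background=L_b,
        positions=positions.astype(np.int64), codes=codes,
        k_focal=kf, k_background=kb, ratio=ratio, background_absent=absent,
    )


def profile_summary(
    profile: KmerProfile, thresholds: tuple[float, ...] = (1.0, 20.0)
) -> dict:
    """Summary statistics of a profile: max, fraction > 1, threshold counts."""
    if len(profile) == 0:
        return {
            "chrom": profile.chrom, "n_positions": 0, "max_ratio": None,
            "median_ratio": None, "fraction_above_1": None,
            "counts_above": {t: 0 for t in thresholds}, "empty": True,
        }
    r = profile.ratio
    return {
        "chrom": profile.chrom,
        "n_positions": len(r),
        "max_ratio": float(r.max()),
        "median_ratio": float(np.median(r)),
        "fraction_above_1": float(np.mean(r > 1.0)),
        "counts_above": {t: int(np.sum(r > t)) for t in thresholds},
        "empty": False,
    }
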