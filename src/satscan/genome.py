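"""Genome data model: chromosomes, focal/background partitions, recombination maps.

The analyses in this package compare a *focal* chromosome set (e.g. the X
chromosome, Müller element A, or the dot chromosome, Müller element F)
against a pooled *background* set (autosomes).  All coordinates are 0-based
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigurationError(ValueError):
    """Raised when inputs are structurally valid but inconsistent with the run."""


class ValidationError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Chromosome:
    """A named chromosome sequence.

    The sequence is uppercased on construction; ``length`` always equals
    ``len(sequence)``.
    """

    name: str
    sequence: str
    muller_label: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeSet:
    """Chromosomes split into focal and background groups.

    Invariants: group names are disjoint; for profiling both groups must be
    non-empty with positive total length.
    """

    focal: list[Chromosome]
    background: list[Chromosome]
    species: str = ""

    def __post_init__(self) -> None:
        names = [c.name for c in self.focal] + [c.name for c in self.background]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names across groups")

    @property
    def focal_length(self) -> int:
        return sum(c.length for c in self.focal)

    @property
    def background_length(self) -> int:
        return sum(c.length for c in self.background)

    @property
    def chromosomes(self) -> list[Chromosome]:
        return list(self.focal) + list(self.background)

    def get(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def group_of(self, name: str) -> str:
        if any(c.name == name for c in self.focal):
            return "focal"
        if any(c.name == name for c in self.background):
            return "background"
        raise KeyError(name)

    def require_profiling(self) -> None:
        if not self.focal:
            raise ConfigurationError("focal group is empty")
        if not self.background:
            raise ConfigurationError("background group is empty")
        if self.focal_length == 0 or self.background_length == 0:
            raise ConfigurationError("zero-length chromosome group")


@dataclass(frozen=True)
class MapWindow:
    """One recombination-map window (0-based half-open, rate in cM/Mb)."""

    chrom: str
    start: int
    end: int
    rate: float


@dataclass
class RecombMap:
    """A recombination-rate map as non-overlapping windows per chromosome."""

    windows: list[MapWindow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.windows = sorted(self.windows, key=lambda w: (w.chrom, w.start))
        prev: MapWindow | None = None
        for w in self.windows:
            if w.start >= w.end:
                raise ValidationError(
                    f"window {w.chrom}:{w.start}-{w.end} has start >= end"
                )
            if w.rate < 0:
                raise ValidationError(
                    f"window {w.chrom}:{w.start}-{w.end} has negative rate {w.rate}"
                )
            if prev is not None and prev.chrom == w.chrom and w.start < prev.end:
                raise ValidationError(
                    f"overlapping windows: {prev.chrom}:{prev.start}-{prev.end} "
                    f"and {w.chrom}:{w.start}-{w.end}"
                )
            prev = w

    def chroms(self) -> set[str]:
        return {w.chrom for w in self.windows}

    def for_chrom(self, chrom: str) -> list[MapWindow]:
        return [w for w in self.windows if w.chrom == chrom]

    def mean_rate(self, chrom: str, start: int, end: int) -> float | None:
        """Length-weighted mean rate over [start, end); None if no overlap."""
        total = 0.0
        weight = 0
        for w in self.for_chrom(chrom):
            lo, hi = max(start, w.start), min(end, w.end)
            if hi > lo:
                total += w.rate * (hi - lo)
                weight += hi - lo
        if weight == 0:
            return None
        return total / weight
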