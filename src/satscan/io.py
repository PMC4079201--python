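"""Reading and writing the external formats: FASTA, recombination TSV, BED.

All interval output is BED-style 0-based half-open; converting a BED line
back yields the originating record.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Chromosome, ConfigurationError, GenomeSet, MapWindow, RecombMap

logger = logging.getLogger(__name__)

GroupName = str  # "focal" | "background" | "ignore"


def read_fasta(
    path: str | Path, grouping: Mapping[str, GroupName], species: str = ""
) -> GenomeSet:
    """Read a multi-FASTA and split records into focal/background groups.

    ``grouping`` maps record name to ``focal``, ``background`` or ``ignore``.
    Records absent from the grouping are dropped with a warning; sequences are
    uppercased on ingest.  Raises :class:`ConfigurationError` if either group
    ends up empty.
    """
    path = Path(path)
    focal: list[Chromosome] = []
    background: list[Chromosome] = []
    for record in SeqIO.parse(str(path), "fasta"):
        group = grouping.get(record.id, "ignore")
        if group == "focal":
            focal.append(Chromosome(record.id, str(record.seq)))
        elif group == "background":
            background.append(Chromosome(record.id, str(record.seq)))
        else:
            if record.id not in grouping:
                logger.warning("record %s not in grouping; dropped", record.id)
    for group, members in (("focal", focal), ("background", background)):
        if not members:
            raise ConfigurationError(
                f"no FASTA record matched the {group} group in {path}"
            )
    return GenomeSet(focal=focal, background=background, species=species)


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def genome_to_fasta(genome: GenomeSet, path: str | Path) -> None:
    write_fasta({c.name: c.sequence for c in genome.chromosomes}, path)


def read_recomb_map(path: str | Path) -> RecombMap:
    """Read a tab-separated windows file: chrom, start, end, rate (cM/Mb).

    Windows are validated non-overlapping and sorted per chromosome.  An
    empty file yields an empty map with a warning.
    """
    windows: list[MapWindow] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{line_no}: expected >=4 tab-separated columns"
                )
            windows.append(
                MapWindow(parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
            )
    if not windows:
        logger.warning("recombination map %s is empty", path)
    return RecombMap(windows)


def write_recomb_map(rmap: RecombMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for w in rmap.windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.rate:.6g}\n")


def write_intervals(items: Iterable, path: str | Path, prefix: str = "feature") -> None:
    """Write interval-bearing records (clusters, hits, loci) as BED.

    Items must expose ``chrom``/``start``/``end`` (loci may use
    ``span_start``/``span_end``).  The score column carries ``peak_ratio``
    (clusters) or ``identity`` (hits) when available.  Output is
    deterministically sorted by (chrom, start).
    """

    def coords(item) -> tuple[str, int, int]:
        start = getattr(item, "start", None)
        if start is None:
            return item.chrom, item.span_start, item.span_end
        return item.chrom, start, item.end

    def score(item) -> float:
        for attr in ("peak_ratio", "identity"):
            v = getattr(item, attr, None)
            if v is not None:
                return float(v)
        return 0.0

    rows = sorted(
        ((coords(it), score(it), getattr(it, "strand", None)) for it in items),
        key=lambda r: r[0],
    )
    with open(path, "w") as fh:
        for i, ((chrom, start, end), sc, strand) in enumerate(rows, 1):
            cols = [chrom, str(start), str(end), f"{prefix}_{i}", f"{sc:g}"]
            if strand is not None:
                cols.append(strand)
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float, str | None]]:
    """Parse a BED file back into (chrom, start, end, name, score, strand) rows."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            score = float(parts[4]) if len(parts) > 4 else 0.0
            strand = parts[5] if len(parts) > 5 else None
            rows.append((chrom, start, end, name, score, strand))
    return rows
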