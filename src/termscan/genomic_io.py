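"""Strand-aware genomic primitives: BED/bedGraph I/O, coverage tracks, windows.

All coordinates are 0-based half-open (BED convention). The transcription
start site (TSS) and 3'-end processing site (TES) of a gene are *points* on
the genomic axis: for a + strand gene tss = start and tes = end; for a −
strand gene tss = end and tes = start. "Downstream" always means the
direction of transcription, so on the − strand a downstream window runs
toward decreasing genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

GENE_CLASSES = ("histone", "snRNA_snoRNA", "protein_coding", "other")


class BedFormatError(ValueError):
    """Raised for malformed BED/bedGraph records; message carries line numbers."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally named/scored/stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise BedFormatError(
                f"interval start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise BedFormatError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with derived TSS/TES point accessors."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str = "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise BedFormatError(
                f"gene {self.gene_id}: start must be < end "
                f"({self.chrom}:{self.start}-{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise BedFormatError(f"gene {self.gene_id}: strand must be + or -")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"gene {self.gene_id}: unknown class {self.gene_class!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def strand_window(
    gene: GeneModel, offset_start: int, offset_end: int, anchor: str = "tes"
) -> GenomicInterval:
    """Genomic interval for a transcript-oriented window around the TSS or TES.

    Offsets are in transcript orientation: positive offsets lie downstream of
    the anchor point, negative offsets upstream. ``offset_start`` is
    inclusive, ``offset_end`` exclusive, so the window always has length
    ``offset_end - offset_start``. On the − strand the window is mirrored:
    downstream means decreasing genomic coordinate, and transcript offset
    ``o`` maps to the genomic base ``anchor - 1 - o``.
    """
    if anchor not in ("tss", "tes"):
        raise ValueError(f"anchor must be 'tss' or 'tes', got {anchor!r}")
    if offset_start >= offset_end:
        raise ValueError("offset_start must be < offset_end")
    point = gene.tes if anchor == "tes" else gene.tss
    if gene.strand == "+":
        return GenomicInterval(gene.chrom, point + offset_start, point + offset_end, "+")
    return GenomicInterval(gene.chrom, point - offset_end, point - offset_start, "-")


@dataclass
class CoverageTrack:
    """Strand-split per-base non-negative coverage with exact interval sums.

    Backed by dense per-(chromosome, strand) float arrays allocated lazily;
    positions never written read as 0. Strand "." queries sum both strands.
    """

    chrom_sizes: Mapping[str, int]
    _data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def _array(self, chrom: str, strand: str) -> np.ndarray:
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        key = (chrom, strand)
        if key not in self._data:
            self._data[key] = np.zeros(self.chrom_sizes[chrom], dtype=np.float64)
        return self._data[key]

    def add_interval(self, chrom: str, strand: str, start: int, end: int, value: float) -> None:
        if value < 0:
            raise ValueError(f"negative coverage value {value} at {chrom}:{start}-{end}")
        arr = self._array(chrom, strand)
        if start < 0 or end > arr.size:
            raise ValueError(f"interval {chrom}:{start}-{end} outside chromosome bounds")
        arr[start:end] += value

    def add_events(self, chrom: str, strand: str, positions: np.ndarray) -> None:
        """Accumulate single-base events (e.g. nascent-RNA 3' ends) as counts."""
        arr = self._array(chrom, strand)
        np.add.at(arr, np.asarray(positions, dtype=np.intp), 1.0)

    def values(self, chrom: str, strand: str) -> np.ndarray:
        return self._array(chrom, strand)

    def interval_sum(self, chrom: str, start: int, end: int, strand: str = ".") -> float:
        """Exact sum of per-base values over [start, end) on the given strand.

        The query interval is clipped to [0, chromosome length); an empty
        interval sums to 0. Strand "." sums both strands.
        """
        if chrom not in self.chrom_sizes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        size = self.chrom_sizes[chrom]
        start, end = max(start, 0), min(end, size)
        if start >= end:
            return 0.0
        strands = ("+", "-") if strand == "." else (strand,)
        total = 0.0
        for s in strands:
            if (chrom, s) in self._data:
                total += float(self._data[(chrom, s)][start:end].sum())
        return total

    def total(self, strand: str = ".") -> float:
        strands = ("+", "-") if strand == "." else (strand,)
        return float(
            sum(arr.sum() for (c, s), arr in self._data.items() if s in strands)
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        """A new track with every value multiplied by ``factor`` (must be > 0)."""
        if factor <= 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        out = CoverageTrack(self.chrom_sizes)
        for key, arr in self._data.items():
            out._data[key] = arr * factor
        return out


def window_in_bounds(interval: GenomicInterval, chrom_sizes: Mapping[str, int]) -> bool:
    size = chrom_sizes.get(interval.chrom)
    if size is None:
        return False
    return interval.start >= 0 and interval.end <= size


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column text file: chromosome name, length."""
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise BedFormatError(f"{path}:{lineno}: expected 2 columns")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{n}\n" for c, n in sizes.items()))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Parse BED3/BED6(+); malformed lines raise with their line number."""
    intervals: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise BedFormatError(f"{path}:{lineno}: fewer than 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        name = fields[3] if len(fields) > 3 else None
        score: float | None = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            score = float(fields[4])
        strand = fields[5] if len(fields) > 5 else "."
        try:
            intervals.append(
                GenomicInterval(fields[0], start, end, strand, score, name)
            )
        except BedFormatError as exc:
            raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "0" if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


def read_gene_classes(path: str | Path) -> dict[str, str]:
    """Two-column gene_id → class map; unknown class labels rejected."""
    classes: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise BedFormatError(f"{path}:{lineno}: expected 2 columns")
        if fields[1] not in GENE_CLASSES:
            raise BedFormatError(f"{path}:{lineno}: unknown gene class {fields[1]!r}")
        classes[fields[0]] = fields[1]
    return classes


def read_genes(bed_path: str | Path, class_map: Mapping[str, str] | None = None) -> list[GeneModel]:
    """Load genes from BED6; gene_class defaults to "other" when unmapped."""
    class_map = class_map or {}
    genes = []
    for iv in read_bed(bed_path):
        if iv.strand not in ("+", "-"):
            raise BedFormatError(f"gene {iv.name!r} lacks a strand")
        if iv.name is None:
            raise BedFormatError(f"gene at {iv.chrom}:{iv.start}-{iv.end} lacks a name")
        genes.append(
            GeneModel(
                gene_id=iv.name,
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                strand=iv.strand,
                gene_class=class_map.get(iv.name, "other"),
            )
        )
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    write_bed(
        (
            GenomicInterval(g.chrom, g.start, g.end, g.strand, 0.0, g.gene_id)
            for g in genes
        ),
        path,
    )


def _read_bedgraph_strand(
    path: str | Path, track: CoverageTrack, strand: str
) -> None:
    records: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise BedFormatError(f"{path}:{lineno}: expected 4 columns")
        chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        if value < 0:
            raise BedFormatError(f"{path}:{lineno}: negative value {value}")
        if start > end:
            raise BedFormatError(f"{path}:{lineno}: start > end")
        records.setdefault(chrom, []).append((start, end, value))
    for chrom, recs in records.items():
        recs.sort()
        prev_end = -1
        for start, end, value in recs:
            if start < prev_end:
                raise BedFormatError(
                    f"{path}: overlapping bedGraph records on {chrom} at {start}"
                )
            prev_end = end
            track.add_interval(chrom, strand, start, end, value)


def read_bedgraph_pair(
    plus_path: str | Path, minus_path: str | Path, chrom_sizes: Mapping[str, int]
) -> CoverageTrack:
    """Build a strand-split coverage track from one bedGraph file per strand."""
    track = CoverageTrack(dict(chrom_sizes))
    _read_bedgraph_strand(plus_path, track, "+")
    _read_bedgraph_strand(minus_path, track, "-")
    return track


def write_bedgraph_pair(
    track: CoverageTrack, plus_path: str | Path, minus_path: str | Path
) -> None:
    """Run-length encode each strand of the track to bedGraph (zeros omitted)."""
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for chrom in track.chrom_sizes:
                if (chrom, strand) not in track._data:
                    continue
                arr = track._data[(chrom, strand)]
                # boundaries where the value changes; emit nonzero runs
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0.0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
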