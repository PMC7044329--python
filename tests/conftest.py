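"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own window/coordinate
code: windows are enumerated base by base in transcript orientation and
mapped to genomic positions with explicit mirror arithmetic, so they can
catch sign/offset errors in the implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from termscan.genomic_io import CoverageTrack, GeneModel


def downstream_base(gene: GeneModel, offset: int) -> int:
    """Genomic position of the base ``offset`` bases past the TES (offset 0 =
    first base after the gene), independent mirror arithmetic."""
    if gene.strand == "+":
        return gene.tes + offset
    return gene.tes - 1 - offset


def oracle_window_sum(
    track: CoverageTrack, gene: GeneModel, off_start: int, off_end: int, strand: str
) -> float:
    """Per-base loop over transcript-oriented offsets [off_start, off_end)."""
    total = 0.0
    for off in range(off_start, off_end):
        pos = downstream_base(gene, off)
        total += track.interval_sum(gene.chrom, pos, pos + 1, strand)
    return total


def oracle_proseq_ratio(track: CoverageTrack, gene: GeneModel) -> float | None:
    num = oracle_window_sum(track, gene, 500, 1000, gene.strand)
    den = oracle_window_sum(track, gene, -50, 0, gene.strand)
    return None if den == 0 else num / den


def oracle_polii_ratio(track: CoverageTrack, gene: GeneModel) -> float | None:
    num = oracle_window_sum(track, gene, 0, 1000, ".")
    den = oracle_window_sum(track, gene, -gene.length, 1000, ".")
    return None if den == 0 else num / den


def random_gene_and_track(
    rng: np.random.Generator, chrom_len: int = 20000
) -> tuple[GeneModel, CoverageTrack]:
    """A random gene with in-bounds windows plus a sparse random track."""
    length = int(rng.integers(200, 3000))
    start = int(rng.integers(1100, chrom_len - length - 1100))
    strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel("g", "chrT", start, start + length, strand)
    track = CoverageTrack({"chrT": chrom_len})
    for s in ("+", "-"):
        n = int(rng.integers(1000, 4000))
        positions = rng.integers(0, chrom_len, size=n)
        track.add_events("chrT", s, positions)
    return gene, track


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def uniform_track() -> tuple[GeneModel, CoverageTrack]:
    """Constant per-base coverage 2.0 on both strands around a + strand gene."""
    track = CoverageTrack({"chr1": 10000})
    for strand in ("+", "-"):
        track.add_interval("chr1", strand, 0, 10000, 2.0)
    gene = GeneModel("uni", "chr1", 3000, 5000, "+", "protein_coding")
    return gene, track
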