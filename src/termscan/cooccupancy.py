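"""Peak filtering and TSS-proximal co-occupancy across ChIP factors.

A gene is occupied by a factor when at least one significant peak of that
factor overlaps the closed window [TSS − w, TSS + w] around the gene's
transcription start site (w defaults to 1000 bp; distance is
strand-independent). Genes occupied by every factor form the co-occupied
set, reported together with the full exclusive Venn partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Set

from .genomic_io import GeneModel, GenomicInterval
from .setops import venn_partition


@dataclass(frozen=True)
class PeakSet:
    factor_name: str
    peaks: tuple[GenomicInterval, ...]


def filter_peaks(
    peak_set: PeakSet, q_max: float = 1e-4, score_scale: str = "q"
) -> PeakSet:
    """Retain peaks with q-value below ``q_max``.

    ``score_scale`` declares how the peak score column is encoded: ``"q"``
    for probability-scale q-values, ``"neglog10"`` for −log10(q) scores as
    emitted by common peak callers (a −log10 score s corresponds to
    q = 10^−s, so larger scores are more significant).
    """
    if score_scale not in ("q", "neglog10"):
        raise ValueError(f"score_scale must be 'q' or 'neglog10', got {score_scale!r}")
    kept = []
    for peak in peak_set.peaks:
        if peak.score is None:
            raise ValueError(f"peak {peak.chrom}:{peak.start}-{peak.end} lacks a score")
        q = 10.0 ** (-peak.score) if score_scale == "neglog10" else peak.score
        if q < q_max:
            kept.append(peak)
    return PeakSet(peak_set.factor_name, tuple(kept))


def tss_proximal_genes(
    peak_set: PeakSet, genes: Iterable[GeneModel], window_bp: int = 1000
) -> set[str]:
    """Gene ids with >= 1 peak intersecting [tss − window_bp, tss + window_bp].

    The window is closed at both ends, so a peak whose nearest covered base
    sits exactly window_bp from the TSS still counts. A gene counts once
    regardless of how many peaks hit its window.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for peak in peak_set.peaks:
        by_chrom.setdefault(peak.chrom, []).append(peak)
    hits: set[str] = set()
    for gene in genes:
        lo, hi = gene.tss - window_bp, gene.tss + window_bp
        for peak in by_chrom.get(gene.chrom, ()):
            # peak covers bases [start, end-1]; empty peaks cannot overlap
            if peak.start <= hi and peak.end - 1 >= lo:
                hits.add(gene.gene_id)
                break
    return hits


def cooccupied_genes(
    gene_sets: Mapping[str, Set[str]]
) -> tuple[set[str], dict[frozenset[str], int]]:
    """Genes occupied by every factor, plus all exclusive Venn region counts."""
    if len(gene_sets) < 2:
        raise ValueError("need >= 2 factors for a co-occupancy analysis")
    intersection = set.intersection(*(set(s) for s in gene_sets.values()))
    return intersection, venn_partition(gene_sets)


def cooccupancy_analysis(
    peak_sets: Sequence[PeakSet],
    genes: Sequence[GeneModel],
    window_bp: int = 1000,
    q_max: float = 1e-4,
    score_scale: str = "q",
) -> tuple[set[str], dict[frozenset[str], int]]:
    """Full pipeline: q-filter each factor's peaks, map to TSS-proximal genes,
    intersect across factors."""
    gene_sets = {
        ps.factor_name: tss_proximal_genes(
            filter_peaks(ps, q_max=q_max, score_scale=score_scale), genes, window_bp
        )
        for ps in peak_sets
    }
    return cooccupied_genes(gene_sets)
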