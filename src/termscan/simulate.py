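"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the real assays:

* a packed synthetic genome with class-dependent gene lengths and guaranteed
  downstream clearance so every read-through window is in bounds;
* nascent-transcription tracks made of single-base 3'-end events — a
  fraction f of polymerases read through the TES and terminate at a
  geometrically distributed distance (mean λ) downstream, the rest
  terminate uniformly inside the gene body;
* polymerase-occupancy tracks with per-base Poisson signal: a plateau over
  the gene body and an exponentially decaying tail (f·exp(−d/λ)) downstream;
* dual-library negative-binomial count matrices with a planted aberrantly
  polyadenylated subset (strong polyA-selected effect, no ribo-depleted
  effect);
* spectral counts drawn from known protein abundances with controlled
  peptide sharing;
* replicate Ct tables generated from known unprocessed fractions with
  Gaussian cycle noise.

Every generator is a pure function of (config, seed): identical inputs give
byte-identical outputs. Default parameters mirror the study conditions the
pipeline is meant to detect (e.g. read-through probability 0.05 in wild
type vs 0.3 in mutant at histone and snRNA genes, equal at protein-coding
genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack, GeneModel
from .dnsaf import PeptideEvidence, SpectralCountData

CONDITIONS = ("WT", "MUT")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative models, with study-condition defaults."""

    seed: int = 0
    # genome
    n_genes: Mapping[str, int] = field(
        default_factory=lambda: {
            "histone": 60,
            "snRNA_snoRNA": 40,
            "protein_coding": 100,
            "other": 0,
        }
    )
    length_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "histone": (400, 1000),
            "snRNA_snoRNA": (100, 300),
            "protein_coding": (2000, 50000),  # log-uniform
            "other": (1000, 5000),
        }
    )
    n_chroms: int = 4
    clearance: int = 2000  # gene-free bases flanking every gene
    # nascent / occupancy tracks
    depth: int = 5000  # 3'-end events (or expected occupancy reads) per gene
    readthrough_prob: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "histone": {"WT": 0.05, "MUT": 0.3},
            "snRNA_snoRNA": {"WT": 0.05, "MUT": 0.3},
            "protein_coding": {"WT": 0.05, "MUT": 0.05},
            "other": {"WT": 0.05, "MUT": 0.05},
        }
    )
    tail_decay: float = 200.0  # λ, mean read-through distance in bases
    # dual-library counts
    n_transcripts: int = 500
    n_planted: int = 50
    replicates: int = 4
    nb_dispersion: float = 0.05
    polya_effect: float = 4.0  # fold change of planted transcripts, polyA library
    ribo_effect: float = 0.5  # fold change of planted transcripts, ribo library
    baseline_log_mean: float = 6.0  # ln-scale mean of baseline expression
    baseline_log_sd: float = 0.6
    # qPCR
    unprocessed_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "HIST1": {"WT": 0.02, "MUT": 0.125},
            "GAPDH": {"WT": 0.01, "MUT": 0.01},
        }
    )
    qpcr_noise_sd: float = 0.1  # cycles
    qpcr_replicates: int = 3
    qpcr_baseline_ct: float = 24.0
    # spectral counts
    n_proteins: int = 50
    peptide_sharing_fraction: float = 0.2
    peptides_per_kres: float = 20.0  # peptides per 1000 residues
    spectra_depth: float = 5000.0  # expected total spectral counts
    abundance_log_sd: float = 1.0

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent child generator for a named simulation stream."""
        return np.random.default_rng([self.seed, *stream])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping genes with ``clearance`` gene-free bases on both sides.

    Genes are dealt round-robin across chromosomes with random strands, so
    every read-through window (up to clearance bases past either gene end)
    stays in bounds and never touches a neighboring gene's signal.
    """
    rng = config.rng(0)
    lengths: list[tuple[str, int]] = []
    for gene_class, n in config.n_genes.items():
        lo, hi = config.length_ranges[gene_class]
        if gene_class == "protein_coding":
            ln = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
        else:
            ln = rng.uniform(lo, hi, size=n)
        lengths.extend((gene_class, int(length)) for length in ln)
    rng.shuffle(lengths)

    cursors = {f"chr{i + 1}": config.clearance for i in range(config.n_chroms)}
    genes: list[GeneModel] = []
    chrom_names = list(cursors)
    for idx, (gene_class, length) in enumerate(lengths):
        chrom = chrom_names[idx % len(chrom_names)]
        start = cursors[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"G{idx:04d}",
                chrom=chrom,
                start=start,
                end=start + length,
                strand=strand,
                gene_class=gene_class,
            )
        )
        cursors[chrom] = start + length + 2 * config.clearance
    chrom_sizes = {c: cursors[c] + config.clearance for c in chrom_names}
    return genes, chrom_sizes


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

def geometric_window_mass(lam: float, a: int, b: int) -> float:
    """P(a <= G < b) for the read-through offset G, geometric with mean λ.

    G counts bases past the TES (support 0, 1, 2, ...) with success
    probability p = 1/(1+λ), so P(G >= k) = (λ/(1+λ))^k.
    """
    r = lam / (1.0 + lam)
    return r**a - r**b


def _downstream_positions(gene: GeneModel, offsets: np.ndarray) -> np.ndarray:
    """Genomic base for each transcript-oriented downstream offset (0 = first
    base past the TES)."""
    if gene.strand == "+":
        return gene.tes + offsets
    return gene.tes - 1 - offsets


def simulate_nascent_track(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    config: SimulationConfig,
    condition: str,
) -> CoverageTrack:
    """Single-base nascent 3'-end events with a class/condition read-through tail.

    Per gene, ``depth`` events: with probability 1−f the polymerase position
    is uniform over the gene body; with probability f it lies G bases past
    the TES, G geometric with mean λ. Tail events beyond the downstream
    clearance are discarded (they would be unmappable in a real assay).
    """
    rng = config.rng(1, CONDITIONS.index(condition))
    track = CoverageTrack(dict(chrom_sizes))
    p_tail = 1.0 / (1.0 + config.tail_decay)
    for gene in genes:
        f = config.readthrough_prob[gene.gene_class][condition]
        is_tail = rng.random(config.depth) < f
        n_tail = int(is_tail.sum())
        body = rng.integers(gene.start, gene.end, size=config.depth - n_tail)
        track.add_events(gene.chrom, gene.strand, body)
        if n_tail:
            offsets = rng.geometric(p_tail, size=n_tail) - 1
            offsets = offsets[offsets < config.clearance]
            track.add_events(
                gene.chrom, gene.strand, _downstream_positions(gene, offsets)
            )
    return track


def expected_polii_ratio(gene_length: int, f: float, lam: float, down_len: int = 1000) -> float:
    """Closed-form expected occupancy read-through ratio under the generative
    model: body rate ρ over L bases, downstream rate ρ·f·e^(−d/λ)."""
    d = np.arange(down_len)
    tail = f * np.exp(-d / lam).sum()
    return float(tail / (gene_length + tail))


def simulate_polii_track(
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    config: SimulationConfig,
    condition: str,
    down_len: int = 1000,
) -> CoverageTrack:
    """Plateau-like polymerase occupancy with an exponential downstream tail.

    Per-base Poisson counts: rate ρ = depth/L over the gene body and
    ρ·f·exp(−d/λ) at distance d past the TES, accumulated on the gene's
    strand (downstream analyses may query it unstranded).
    """
    rng = config.rng(2, CONDITIONS.index(condition))
    track = CoverageTrack(dict(chrom_sizes))
    for gene in genes:
        f = config.readthrough_prob[gene.gene_class][condition]
        rho = config.depth / gene.length
        body = rng.poisson(rho, size=gene.length).astype(np.float64)
        arr = track.values(gene.chrom, gene.strand)
        arr[gene.start : gene.end] += body
        d = np.arange(down_len)
        tail = rng.poisson(rho * f * np.exp(-d / config.tail_decay)).astype(np.float64)
        positions = _downstream_positions(gene, d)
        arr[positions] += tail
    return track


# ---------------------------------------------------------------------------
# dual-library counts
# ---------------------------------------------------------------------------

def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float, size: tuple[int, int]
) -> np.ndarray:
    """Negative-binomial counts with var = μ + α μ² (α = dispersion)."""
    if dispersion <= 0:
        return rng.poisson(mean[:, None], size=size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p[:, None], size=size)


def simulate_counts_dual_library(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(polyA counts, ribo counts, truth table) with a planted aberrant subset.

    The first ``n_planted`` transcripts carry a ``polya_effect``-fold
    increase in the perturbation samples of the polyA-selected library and a
    ``ribo_effect``-fold (default: none) change in the ribo-depleted
    library; all other transcripts are null in both. Columns are
    ctrl_1..n, kd_1..n per library.
    """
    rng = config.rng(3)
    ids = [f"T{i:04d}" for i in range(config.n_transcripts)]
    baseline = rng.lognormal(
        config.baseline_log_mean, config.baseline_log_sd, config.n_transcripts
    )
    planted = np.zeros(config.n_transcripts, dtype=bool)
    planted[: config.n_planted] = True

    frames = {}
    for lib, effect in (("polyA", config.polya_effect), ("ribo", config.ribo_effect)):
        mean_kd = np.where(planted, baseline * effect, baseline)
        n_rep = config.replicates
        ctrl = _nb_counts(rng, baseline, config.nb_dispersion, (config.n_transcripts, n_rep))
        kd = _nb_counts(rng, mean_kd, config.nb_dispersion, (config.n_transcripts, n_rep))
        cols = [f"ctrl_{i + 1}" for i in range(n_rep)] + [f"kd_{i + 1}" for i in range(n_rep)]
        frames[lib] = pd.DataFrame(
            np.hstack([ctrl, kd]), index=pd.Index(ids, name="transcript_id"), columns=cols
        )
    truth = pd.DataFrame(
        {"aberrant_polyA": planted, "baseline_mean": baseline},
        index=pd.Index(ids, name="transcript_id"),
    )
    return frames["polyA"], frames["ribo"], truth


# ---------------------------------------------------------------------------
# spectral counts
# ---------------------------------------------------------------------------

def simulate_spectral_counts(
    config: SimulationConfig,
) -> tuple[SpectralCountData, pd.Series]:
    """Spectral counts from known abundances with controlled peptide sharing.

    Protein lengths are log-uniform over 100–2000 residues and abundances
    log-normal. Each protein gets peptides in proportion to its length; a
    configured fraction of peptides is additionally assigned to one other
    random protein (shared evidence). Peptide counts are Poisson with rate
    proportional to the summed abundance of the proteins carrying it.
    """
    rng = config.rng(4)
    n = config.n_proteins
    ids = [f"P{i:03d}" for i in range(n)]
    lengths = np.exp(rng.uniform(np.log(100), np.log(2000), n)).astype(int)
    abundance = pd.Series(rng.lognormal(0.0, config.abundance_log_sd, n), index=ids)

    peptides: list[tuple[frozenset[str], float]] = []
    for i, pid in enumerate(ids):
        n_pep = max(2, int(round(lengths[i] * config.peptides_per_kres / 1000)))
        for _ in range(n_pep):
            members = {pid}
            if rng.random() < config.peptide_sharing_fraction and n > 1:
                other = int(rng.integers(n - 1))
                members.add(ids[other if other < i else other + 1])
            rate = sum(abundance[m] for m in members)
            peptides.append((frozenset(members), rate))

    total_rate = sum(rate for _, rate in peptides)
    evidence = [
        PeptideEvidence(
            f"pep{j:05d}",
            members,
            int(rng.poisson(config.spectra_depth * rate / total_rate)),
        )
        for j, (members, rate) in enumerate(peptides)
    ]
    data = SpectralCountData(dict(zip(ids, (int(x) for x in lengths))), evidence)
    return data, abundance


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(config: SimulationConfig) -> pd.DataFrame:
    """Tidy Ct table from known unprocessed fractions q per (target, condition).

    Ct_CT is drawn around a baseline; Ct_UT = Ct_CT − log2(q) plus Gaussian
    cycle noise, so a noise-free table inverts exactly to q through 2^−ΔCt.
    """
    rng = config.rng(5)
    rows = []
    for target, by_condition in config.unprocessed_fractions.items():
        for condition, q in by_condition.items():
            if not 0 < q <= 1:
                raise ValueError(f"unprocessed fraction must be in (0, 1], got {q}")
            for rep in range(1, config.qpcr_replicates + 1):
                ct_ct = config.qpcr_baseline_ct + rng.normal(0, config.qpcr_noise_sd)
                ct_ut = ct_ct - np.log2(q) + rng.normal(0, config.qpcr_noise_sd)
                sample = f"{condition}_{rep}"
                rows.append((sample, condition, target, "CT", rep, ct_ct))
                rows.append((sample, condition, target, "UT", rep, ct_ut))
    return pd.DataFrame(
        rows, columns=["sample", "condition", "target", "amplicon", "replicate", "ct"]
    )


# ---------------------------------------------------------------------------
# file-writing front end (used by the CLI)
# ---------------------------------------------------------------------------

def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Run every generator and write all pipeline input files to ``outdir``.

    Returns a manifest mapping logical names to file paths. bedGraph pairs
    are written per condition for both the nascent and occupancy tracks.
    """
    from . import genomic_io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    genes, chrom_sizes = simulate_genome(config)
    gio.write_genes(genes, outdir / "genes.bed")
    gio.write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")
    (outdir / "gene_classes.tsv").write_text(
        "".join(f"{g.gene_id}\t{g.gene_class}\n" for g in genes)
    )
    paths.update(
        genes=str(outdir / "genes.bed"),
        chrom_sizes=str(outdir / "chrom.sizes"),
        gene_classes=str(outdir / "gene_classes.tsv"),
    )

    for condition in CONDITIONS:
        nascent = simulate_nascent_track(genes, chrom_sizes, config, condition)
        polii = simulate_polii_track(genes, chrom_sizes, config, condition)
        for label, track in (("proseq", nascent), ("polii", polii)):
            plus = outdir / f"{label}_{condition}_plus.bedgraph"
            minus = outdir / f"{label}_{condition}_minus.bedgraph"
            gio.write_bedgraph_pair(track, plus, minus)
            paths[f"{label}_{condition}_plus"] = str(plus)
            paths[f"{label}_{condition}_minus"] = str(minus)

    polya, ribo, truth = simulate_counts_dual_library(config)
    polya.to_csv(outdir / "counts_polyA.tsv", sep="\t")
    ribo.to_csv(outdir / "counts_ribo.tsv", sep="\t")
    truth.to_csv(outdir / "counts_truth.tsv", sep="\t")
    paths.update(
        counts_polyA=str(outdir / "counts_polyA.tsv"),
        counts_ribo=str(outdir / "counts_ribo.tsv"),
        counts_truth=str(outdir / "counts_truth.tsv"),
    )

    spectra, abundance = simulate_spectral_counts(config)
    from .dnsaf import write_spectral_counts

    write_spectral_counts(spectra, outdir / "proteins.tsv", outdir / "peptides.tsv")
    abundance.rename("abundance").to_csv(outdir / "protein_abundance.tsv", sep="\t")
    paths.update(
        proteins=str(outdir / "proteins.tsv"),
        peptides=str(outdir / "peptides.tsv"),
        protein_abundance=str(outdir / "protein_abundance.tsv"),
    )

    simulate_qpcr(config).to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    paths["qpcr_ct"] = str(outdir / "qpcr_ct.tsv")
    return paths
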