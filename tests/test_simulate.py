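"""Generative-model correctness: determinism, closed forms, truth recovery."""

import numpy as np
import pytest

from termscan.genomic_io import read_bedgraph_pair, read_genes
from termscan.qpcr import unprocessed_fraction
from termscan.readthrough import proseq_readthrough_ratio, readthrough_table
from termscan.dnsaf import dnsaf_table
from termscan.simulate import (
    SimulationConfig,
    expected_polii_ratio,
    geometric_window_mass,
    simulate_counts_dual_library,
    simulate_genome,
    simulate_nascent_track,
    simulate_polii_track,
    simulate_qpcr,
    simulate_spectral_counts,
    write_simulation,
)

SMALL = dict(
    n_genes={"histone": 6, "snRNA_snoRNA": 6, "protein_coding": 6, "other": 6},
    length_ranges={
        "histone": (400, 1000),
        "snRNA_snoRNA": (100, 300),
        "protein_coding": (2000, 6000),
        "other": (1000, 3000),
    },
    depth=2000,
)


class TestSimulateGenome:
    def test_counts_and_class_balance(self):
        genes, sizes = simulate_genome(SimulationConfig(seed=3, **SMALL))
        assert len(genes) == 24
        assert {g.gene_class for g in genes} == {
            "histone", "snRNA_snoRNA", "protein_coding", "other",
        }
        assert {g.strand for g in genes} == {"+", "-"}

    def test_all_readthrough_windows_in_bounds(self):
        config = SimulationConfig(seed=3, **SMALL)
        genes, sizes = simulate_genome(config)
        track = simulate_nascent_track(genes, sizes, config, "WT")
        results = readthrough_table(track, genes, "proseq")
        assert all(r.invalid_reason != "window_out_of_bounds" for r in results)

    def test_deterministic_given_seed(self, tmp_path):
        cfg = SimulationConfig(seed=7, **SMALL)
        for sub in ("a", "b"):
            (tmp_path / sub).mkdir()
            write_simulation(cfg, tmp_path / sub)
        for name in ("genes.bed", "chrom.sizes", "proseq_WT_plus.bedgraph",
                     "counts_polyA.tsv", "qpcr_ct.tsv", "peptides.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_seed_changes_coordinates_not_counts(self):
        g1, _ = simulate_genome(SimulationConfig(seed=1, **SMALL))
        g2, _ = simulate_genome(SimulationConfig(seed=2, **SMALL))
        assert len(g1) == len(g2)
        assert [g.start for g in g1] != [g.start for g in g2]


class TestNascentTrack:
    def test_no_readthrough_means_zero_downstream(self):
        cfg = SimulationConfig(
            seed=5, **SMALL,
            readthrough_prob={c: {"WT": 0.0, "MUT": 0.0}
                              for c in ("histone", "snRNA_snoRNA", "protein_coding", "other")},
        )
        genes, sizes = simulate_genome(cfg)
        track = simulate_nascent_track(genes, sizes, cfg, "WT")
        for r in readthrough_table(track, genes, "proseq"):
            assert r.valid and r.ratio == 0.0

    def test_numerator_matches_geometric_closed_form(self):
        # expected numerator = D * f * P(500 <= G < 1000)
        cfg = SimulationConfig(
            seed=5,
            n_genes={"histone": 40, "snRNA_snoRNA": 0, "protein_coding": 0, "other": 0},
            depth=10000,
        )
        genes, sizes = simulate_genome(cfg)
        track = simulate_nascent_track(genes, sizes, cfg, "MUT")
        f, lam, D = 0.3, cfg.tail_decay, cfg.depth
        expect = D * f * geometric_window_mass(lam, 500, 1000)
        nums = [proseq_readthrough_ratio(track, g).numerator for g in genes]
        se = np.sqrt(expect) / np.sqrt(len(nums))  # Poisson-scale error of the mean
        assert abs(np.mean(nums) - expect) < 3 * se

    def test_full_readthrough_starves_denominator(self):
        cfg = SimulationConfig(
            seed=5, **SMALL,
            readthrough_prob={c: {"WT": 1.0, "MUT": 1.0}
                              for c in ("histone", "snRNA_snoRNA", "protein_coding", "other")},
        )
        genes, sizes = simulate_genome(cfg)
        track = simulate_nascent_track(genes, sizes, cfg, "WT")
        results = readthrough_table(track, genes, "proseq")
        invalid = [r for r in results if not r.valid]
        assert len(invalid) > len(results) / 2
        assert all(r.invalid_reason == "zero_denominator" for r in invalid)


class TestPoliiTrack:
    def test_no_readthrough_gives_near_zero_ratio(self):
        cfg = SimulationConfig(
            seed=5, **{**SMALL, "depth": 10000},
            readthrough_prob={c: {"WT": 0.0, "MUT": 0.0}
                              for c in ("histone", "snRNA_snoRNA", "protein_coding", "other")},
        )
        genes, sizes = simulate_genome(cfg)
        track = simulate_polii_track(genes, sizes, cfg, "WT")
        ratios = [r.ratio for r in readthrough_table(track, genes, "polii")]
        assert np.mean(ratios) < 0.01

    def test_saturating_tail_approaches_uniform_limit(self):
        # f = 1 and lambda >> 1000: downstream rate ~ body rate, so the
        # expected ratio tends to 1000 / (L + 1000)
        cfg = SimulationConfig(
            seed=5, depth=20000, tail_decay=1e6,
            n_genes={"histone": 30, "snRNA_snoRNA": 0, "protein_coding": 0, "other": 0},
            length_ranges=SMALL["length_ranges"],
            readthrough_prob={"histone": {"WT": 1.0, "MUT": 1.0},
                              "snRNA_snoRNA": {"WT": 0, "MUT": 0},
                              "protein_coding": {"WT": 0, "MUT": 0},
                              "other": {"WT": 0, "MUT": 0}},
        )
        genes, sizes = simulate_genome(cfg)
        track = simulate_polii_track(genes, sizes, cfg, "WT")
        for gene in genes:
            from termscan.readthrough import polii_readthrough_ratio

            r = polii_readthrough_ratio(track, gene)
            limit = 1000 / (gene.length + 1000)
            assert r.ratio == pytest.approx(limit, rel=0.15)
            assert r.ratio == pytest.approx(
                expected_polii_ratio(gene.length, 1.0, 1e6), rel=0.15
            )

    def test_higher_f_gives_higher_mean_ratio(self):
        cfg = SimulationConfig(seed=5, **SMALL)
        genes, sizes = simulate_genome(cfg)
        wt = simulate_polii_track(genes, sizes, cfg, "WT")
        mut = simulate_polii_track(genes, sizes, cfg, "MUT")
        hist = [g for g in genes if g.gene_class == "histone"]
        mean_wt = np.mean([r.ratio for r in readthrough_table(wt, hist, "polii")])
        mean_mut = np.mean([r.ratio for r in readthrough_table(mut, hist, "polii")])
        assert mean_mut > mean_wt


class TestCountsDualLibrary:
    def test_same_seed_identical(self):
        a = simulate_counts_dual_library(SimulationConfig(seed=9))
        b = simulate_counts_dual_library(SimulationConfig(seed=9))
        for x, y in zip(a, b):
            assert x.equals(y)

    def test_truth_table_marks_planted_subset(self):
        cfg = SimulationConfig(seed=9)
        _, _, truth = simulate_counts_dual_library(cfg)
        assert truth["aberrant_polyA"].sum() == cfg.n_planted

    def test_planted_effect_visible_in_raw_means(self):
        cfg = SimulationConfig(seed=9)
        polya, ribo, truth = simulate_counts_dual_library(cfg)
        planted = truth["aberrant_polyA"]
        kd = polya.filter(like="kd_").mean(axis=1)
        ctrl = polya.filter(like="ctrl_").mean(axis=1)
        assert (kd[planted] / ctrl[planted]).median() == pytest.approx(4.0, rel=0.15)
        assert (kd[~planted] / ctrl[~planted]).median() == pytest.approx(1.0, rel=0.1)


class TestSpectralCounts:
    def test_no_sharing_reduces_to_nsaf(self):
        cfg = SimulationConfig(seed=11, peptide_sharing_fraction=0.0)
        data, _ = simulate_spectral_counts(cfg)
        assert all(not p.shared for p in data.peptides)
        tab = dnsaf_table(data)
        saf = (tab["uSpC"] / [data.protein_lengths[p] for p in tab.index])
        np.testing.assert_allclose(tab["dNSAF"], saf / saf.sum(), rtol=1e-12)

    def test_equal_abundance_symmetry(self):
        cfg = SimulationConfig(seed=11, n_proteins=2, abundance_log_sd=0.0,
                               spectra_depth=20000.0)
        data, abundance = simulate_spectral_counts(cfg)
        tab = dnsaf_table(data)
        # equal abundance; dNSAF deviates from 1/2 only through lengths and
        # sampling, and protein lengths cancel in expectation per residue
        assert abundance.iloc[0] == abundance.iloc[1]
        assert tab["dNSAF"].sum() == pytest.approx(1.0, abs=1e-9)


class TestQpcrTable:
    def test_noise_free_inversion_exact(self):
        cfg = SimulationConfig(
            seed=13, qpcr_noise_sd=0.0,
            unprocessed_fractions={"H1": {"WT": 0.125, "MUT": 1.0}},
        )
        table = simulate_qpcr(cfg)
        assert unprocessed_fraction(table, "WT", "H1").mean == pytest.approx(0.125, rel=1e-12)
        assert unprocessed_fraction(table, "MUT", "H1").mean == pytest.approx(1.0, rel=1e-12)

    def test_noisy_estimate_unbiased(self):
        cfg = SimulationConfig(
            seed=13, qpcr_noise_sd=0.1, qpcr_replicates=1000,
            unprocessed_fractions={"H1": {"WT": 0.25}},
        )
        level = unprocessed_fraction(simulate_qpcr(cfg), "WT", "H1")
        # 2^noise has mean slightly above 1; with sd 0.1 cycles the bias is
        # ~0.5% so the mean recovers q within 2%
        assert level.mean == pytest.approx(0.25, rel=0.02)

    def test_invalid_fraction_rejected(self):
        cfg = SimulationConfig(seed=13, unprocessed_fractions={"H1": {"WT": 1.5}})
        with pytest.raises(ValueError, match="unprocessed fraction"):
            simulate_qpcr(cfg)


def test_written_files_parse_cleanly(tmp_path):
    cfg = SimulationConfig(seed=21, **SMALL)
    paths = write_simulation(cfg, tmp_path)
    from termscan.genomic_io import read_chrom_sizes, read_gene_classes

    sizes = read_chrom_sizes(paths["chrom_sizes"])
    genes = read_genes(paths["genes"], read_gene_classes(paths["gene_classes"]))
    assert len(genes) == 24
    track = read_bedgraph_pair(
        paths["proseq_WT_plus"], paths["proseq_WT_minus"], sizes
    )
    assert track.total() > 0
    # round trip: parsed track equals the in-memory original
    original = simulate_nascent_track(genes, sizes, cfg, "WT")
    for chrom in sizes:
        for strand in ("+", "-"):
            np.testing.assert_array_equal(
                track.values(chrom, strand), original.values(chrom, strand)
            )
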