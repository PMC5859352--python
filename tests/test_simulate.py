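"""Generator tests: determinism, planted structure, round-trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiconcord import io as eio
from epiconcord.simulate import (SimulationConfig, generate_annotation,
                                 generate_chip_reads, generate_expression_counts,
                                 generate_promoter_sequences, generate_pwm_library,
                                 generate_snp_table, simulate_study)
from epiconcord.states import fit_three_component_mixture


class TestAnnotation:
    def test_spacing_and_bounds(self, small_config):
        ann = generate_annotation(small_config)
        assert len(ann) == small_config.n_genes
        assert ann["gene_id"].is_unique
        for _, block in ann.groupby("chrom"):
            tss = np.sort(block["tss"].to_numpy())
            assert (np.diff(tss) >= 2000).all()
            assert tss.min() >= 500
            assert tss.max() <= small_config.chrom_length - 500

    def test_two_genes_small_chromosome(self):
        cfg = SimulationConfig(n_genes=2, n_chromosomes=1, chrom_length=10_000)
        ann = generate_annotation(cfg)
        assert len(ann) == 2
        assert abs(ann["tss"].iloc[1] - ann["tss"].iloc[0]) >= 2000

    def test_deterministic(self, small_config):
        a = generate_annotation(small_config)
        b = generate_annotation(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_capacity_error_names_required_length(self):
        cfg = SimulationConfig(n_genes=2, n_chromosomes=1, chrom_length=10_000)
        cfg = dataclasses.replace(cfg, n_genes=100)
        with pytest.raises(ValueError, match=r"needs at least \d+ bp"):
            generate_annotation(cfg)


class TestPromoterSequences:
    def test_forced_gc_within_binomial_bounds(self, small_config):
        ann = generate_annotation(small_config).head(20)
        seqs, gc = generate_promoter_sequences(ann, 0.5, 0.5, None, None, seed=3)
        # 99% binomial bounds for n=1000, p=0.5
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.5)
        for g, s in seqs.items():
            n_gc = s.count("G") + s.count("C")
            assert lo <= n_gc <= hi

    def test_planted_consensus_found_by_substring_search(self, small_config):
        ann = generate_annotation(small_config)
        pwms = generate_pwm_library(2, 8, 10, 0.1, seed=5)
        target = ann["gene_id"].iloc[0]
        seqs, _ = generate_promoter_sequences(
            ann, 0.4, 0.6, {pwms[0].id: [target]}, pwms, seed=5)
        assert pwms[0].consensus in seqs[target]

    def test_gc_uniform_by_ks(self):
        cfg = SimulationConfig(n_genes=2000, n_chromosomes=4, chrom_length=1_500_000)
        ann = generate_annotation(cfg)
        _, gc = generate_promoter_sequences(ann, 0.3, 0.7, None, None, seed=11)
        stat = stats.kstest(gc.to_numpy(), stats.uniform(0.3, 0.4).cdf)
        assert stat.pvalue > 0.01

    def test_motif_wider_than_sequence_rejected(self, small_config):
        ann = generate_annotation(small_config).head(2)
        pwms = generate_pwm_library(1, 8, 8, 0.1, seed=5)
        with pytest.raises(ValueError, match="wider"):
            generate_promoter_sequences(ann, 0.4, 0.6,
                                        {pwms[0].id: [ann["gene_id"].iloc[0]]},
                                        pwms, seed=5, length=4)


class TestPWMLibrary:
    def test_columns_stochastic_and_deterministic(self):
        a = generate_pwm_library(5, 6, 12, 0.5, seed=2)
        b = generate_pwm_library(5, 6, 12, 0.5, seed=2)
        for pa, pb in zip(a, b):
            np.testing.assert_allclose(pa.probs.sum(axis=0), 1.0, atol=1e-9)
            np.testing.assert_array_equal(pa.probs, pb.probs)
        widths = {p.width for p in a}
        assert widths <= set(range(6, 13))

    def test_peaked_concentration_has_more_information(self):
        def mean_ic(pwms):
            ics = []
            for p in pwms:
                q = np.clip(p.probs, 1e-12, 1)
                ics.append(np.mean(2 + (q * np.log2(q)).sum(axis=0)))
            return np.mean(ics)

        peaked = generate_pwm_library(30, 8, 8, 0.1, seed=4)
        flat = generate_pwm_library(30, 8, 8, 10.0, seed=4)
        assert mean_ic(peaked) > mean_ic(flat)

    def test_invalid_concentration(self):
        with pytest.raises(ValueError):
            generate_pwm_library(2, 4, 6, 0.0, seed=1)


class TestExpressionCounts:
    def test_null_effect_gives_empty_truth(self, small_config):
        cfg = dataclasses.replace(small_config, effect_logfc=0.0)
        ann = generate_annotation(cfg)
        counts, samples, truth = generate_expression_counts(ann, cfg)
        assert (truth.genes["archetype"] == "none").all()
        for ct in cfg.cell_types:
            assert (truth.genes[f"de_{ct}"] == "none").all()

    def test_counts_nonnegative_integers(self, small_sim):
        values = small_sim.rna_counts.to_numpy()
        assert (values >= 0).all()
        assert np.issubdtype(values.dtype, np.integer)

    def test_planted_fold_change_monte_carlo(self):
        """Planted 4-fold genes show an empirical SLE/control mean ratio in
        [2, 8] in >= 90% of seeds (the generator's documented power)."""
        hits = total = 0
        for seed in range(200):
            cfg = SimulationConfig(seed=seed, n_genes=12, n_chromosomes=1,
                                   chrom_length=40_000, frac_shared_de=0.5,
                                   frac_cellspecific_de=0.0, effect_logfc=2.0)
            ann = generate_annotation(cfg)
            counts, samples, truth = generate_expression_counts(ann, cfg)
            up = truth.genes.loc[truth.genes["archetype"] == "shared_up", "gene_id"]
            if up.empty:
                continue
            meta = samples.set_index("sample_id")
            ct = cfg.cell_types[0]
            cols_c = meta[(meta.cell_type == ct) & (meta.group == "control")].index
            cols_s = meta[(meta.cell_type == ct) & (meta.group == "sle")].index
            g = up.iloc[0]
            ratio = counts.loc[g, cols_s].mean() / max(counts.loc[g, cols_c].mean(), 1e-9)
            total += 1
            hits += 2.0 <= ratio <= 8.0
        assert total >= 150
        assert hits / total >= 0.9


class TestChipReads:
    def test_degenerate_weights_all_inactive(self, small_config):
        cfg = dataclasses.replace(small_config, trimodal_weights=(1.0, 0.0, 0.0),
                                  trimodal_means=(1.0, 3.0, 5.0))
        ann = generate_annotation(cfg)
        _, _, truth = generate_chip_reads(ann, cfg)
        assert (truth.genes["promoter_state"] == "inactive").all()

    def test_poised_enrichment_of_planted_changes(self):
        cfg = SimulationConfig(seed=3, n_genes=2000, poised_change_odds=3.0)
        ann = generate_annotation(cfg)
        _, _, truth = generate_chip_reads(ann, cfg)
        tg = truth.genes
        changed = (tg[[f"chip_{ct}" for ct in cfg.cell_types]] != "none").any(axis=1)
        rate = changed.groupby(tg["promoter_state"]).mean()
        assert rate["poised"] >= 2.0 * rate["active"]
        assert rate["poised"] >= 2.0 * rate["inactive"]

    def test_trimodal_depth_recovered_by_mixture_fit(self):
        """Per-promoter mean log2 depth reproduces the three planted modes."""
        cfg = SimulationConfig(seed=9, n_genes=2000, n_per_group=2,
                               trimodal_means=(1.0, 4.0, 7.0),
                               trimodal_sds=(0.7, 0.7, 0.7),
                               frac_chip_change=0.0, chip_decoy_fraction=0.0)
        ann = generate_annotation(cfg)
        reads, samples, truth = generate_chip_reads(ann, cfg)
        meta = samples.set_index("sample_id")
        ct = cfg.cell_types[0]
        controls = meta[(meta.cell_type == ct) & (meta.group == "control")].index
        from epiconcord.quantify import count_promoter_reads, make_promoter_windows
        wins = make_promoter_windows(ann)
        mat = count_promoter_reads({s: reads[s] for s in controls}, wins)
        mean_log2 = np.log2(mat + 1).mean(axis=1)
        fit = fit_three_component_mixture(mean_log2.to_numpy(), seed=1)
        # oracle: the same observation chain (promoter-level normal depth,
        # per-sample lognormal noise, Poisson counts, log2(n+1)) simulated
        # directly per planted state
        oracle_rng = np.random.default_rng(99)
        expected = []
        for m in cfg.trimodal_means:
            b = oracle_rng.normal(m, cfg.trimodal_sds[0], size=20_000)
            obs = np.zeros_like(b)
            for _ in range(cfg.n_per_group):
                lam = 2.0 ** (b + oracle_rng.normal(0, cfg.chip_sample_sd, b.size))
                obs += np.log2(oracle_rng.poisson(lam) + 1.0)
            expected.append((obs / cfg.n_per_group).mean())
        np.testing.assert_allclose(fit.means, expected, atol=0.2)


class TestSNPTable:
    def test_all_proximal_within_10kb_of_down_gene(self, small_config):
        cfg = dataclasses.replace(small_config, snp_proximal_fraction=1.0)
        ann = generate_annotation(cfg)
        _, _, truth = generate_expression_counts(ann, cfg)
        snps, truth = generate_snp_table(ann, truth, cfg)
        down = truth.genes.loc[
            (truth.genes[[f"de_{ct}" for ct in cfg.cell_types]] == "down").any(axis=1)]
        down_ann = ann.merge(down[["gene_id"]], on="gene_id")
        for _, s in snps.iterrows():
            d = np.abs(down_ann.loc[down_ann["chrom"] == s["chrom"], "tss"] - s["pos"])
            assert len(d) and d.min() <= 10_000

    def test_requires_down_genes_when_proximal(self, small_config):
        cfg = dataclasses.replace(small_config, effect_logfc=0.0,
                                  snp_proximal_fraction=0.5)
        ann = generate_annotation(cfg)
        _, _, truth = generate_expression_counts(ann, cfg)
        with pytest.raises(ValueError, match="downregulated"):
            generate_snp_table(ann, truth, cfg)

    def test_uniform_placement_matches_uniform_null(self, small_config):
        cfg = dataclasses.replace(small_config, snp_proximal_fraction=0.0,
                                  snp_count=400)
        ann = generate_annotation(cfg)
        _, _, truth = generate_expression_counts(ann, cfg)
        snps, _ = generate_snp_table(ann, truth, cfg)

        def mean_nearest(positions, chroms):
            dists = []
            for c, p in zip(chroms, positions):
                tss = ann.loc[ann["chrom"] == c, "tss"].to_numpy()
                dists.append(np.abs(tss - p).min())
            return np.mean(dists)

        observed = mean_nearest(snps["pos"], snps["chrom"])
        rng = np.random.default_rng(0)
        null = [mean_nearest(rng.integers(0, cfg.chrom_length, size=len(snps)),
                             rng.choice(ann["chrom"].unique(), size=len(snps)))
                for _ in range(100)]
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= observed <= hi

    def test_every_snp_labelled_and_p_in_range(self, small_sim):
        snps = small_sim.snps
        assert (snps["set_label"].str.len() > 0).all()
        assert ((snps["pvalue"] > 0) & (snps["pvalue"] <= 1)).all()


class TestStudyRoundTrip:
    def test_fixed_seed_reproducible(self, small_config):
        a = simulate_study(small_config)
        b = simulate_study(small_config)
        pd.testing.assert_frame_equal(a.rna_counts, b.rna_counts)
        pd.testing.assert_frame_equal(a.snps, b.snps)
        first = sorted(a.chip_reads)[0]
        pd.testing.assert_frame_equal(a.chip_reads[first], b.chip_reads[first])
        assert a.sequences == b.sequences

    def test_files_round_trip_losslessly(self, small_config, tmp_path):
        sim = simulate_study(small_config, outdir=tmp_path)
        ann = eio.read_annotation(sim.paths["annotation"])
        pd.testing.assert_frame_equal(ann, sim.annotation)
        counts = eio.read_matrix(sim.paths["rna_counts"])
        pd.testing.assert_frame_equal(counts, sim.rna_counts, check_names=False)
        seqs = eio.read_fasta(sim.paths["promoters"])
        assert seqs == sim.sequences
        snps = eio.read_snp_table(sim.paths["snps"])
        pd.testing.assert_frame_equal(snps, sim.snps)
        sample = sorted(sim.chip_reads)[0]
        reads = eio.read_reads(sim.paths["reads"][sample])
        orig = sim.chip_reads[sample].reset_index(drop=True)
        pd.testing.assert_frame_equal(reads[["chrom", "start", "end", "strand"]],
                                      orig[["chrom", "start", "end", "strand"]])


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"trimodal_weights": (0.5, 0.5, 0.1)},
        {"n_per_group": 1},
        {"nb_dispersion": -0.1},
        {"gc_low": 0.0},
        {"snp_count": 0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
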