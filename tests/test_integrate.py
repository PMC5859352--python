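"""PCA, sharing odds, profile clustering and overlap tests."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from epiconcord.integrate import (ClusterAssignment, cluster_gene_profiles,
                                  cluster_overlap_exact,
                                  cross_celltype_sharing_odds,
                                  principal_components, rna_chip_concordance)
from epiconcord.states import fisher_exact_2x2

CELL_TYPES = ("Bcell", "Tcell", "Monocyte")


def _sample_table(n_per_group=4, assay="rna"):
    rows = []
    for ct in CELL_TYPES:
        for grp in ("control", "sle"):
            for r in range(1, n_per_group + 1):
                rows.append((f"{assay}_{ct}_{grp}{r}", ct, grp, assay))
    return pd.DataFrame(rows, columns=["sample_id", "cell_type", "group", "assay"])


def _archetype_matrix(n_per_arch=40, noise=0.2, seed=0):
    """Genes drawn from 8 direction archetypes (2 shared + 6 cell-specific)."""
    rng = np.random.default_rng(seed)
    samples = _sample_table()
    archs = ["shared_up", "shared_down"] + \
        [f"{ct}_{d}" for ct in CELL_TYPES for d in ("up", "down")]
    rows, truth = [], []
    for arch in archs:
        for i in range(n_per_arch):
            base = rng.normal(7, 1)
            vals = {}
            for _, s in samples.iterrows():
                delta = 0.0
                if arch.startswith("shared"):
                    delta = 2.0 if arch.endswith("up") else -2.0
                else:
                    ct, d = arch.rsplit("_", 1)
                    if s["cell_type"] == ct:
                        delta = 2.0 if d == "up" else -2.0
                v = base + (delta if s["group"] == "sle" else 0.0)
                vals[s["sample_id"]] = v + rng.normal(0, noise)
            rows.append(vals)
            truth.append(arch)
    mat = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
    return mat, pd.Series(truth, index=mat.index), samples


class TestPCA:
    def test_planted_one_dimensional_structure(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(200, 5))
        b = rng.normal(10, 0.1, size=(200, 5))
        mat = pd.DataFrame(np.hstack([a, b]),
                           columns=[f"s{i}" for i in range(10)])
        coords, frac = principal_components(mat, 3)
        assert frac[0] > 0.9
        assert (np.diff(frac) <= 1e-12).all()

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(50, 8)),
                           columns=[f"s{i}" for i in range(8)])
        from sklearn.decomposition import PCA
        x = mat.to_numpy().T
        pca = PCA().fit(x)
        recon = pca.inverse_transform(pca.transform(x))
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_constant_matrix_rejected(self):
        mat = pd.DataFrame(np.ones((20, 4)), columns=list("abcd"))
        with pytest.raises(ValueError):
            principal_components(mat, 2)


class TestSharingOdds:
    def _universe(self, n=10_000):
        return [f"g{i}" for i in range(n)]

    def test_identical_lists_capped_or(self):
        uni = self._universe(1000)
        de = {"A": {"up": set(uni[:50]), "down": set(uni[50:100])},
              "B": {"up": set(uni[:50]), "down": set(uni[50:100])}}
        frame, summary = cross_celltype_sharing_odds(de, uni)
        same = frame[frame["kind"] == "same"]
        assert (same["odds_ratio"] == 1e6).all()

    def test_planted_sharing_strong_odds(self):
        rng = np.random.default_rng(2)
        uni = self._universe()
        de_a_up = set(rng.choice(uni, 500, replace=False))
        shared = set(list(de_a_up)[:250])
        de_b_up = shared | set(rng.choice(uni, 250, replace=False))
        de = {"A": {"up": de_a_up, "down": set(rng.choice(uni, 100, replace=False))},
              "B": {"up": de_b_up, "down": set(rng.choice(uni, 100, replace=False))}}
        frame, summary = cross_celltype_sharing_odds(de, uni)
        row = frame[(frame.cell_a == "A") & (frame.cell_b == "B") &
                    (frame.dir_a == "up") & (frame.dir_b == "up")].iloc[0]
        assert row["odds_ratio"] > 5
        assert row["pvalue"] < 1e-10

    def test_null_lists_odds_near_one(self):
        rng = np.random.default_rng(3)
        uni = self._universe(4000)
        medians = []
        for rep in range(100):
            lists = {}
            for ct in ("A", "B"):
                picks = rng.choice(uni, 400, replace=False)
                lists[ct] = {"up": set(picks[:200]), "down": set(picks[200:])}
            frame, _ = cross_celltype_sharing_odds(lists, uni)
            medians.append(frame.loc[frame["kind"] == "same", "odds_ratio"].median())
        assert 0.8 <= float(np.median(medians)) <= 1.25

    def test_symmetry_under_pair_reversal(self):
        rng = np.random.default_rng(4)
        uni = self._universe(2000)
        de = {ct: {"up": set(rng.choice(uni, 80, replace=False)),
                   "down": set(rng.choice(uni, 80, replace=False))}
              for ct in ("A", "B")}
        frame, _ = cross_celltype_sharing_odds(de, uni)
        ab = frame[(frame.cell_a == "A") & (frame.dir_a == "up") &
                   (frame.dir_b == "up")].iloc[0]
        ba = frame[(frame.cell_a == "B") & (frame.dir_a == "up") &
                   (frame.dir_b == "up")].iloc[0]
        assert ab["odds_ratio"] == pytest.approx(ba["odds_ratio"])
        assert ab["pvalue"] == pytest.approx(ba["pvalue"])

    def test_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            cross_celltype_sharing_odds(
                {"A": {"up": {"zz"}, "down": set()}}, ["g1"])


class TestClustering:
    def test_separated_archetypes_fully_recovered(self):
        mat, truth, samples = _archetype_matrix(noise=0.05)
        ca = cluster_gene_profiles(mat, samples, list(mat.index), k=8, seed=0)
        assert adjusted_rand_score(truth.loc[ca.labels.index], ca.labels) == 1.0

    def test_deterministic_under_seed(self):
        mat, truth, samples = _archetype_matrix(noise=0.3, seed=5)
        a = cluster_gene_profiles(mat, samples, list(mat.index), k=8, seed=3)
        b = cluster_gene_profiles(mat, samples, list(mat.index), k=8, seed=3)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_labels_ordered_by_descending_size(self):
        mat, truth, samples = _archetype_matrix(noise=0.3, seed=6)
        ca = cluster_gene_profiles(mat, samples, list(mat.index), k=8, seed=1)
        sizes = ca.sizes.to_numpy()
        assert (np.diff(sizes) <= 0).all()

    def test_concordant_clusters_and_share(self):
        # shared archetypes hold 55% of the genes: 2 concordant clusters
        mat, truth, samples = _archetype_matrix(n_per_arch=20, noise=0.1, seed=7)
        shared_extra, _, _ = _archetype_matrix(n_per_arch=29, noise=0.1, seed=8)
        shared_ids = truth.index[truth.isin(["shared_up", "shared_down"])]
        # build a 55%-shared gene pool: 40 shared + 120 specific -> add more shared
        reps = []
        base_shared = mat.loc[shared_ids]
        for i in range(3):
            block = base_shared.copy()
            block.index = [f"{g}_r{i}" for g in base_shared.index]
            reps.append(block)
        mat2 = pd.concat([mat] + reps)
        truth2 = pd.concat([truth] + [
            pd.Series(truth.loc[shared_ids].to_numpy(),
                      index=[f"{g}_r{i}" for g in shared_ids]) for i in range(3)])
        ca = cluster_gene_profiles(mat2, samples, list(mat2.index), k=8, seed=2)
        planted_share = truth2.isin(["shared_up", "shared_down"]).mean()
        assert abs(ca.concordant_share() - planted_share) <= 0.05
        assert len(ca.concordant_clusters) == 2

    def test_too_few_genes_rejected(self):
        mat, truth, samples = _archetype_matrix(n_per_arch=1)
        with pytest.raises(ValueError):
            cluster_gene_profiles(mat, samples, list(mat.index[:5]), k=8, seed=0)


class TestClusterOverlap:
    def _assignment(self, labels, index):
        return ClusterAssignment(labels=pd.Series(labels, index=index, name="cluster"),
                                 k=len(set(labels)), inertia=0.0, seed=0,
                                 profiles=pd.DataFrame(index=index))

    def test_identical_clusterings_diagonal(self):
        rng = np.random.default_rng(9)
        idx = [f"g{i}" for i in range(400)]
        labels = rng.integers(1, 5, size=400)
        a = self._assignment(labels, idx)
        b = self._assignment(labels, idx)
        grid = cluster_overlap_exact(a, b)
        diag = grid[grid.cluster_a == grid.cluster_b]
        off = grid[grid.cluster_a != grid.cluster_b]
        assert (diag["odds_ratio"] > 1).all()
        assert (off["odds_ratio"] <= 1).all()

    def test_matches_fisher_cell_by_cell(self):
        rng = np.random.default_rng(10)
        idx = [f"g{i}" for i in range(300)]
        a = self._assignment(rng.integers(1, 4, size=300), idx)
        b = self._assignment(rng.integers(1, 4, size=300), idx)
        grid = cluster_overlap_exact(a, b)
        for _, row in grid.iterrows():
            odds, p = fisher_exact_2x2([[row["both"], row["a_only"]],
                                        [row["b_only"], row["neither"]]])
            assert row["odds_ratio"] == pytest.approx(odds)
            assert row["pvalue"] == pytest.approx(p)

    def test_independent_clusterings_calibrated(self):
        rng = np.random.default_rng(11)
        idx = [f"g{i}" for i in range(300)]
        sig_frac = []
        for rep in range(100):
            a = self._assignment(rng.integers(1, 5, size=300), idx)
            b = self._assignment(rng.integers(1, 5, size=300), idx)
            grid = cluster_overlap_exact(a, b)
            sig_frac.append((grid["fdr"] < 0.05).mean())
        assert float(np.mean(sig_frac)) <= 0.05


class TestRnaChipConcordance:
    def test_planted_concordant_fraction_recovered(self):
        rng = np.random.default_rng(12)
        uni = [f"g{i}" for i in range(8000)]
        rna_up = set(rng.choice(uni, 400, replace=False))
        rna_down = set(rng.choice([g for g in uni if g not in rna_up], 400,
                                  replace=False))
        # 30% of differential genes get a same-direction chromatin change
        chip_up = set(list(rna_up)[:120]) | set(rng.choice(uni, 200, replace=False))
        chip_down = set(list(rna_down)[:120]) | set(rng.choice(uni, 200, replace=False))
        chip_up -= rna_down
        chip_down -= rna_up | chip_up
        de_rna = {"Bcell": {"up": rna_up, "down": rna_down}}
        de_chip = {"Bcell": {"up": chip_up, "down": chip_down}}
        table = rna_chip_concordance(de_rna, de_chip, uni)
        frac = table["frac_concordant"].iloc[0]
        assert abs(frac - 0.30) <= 0.05
        same = table[table["kind"] == "same"]
        assert (same["odds_ratio"] > 1).all()

    def test_disjoint_sets_not_positively_associated(self):
        uni = [f"g{i}" for i in range(1000)]
        de_rna = {"Bcell": {"up": set(uni[:100]), "down": set(uni[100:200])}}
        de_chip = {"Bcell": {"up": set(uni[200:300]), "down": set(uni[300:400])}}
        table = rna_chip_concordance(de_rna, de_chip, uni)
        same = table[table["kind"] == "same"]
        assert ((same["odds_ratio"] < 1) | (same["pvalue"] >= 0.05)).all()
        assert table["frac_concordant"].iloc[0] == 0.0
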