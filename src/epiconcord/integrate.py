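"""Cross-cell-type and cross-assay synthesis.

PCA overviews of normalized matrices, direction-stratified sharing odds
between cell types, k-means clustering of differential genes into profile
archetypes (the eight-cluster view), exact-test overlap of RNA- and
ChIP-derived clusterings, and RNA-vs-H3K4me3 concordance within each cell
type. Every 2x2 test delegates to the single oracle-tested
:func:`epiconcord.states.fisher_exact_2x2`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .differential import benjamini_hochberg
from .states import fisher_exact_2x2

logger = logging.getLogger(__name__)

OR_CAP = 1e6  # reported in place of an infinite odds ratio (flagged)

# minimum |mean SLE - control difference| (standardized profile units) for a
# cluster to count as moved in a cell type; a bare sign rule would let
# noise flips mislabel cell-specific clusters as concordant
MIN_CONCORDANT_SHIFT = 0.25


def principal_components(matrix: pd.DataFrame, n_components: int):
    """PCA of samples on centered features.

    ``matrix`` is features x samples; returns (coordinates, variance
    fractions) with samples as rows of the coordinate frame.
    """
    x = matrix.to_numpy(dtype=float).T  # samples x features
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds min(samples, features)")
    if np.allclose(x.std(axis=0), 0.0):
        raise ValueError("constant matrix has no principal components")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(x)
    frame = pd.DataFrame(coords, index=matrix.columns,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    return frame, pca.explained_variance_ratio_


# ---------------------------------------------------------------------------
# sharing odds


def _pair_table(set_a: set, set_b: set, universe: set) -> list[list[int]]:
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    return [[a, b], [c, d]]


def _table_or_p(set_a, set_b, universe):
    table = _pair_table(set_a, set_b, universe)
    (a, b), (c, d) = table
    if b == 0 and c == 0 and a > 0:
        # identical non-empty lists: infinite association, cap and flag
        logger.warning("sharing odds: perfect overlap, odds ratio capped at %g", OR_CAP)
        _, p = fisher_exact_2x2(table)
        return OR_CAP, p, table
    odds, p = fisher_exact_2x2(table)
    return min(odds, OR_CAP), p, table


def cross_celltype_sharing_odds(de_lists: dict, universe) -> tuple[pd.DataFrame, dict]:
    """Direction-stratified sharing of differential genes between cell types.

    ``de_lists`` maps cell type -> {"up": set, "down": set}. For each
    ordered pair (A, B) the same-direction tables pair up(A) with up(B) and
    down(A) with down(B); opposite-direction tables pair up(A) with down(B)
    and down(A) with up(B). Returns (per-table frame, summary) where the
    summary holds geometric-mean odds ratios across pairs.
    """
    universe = set(universe)
    for ct, d in de_lists.items():
        for k in ("up", "down"):
            if not set(d[k]) <= universe:
                raise ValueError(f"{ct} {k} list contains genes outside the universe")
    rows = []
    cts = list(de_lists)
    for a_ct in cts:
        for b_ct in cts:
            if a_ct == b_ct:
                continue
            for da, db, kind in (("up", "up", "same"), ("down", "down", "same"),
                                 ("up", "down", "opposite"), ("down", "up", "opposite")):
                sa, sb = set(de_lists[a_ct][da]), set(de_lists[b_ct][db])
                if not sa or not sb:
                    logger.info("sharing odds: empty %s list for %s; pair skipped",
                                da if not sa else db, a_ct if not sa else b_ct)
                    continue
                odds, p, table = _table_or_p(sa, sb, universe)
                (aa, bb), (cc, dd) = table
                rows.append((a_ct, b_ct, da, db, kind, aa, bb, cc, dd, odds, p))
    frame = pd.DataFrame(rows, columns=["cell_a", "cell_b", "dir_a", "dir_b", "kind",
                                        "both", "a_only", "b_only", "neither",
                                        "odds_ratio", "pvalue"])
    summary = {}
    for kind in ("same", "opposite"):
        ors = frame.loc[frame["kind"] == kind, "odds_ratio"]
        ors = ors[(ors > 0) & np.isfinite(ors)]
        summary[f"{kind}_direction_or"] = float(np.exp(np.log(ors).mean())) if len(ors) else np.nan
    return frame, summary


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterAssignment:
    """k-means clusters of gene profiles, labels 1..k by descending size."""

    labels: pd.Series
    k: int
    inertia: float
    seed: int
    profiles: pd.DataFrame
    cluster_means: pd.DataFrame = field(default=None)
    concordant_clusters: list[int] = field(default_factory=list)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def concordant_share(self) -> float:
        """Fraction of clustered genes sitting in concordant clusters."""
        if not len(self.labels):
            return np.nan
        return float(self.labels.isin(self.concordant_clusters).mean())


def gene_profiles(matrix: pd.DataFrame, samples: pd.DataFrame,
                  genes=None) -> pd.DataFrame:
    """Mean log2 value per (cell type, group), row-standardized per gene."""
    sub = matrix if genes is None else matrix.loc[list(genes)]
    cols = {}
    meta = samples.set_index("sample_id")
    for (ct, grp), block in meta.groupby(["cell_type", "group"], sort=True):
        ids = [s for s in block.index if s in sub.columns]
        if ids:
            cols[f"{ct}.{grp}"] = sub[ids].mean(axis=1)
    prof = pd.DataFrame(cols)
    centered = prof.sub(prof.mean(axis=1), axis=0)
    sd = prof.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("gene_profiles: dropped %d constant profiles", dropped)
    return centered.loc[keep].div(sd[keep], axis=0)


def cluster_gene_profiles(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    selected_genes,
    k: int = 8,
    seed: int = 0,
    n_restarts: int = 20,
    method: str = "kmeans",
    min_shift: float = MIN_CONCORDANT_SHIFT,
) -> ClusterAssignment:
    """Cluster selected genes by their standardized (cell type x group)
    profile into ``k`` groups.

    Labels are relabeled 1..k by descending cluster size. A cluster is
    *concordant* when its mean SLE - control difference has the same sign
    and magnitude >= ``min_shift`` in every cell type.
    """
    selected = [g for g in selected_genes if g in matrix.index]
    if len(selected) < k:
        raise ValueError(f"only {len(selected)} selected genes for k={k}")
    profiles = gene_profiles(matrix, samples, selected)
    if profiles.shape[0] < k or len(profiles.drop_duplicates()) < k:
        raise ValueError("fewer distinct profiles than clusters")
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=int(seed))
        raw = km.fit_predict(profiles.to_numpy())
        inertia = float(km.inertia_)
    elif method == "ward":
        from sklearn.cluster import AgglomerativeClustering
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(
            profiles.to_numpy())
        inertia = np.nan
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    # stable relabeling: descending size, ties by lowest member order
    counts = pd.Series(raw).value_counts()
    order = sorted(counts.index, key=lambda c: (-counts[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=profiles.index, name="cluster")

    cell_types = sorted(samples["cell_type"].unique())
    cluster_means = profiles.groupby(labels).mean()
    concordant = []
    for cl, row in cluster_means.iterrows():
        diffs = [row[f"{ct}.sle"] - row[f"{ct}.control"] for ct in cell_types]
        signs = np.sign(diffs)
        if (np.abs(diffs) >= min_shift).all() and len(set(signs)) == 1:
            concordant.append(int(cl))
    return ClusterAssignment(labels=labels, k=k, inertia=inertia, seed=int(seed),
                             profiles=profiles, cluster_means=cluster_means,
                             concordant_clusters=concordant)


def cluster_overlap_exact(
    clusters_a: ClusterAssignment, clusters_b: ClusterAssignment
) -> pd.DataFrame:
    """Fisher OR/p for every (cluster i of A, cluster j of B) membership
    table over the shared gene universe, with BH FDR across the grid."""
    shared = clusters_a.labels.index.intersection(clusters_b.labels.index)
    la = clusters_a.labels.loc[shared]
    lb = clusters_b.labels.loc[shared]
    rows = []
    n = len(shared)
    for i in sorted(la.unique()):
        in_a = la == i
        for j in sorted(lb.unique()):
            in_b = lb == j
            a = int((in_a & in_b).sum())
            b = int((in_a & ~in_b).sum())
            c = int((~in_a & in_b).sum())
            d = n - a - b - c
            odds, p = fisher_exact_2x2([[a, b], [c, d]])
            rows.append((i, j, a, b, c, d, odds, p))
    frame = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "both", "a_only",
                                        "b_only", "neither", "odds_ratio", "pvalue"])
    frame["fdr"] = benjamini_hochberg(frame["pvalue"].to_numpy())
    return frame


def rna_chip_concordance(de_rna: dict, de_chip: dict, universe) -> pd.DataFrame:
    """Within-cell-type direction concordance of RNA and H3K4me3 changes.

    ``de_rna`` / ``de_chip`` map cell type -> {"up": set, "down": set}.
    Per cell type: same-direction and opposite-direction Fisher tables (as
    for cross-cell-type sharing, pairing RNA with ChIP direction), and the
    fraction of differential genes with a same-direction significant ChIP
    change.
    """
    universe = set(universe)
    rows = []
    for ct in de_rna:
        rna, chip = de_rna[ct], de_chip[ct]
        rna_de = set(rna["up"]) | set(rna["down"])
        same = (set(rna["up"]) & set(chip["up"])) | (set(rna["down"]) & set(chip["down"]))
        frac = len(same) / len(rna_de) if rna_de else np.nan
        for kind, pairs in (("same", (("up", "up"), ("down", "down"))),
                            ("opposite", (("up", "down"), ("down", "up")))):
            for dr, dc in pairs:
                sa, sb = set(rna[dr]), set(chip[dc])
                if not sa or not sb:
                    continue
                odds, p, table = _table_or_p(sa, sb, universe)
                (a, b), (c, d) = table
                rows.append((ct, kind, dr, dc, a, b, c, d, odds, p, frac))
    frame = pd.DataFrame(rows, columns=["cell_type", "kind", "rna_dir", "chip_dir",
                                        "both", "rna_only", "chip_only", "neither",
                                        "odds_ratio", "pvalue", "frac_concordant"])
    bad = ~frame["frac_concordant"].between(0, 1) & frame["frac_concordant"].notna()
    if bad.any():
        raise AssertionError("concordant fractions outside [0, 1]")
    return frame


def welch_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t (reference statistic alongside permutation p)."""
    t, p = sp_stats.ttest_ind(values_a, values_b, equal_var=False)
    return float(t), float(p)
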