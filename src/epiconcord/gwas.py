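"""Cross-referencing disease-associated SNPs with expression and chromatin.

SNP sets from several sources are merged by position, mapped to the nearest
gene TSS on the same chromosome, binned by association p-value, and the
RNA or H3K4me3 signal near the variants is contrasted against background
with a label-permutation test. Four contrast modes mirror the analysis
questions: baseline expression, baseline promoter/window H3K4me3, and the
SLE-control change of each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .integrate import welch_t
from . import io as eio

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (1e-8, 1e-5, 1e-3, 1.0)


def merge_snp_sets(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of SNP tables keyed by (chrom, pos).

    Source-set labels are unioned, the association p is the minimum across
    sources, and the first id seen wins on conflicts (logged). Idempotent.
    """
    if not tables:
        raise ValueError("no SNP tables to merge")
    frames = []
    for t in tables:
        f = t.copy()
        f["_labels"] = eio.snp_labels(f)
        frames.append(f)
    merged = pd.concat(frames, ignore_index=True)
    out_rows = []
    for (chrom, pos), block in merged.groupby(["chrom", "pos"], sort=True):
        ids = block["snp_id"].unique()
        if len(ids) > 1:
            logger.warning("merge_snp_sets: conflicting ids %s at %s:%d; keeping %s",
                           list(ids), chrom, pos, ids[0])
        labels = frozenset().union(*block["_labels"])
        out_rows.append((ids[0], chrom, int(pos), float(block["pvalue"].min()),
                         ",".join(sorted(labels))))
    return pd.DataFrame(out_rows, columns=["snp_id", "chrom", "pos", "pvalue",
                                           "set_label"])


@dataclass
class SNPGeneMap:
    """Nearest-TSS assignment: one row per mapped SNP."""

    table: pd.DataFrame  # snp_id, gene_id, distance, tie
    unmapped: list[str]

    def genes(self) -> list[str]:
        return self.table["gene_id"].unique().tolist()


def nearest_tss_map(snps: pd.DataFrame, annotation: pd.DataFrame) -> SNPGeneMap:
    """Map each SNP to the gene with the nearest TSS on its chromosome.

    Exact distance ties go to the lexicographically smallest gene id with
    the tie flag set. SNPs on gene-free chromosomes are reported unmapped.
    """
    rows, unmapped = [], []
    by_chrom = {}
    for chrom, block in annotation.groupby("chrom", sort=False):
        b = block.sort_values(["tss", "gene_id"], kind="mergesort")
        by_chrom[chrom] = (b["tss"].to_numpy(np.int64), b["gene_id"].to_numpy())
    for snp_id, chrom, pos in snps[["snp_id", "chrom", "pos"]].itertuples(index=False):
        if chrom not in by_chrom:
            unmapped.append(snp_id)
            continue
        tss, gids = by_chrom[chrom]
        i = int(np.searchsorted(tss, pos))
        candidates = []
        if i > 0:
            candidates.append((abs(pos - int(tss[i - 1])), gids[i - 1]))
        if i < len(tss):
            candidates.append((abs(int(tss[i]) - pos), gids[i]))
        dmin = min(c[0] for c in candidates)
        winners = sorted(g for dist, g in candidates if dist == dmin)
        rows.append((snp_id, winners[0], int(dmin), len(winners) > 1))
    if unmapped:
        logger.warning("nearest_tss_map: %d SNPs on chromosomes without genes",
                       len(unmapped))
    table = pd.DataFrame(rows, columns=["snp_id", "gene_id", "distance", "tie"])
    return SNPGeneMap(table=table, unmapped=unmapped)


def bin_by_association_p(snps: pd.DataFrame, edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Assign each SNP to one half-open association-p bin.

    ``edges`` are ascending inner edges; bins are [0, e1), [e1, e2), ...,
    with the last bin closed at 1 — a boundary p-value falls in the
    less-significant bin. Adds a ``p_bin`` column; named source sets remain
    available via ``set_label`` and pass through as their own groups.
    """
    edges = tuple(edges)
    if list(edges) != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("bin edges must be strictly increasing")
    p = snps["pvalue"].to_numpy(dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("association p-values must lie in (0, 1]")
    labels = [f"<{edges[0]:g}"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"[{lo:g},{hi:g})")
    idx = np.searchsorted(np.asarray(edges), p, side="right")
    idx = np.minimum(idx, len(labels) - 1)  # p == 1 stays in the last bin
    out = snps.copy()
    out["p_bin"] = pd.Categorical([labels[i] for i in idx], categories=labels,
                                  ordered=True)
    return out


def snp_groups(binned: pd.DataFrame) -> dict[str, list[str]]:
    """SNP ids per p-value bin plus per named source set."""
    groups: dict[str, list[str]] = {}
    for b, block in binned.groupby("p_bin", observed=False, sort=True):
        groups[str(b)] = block["snp_id"].tolist()
    labels = eio.snp_labels(binned)
    for name in sorted(frozenset().union(*labels) if len(labels) else []):
        groups[name] = binned.loc[[name in l for l in labels], "snp_id"].tolist()
    return groups


def proximal_background_contrast(
    values: pd.Series,
    focal_set,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Mean difference between a focal id set and the background, with a
    permutation null.

    delta = mean(values over focal ids) - mean(values elsewhere). The null
    redraws |focal| ids without replacement ``n_perm`` times;
    Z = delta / SD(null deltas) and
    p = (1 + #{|null| >= |delta|}) / (n_perm + 1). A Welch t between focal
    and background values is reported for reference. The same routine
    serves baseline expression, baseline window coverage, and the two
    SLE-control change modes.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    focal = [f for f in focal_set if f in values.index]
    m = len(set(focal))
    if m < 5:
        raise ValueError(f"focal set has only {m} usable ids (need >= 5)")
    v = values.to_numpy(dtype=float)
    n = len(v)
    is_focal = values.index.isin(set(focal))
    total = v.sum()
    focal_sum = v[is_focal].sum()
    if m == n:
        return {"delta": 0.0, "z": np.nan, "p_perm": 1.0, "m": m, "n": n,
                "welch_t": np.nan, "welch_p": np.nan}
    mean_focal = focal_sum / m
    mean_bg = (total - focal_sum) / (n - m)
    delta = mean_focal - mean_bg

    rng = substream(seed, "snp_contrast")
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        s = v[idx].sum()
        null[i] = s / m - (total - s) / (n - m)
    sd = null.std(ddof=0)
    z = delta / sd if sd > 0 else np.nan
    p_perm = (1.0 + np.count_nonzero(np.abs(null) >= abs(delta))) / (n_perm + 1.0)
    wt, wp = welch_t(v[is_focal], v[~is_focal])
    return {"delta": float(delta), "z": float(z) if np.isfinite(z) else np.nan,
            "p_perm": float(p_perm), "m": m, "n": n, "welch_t": wt, "welch_p": wp}
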