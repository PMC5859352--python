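"""Normalization and empirical-Bayes moderated two-group testing.

Count matrices are moved to log2 scale with a pseudocount, normalized
between samples by MA-loess against the row-mean reference, and tested
per feature with a moderated t-statistic: per-feature residual variances
are shrunk toward a prior estimated by moment-matching on log variances
(digamma/trigamma inversion), and the t-statistic gains the prior degrees
of freedom. This is the standard empirical-Bayes construction for small
two-group designs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ModeratedTestParams:
    """Empirical-Bayes hyperparameters: prior df d0 and prior variance s0^2.

    ``d0 = 0`` disables shrinkage (ordinary pooled t); ``d0 = inf`` fixes
    every feature's variance at s0^2 (z-like statistic).
    """

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def log2_with_pseudocount(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(count + pseudocount); rejects negative input."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValueError("counts must be nonnegative")
    return pd.DataFrame(np.log2(values + pseudocount),
                        index=counts.index, columns=counts.columns)


def drop_all_zero(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop features with zero counts in every sample (logged)."""
    keep = (counts.to_numpy() != 0).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d features with all-zero counts", dropped)
    return counts.loc[keep]


def loess_normalize(matrix: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Remove intensity-dependent bias per sample by one MA-loess pass.

    For each sample x: M = x - ref, A = (x + ref)/2 with ref the row-wise
    mean across samples; the loess trend of M on A is subtracted. Samples
    with zero variance are left unchanged with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("loess normalization needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix must be finite")
    ref = values.mean(axis=1)
    out = values.copy()
    for j in range(values.shape[1]):
        x = values[:, j]
        if np.var(x) == 0.0:
            warnings.warn(
                f"sample {matrix.columns[j]!r} has zero variance; left unnormalized",
                RuntimeWarning, stacklevel=2)
            continue
        m = x - ref
        a = (x + ref) / 2.0
        delta = 0.01 * (a.max() - a.min())
        with np.errstate(invalid="ignore", divide="ignore"):  # duplicate-A guard
            fitted = sm_lowess(m, a, frac=span, it=1, delta=delta,
                               return_sorted=False)
        out[:, j] = x - fitted
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# hyperparameter estimation (moment matching on log s^2)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-12 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> ModeratedTestParams:
    """Moment-match (d0, s0^2) from per-feature sample variances.

    Works on z = log s^2, whose mean and excess variance over the
    trigamma(df/2) sampling noise identify the scaled-inverse-chi-square
    prior. Zero variances are excluded from estimation.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return ModeratedTestParams(d0=np.inf, s0_sq=float(np.median(s2[ok])) if ok.any() else 1.0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        half_d0 = _trigamma_inverse(float(evar))
        d0 = 2.0 * half_d0
        s0_sq = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return ModeratedTestParams(d0=d0, s0_sq=s0_sq)


def fit_moderated_t(
    matrix: pd.DataFrame,
    groups,
    group_order: tuple[str, str] = ("control", "sle"),
    params: ModeratedTestParams | None = None,
) -> tuple[pd.DataFrame, ModeratedTestParams]:
    """Per-feature moderated two-group test on a log-scale matrix.

    logFC = mean(second group) - mean(first group) under ``group_order``
    (SLE minus control by default). Residual variances with n - 2 df are
    shrunk toward the moment-matched prior; the statistic
    t = logFC / (s_tilde * sqrt(1/n1 + 1/n2)) is referred to a t
    distribution with d0 + n - 2 df. Pass ``params`` to pin the
    hyperparameters instead of estimating them.

    Features that are constant across all samples are flagged and given
    t = 0, p = 1. Returns (result frame, hyperparameters).
    """
    groups = pd.Series(np.asarray(groups, dtype=object), index=matrix.columns)
    g1, g2 = group_order
    in1 = (groups == g1).to_numpy()
    in2 = (groups == g2).to_numpy()
    n1, n2 = int(in1.sum()), int(in2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >= 2 samples")
    unknown = set(groups) - {g1, g2}
    if unknown:
        raise ValueError(f"unexpected group labels: {sorted(unknown)}")

    x = matrix.to_numpy(dtype=float)
    m1 = x[:, in1].mean(axis=1)
    m2 = x[:, in2].mean(axis=1)
    logfc = m2 - m1
    rss = ((x[:, in1] - m1[:, None]) ** 2).sum(axis=1) + \
          ((x[:, in2] - m2[:, None]) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = rss / df_resid

    if params is None:
        params = estimate_prior(s2, df_resid)
    d0, s0_sq = params.d0, params.s0_sq

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    flagged = x.var(axis=1) == 0.0
    t = np.where(flagged, 0.0, t)
    p = np.where(flagged, 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    result = pd.DataFrame({
        "logFC": logfc,
        "t": t,
        "pvalue": p,
        "fdr": benjamini_hochberg(p),
        "direction": "none",
        "flagged": flagged,
        "s2": s2,
        "s2_tilde": s2_tilde,
    }, index=matrix.index)
    result.index.name = "feature_id"
    return result, params


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_differential(
    result: pd.DataFrame, min_fold: float = 2.0, max_p: float = 0.05
) -> tuple[list[str], list[str]]:
    """Up/down feature lists at |fold| >= min_fold and p < max_p.

    The study-style selection rule: at least ``min_fold``-fold change with unadjusted
    p below ``max_p``. Also records the direction on ``result`` in place.
    """
    if min_fold <= 0 or max_p <= 0:
        raise ValueError("thresholds must be positive")
    lfc_cut = np.log2(min_fold)
    sig = result["pvalue"].to_numpy() < max_p
    up = sig & (result["logFC"].to_numpy() >= lfc_cut)
    down = sig & (result["logFC"].to_numpy() <= -lfc_cut)
    result["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return list(result.index[up]), list(result.index[down])
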