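"""Trimodal promoter-state classification and exact association tests.

Promoter H3K4me3 depth (log2) in resting cells is empirically trimodal:
a low mode of inactive promoters, a high mode of active promoters, and an
intermediate "poised" mode. Each control sample's depths are fit with a
three-component univariate Gaussian mixture by EM; promoters are assigned
by maximum posterior per sample, and only promoters classified unanimously
across control samples keep a consensus state (others are "unclassified").
Association between the baseline state and SLE-related change is tested
with Fisher's exact test on 2x2 tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)

STATES = ("inactive", "poised", "active")
_SD_FLOOR = 1e-6


@dataclass
class MixtureFit:
    """Three-component Gaussian mixture, components sorted by mean."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


def _em_once(x: np.ndarray, mu0, sd0, w0, max_iter: int, tol: float,
             sd_floor: float = _SD_FLOOR):
    mu, sd, w = map(np.array, (mu0, sd0, w0))
    trace: list[float] = []
    degenerate = False
    converged = False
    prev = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = np.log(w)[None, :] + norm.logpdf(x[:, None], mu[None, :], sd[None, :])
        row_ll = logsumexp(logp, axis=1)
        ll = float(row_ll.sum())
        trace.append(ll)
        resp = np.exp(logp - row_ll[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(var)
        if (sd < sd_floor).any():
            degenerate = True
            sd = np.maximum(sd, sd_floor)
        if ll - prev < tol and n_iter > 1:
            converged = True
            break
        prev = ll
    return mu, sd, w, trace, converged, degenerate, n_iter


def fit_three_component_mixture(
    values,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 5,
) -> MixtureFit:
    """EM fit of a 3-component Gaussian mixture to log2 depths.

    The best of ``n_restarts`` seeded restarts is kept (restart 0 starts
    from data quantiles, the rest from random data points); components are
    relabeled ascending by mean so index 0/1/2 = inactive/poised/active.
    Convergence: log-likelihood gain below ``tol``. Component SDs are
    floored at 1e-6 and the fit flagged degenerate if the floor binds.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not np.isfinite(x).all():
        raise ValueError("mixture input must be finite")
    if x.size < 30:
        raise ValueError("need >= 30 values to fit a 3-component mixture")

    overall_sd = max(x.std(), _SD_FLOOR * 10)
    # floor tied to the data spread: a vanishing component SD signals a
    # point-mass singularity whose likelihood would otherwise dominate
    sd_floor = max(_SD_FLOOR, 1e-3 * overall_sd)
    best: MixtureFit | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), r]))
        if r == 0:
            mu0 = np.quantile(x, [1 / 6, 0.5, 5 / 6])
        else:
            mu0 = np.sort(rng.choice(x, size=3, replace=False))
        mu0 = mu0 + rng.normal(0.0, 1e-6, size=3)  # break exact ties
        sd0 = np.full(3, overall_sd / 2)
        w0 = np.full(3, 1 / 3)
        mu, sd, w, trace, converged, degenerate, n_iter = _em_once(
            x, mu0, sd0, w0, max_iter, tol, sd_floor=sd_floor)
        order = np.argsort(mu)
        fit = MixtureFit(means=mu[order], sds=sd[order], weights=w[order],
                         loglik=trace[-1], n_iter=n_iter, converged=converged,
                         loglik_trace=trace, degenerate=degenerate)
        # a degenerate (floored) component inflates the likelihood; prefer
        # proper fits and fall back to a degenerate one only if all are
        if best is None or (fit.loglik > best.loglik and
                            fit.degenerate == best.degenerate) or \
                (best.degenerate and not fit.degenerate):
            best = fit
    assert best is not None
    if best.degenerate:
        logger.warning("mixture fit hit the variance floor (point-mass component)")
    return best


def classify_by_posterior(fit: MixtureFit, values) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-posterior state per value.

    Returns (classes, posteriors); posteriors rows sum to 1. Exact posterior
    ties break toward the lower-mean class (argmax takes the first of the
    ascending-mean components).
    """
    x = np.asarray(values, dtype=float)
    logp = np.log(fit.weights)[None, :] + norm.logpdf(
        x[:, None], fit.means[None, :], fit.sds[None, :])
    post = np.exp(logp - logsumexp(logp, axis=1)[:, None])
    idx = post.argmax(axis=1)
    classes = np.asarray(STATES, dtype=object)[idx]
    return classes, post


def consensus_state(per_sample_classes: Sequence[Sequence[str]] | np.ndarray) -> np.ndarray:
    """Unanimous per-sample class, else "unclassified".

    ``per_sample_classes`` is (n_samples, n_promoters) or a list of equal-
    length per-sample class vectors; needs >= 2 samples. Order-invariant.
    """
    arr = np.asarray(per_sample_classes, dtype=object)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 per-sample class vectors")
    unanimous = (arr == arr[0]).all(axis=0)
    out = np.where(unanimous, arr[0], "unclassified")
    return out.astype(object)


# ---------------------------------------------------------------------------
# Fisher's exact test (probability-mass two-sided rule, exact integers)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test for a 2x2 table [[a, b], [c, d]].

    p sums the hypergeometric probabilities (margins fixed) of every table
    at most as probable as the observed one; computed in exact integer
    arithmetic, so ties at the observed probability are handled without
    floating-point tolerance. The odds ratio is (a*d)/(b*c); if any cell is
    zero the Haldane 0.5 continuity correction is applied and flagged in
    the log.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    if (t == 0).any():
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        logger.debug("fisher_exact_2x2: zero cell, Haldane-corrected OR used")
    else:
        odds = (a * d) / (b * c)

    if n == 0 or r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return float(odds), 1.0

    n_obs = comb(r1, a) * comb(r2, c)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    num = 0
    for k in range(lo, hi + 1):
        nk = comb(r1, k) * comb(r2, c1 - k)
        if nk <= n_obs:
            num += nk
    p = num / comb(n, c1)
    return float(odds), float(min(p, 1.0))


def state_change_association(
    consensus: pd.Series,
    differential: pd.DataFrame,
    direction: str = "either",
    max_p: float = 0.05,
    min_fold: float | None = None,
) -> pd.DataFrame:
    """Per-state 2x2 association between baseline state and SLE change.

    ``consensus`` maps gene -> state; unclassified promoters are excluded.
    A gene counts as "changed" when its moderated-test p is below ``max_p``
    in the requested direction ("up"/"down" by sign of logFC, or "either"),
    optionally with a fold filter. For each state s the table is
    (state == s vs other classified states) x (changed vs not); returns
    one row per state with counts, Fisher OR and p.
    """
    if direction not in ("up", "down", "either"):
        raise ValueError("direction must be 'up', 'down' or 'either'")
    shared = consensus.index.intersection(differential.index)
    cons = consensus.loc[shared]
    diff = differential.loc[shared]
    classified = cons != "unclassified"
    cons = cons[classified]
    diff = diff.loc[cons.index]

    changed = diff["pvalue"].to_numpy() < max_p
    lfc = diff["logFC"].to_numpy()
    if direction == "up":
        changed &= lfc > 0
    elif direction == "down":
        changed &= lfc < 0
    if min_fold is not None:
        changed &= np.abs(lfc) >= np.log2(min_fold)
    if not changed.any():
        logger.warning("state_change_association: no changed genes at the "
                       "configured thresholds; all p = 1")

    rows = []
    states_arr = cons.to_numpy()
    for s in STATES:
        in_state = states_arr == s
        if not in_state.any():
            logger.info("state_change_association: empty state %r skipped", s)
            continue
        a = int((in_state & changed).sum())
        b = int((in_state & ~changed).sum())
        c = int((~in_state & changed).sum())
        d = int((~in_state & ~changed).sum())
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append((s, direction, a, b, c, d, odds, p))
    return pd.DataFrame(rows, columns=["state", "direction", "changed_in_state",
                                       "unchanged_in_state", "changed_other",
                                       "unchanged_other", "odds_ratio", "pvalue"])
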