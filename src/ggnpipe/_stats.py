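"""Shared statistical primitives.

Exact/asymptotic Wilcoxon rank-sum on small per-sample summaries, a robust
profiled-ML random-intercept linear mixed model, vectorised per-gene
rank-sum testing, and log-normalisation helpers used across the pipeline.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "log_normalize",
    "percent",
    "rank_sum_test",
    "ranksum_genes",
    "bh_adjust",
    "RandomInterceptFit",
    "fit_random_intercept",
    "stage_lrt",
]


def log_normalize(X, target_sum: float = 1e4) -> np.ndarray:
    """ln(1 + counts-per-`target_sum`) on a dense copy of ``X``.

    Cells with zero total counts are left at zero.
    """
    X = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
    totals = X.sum(axis=1, keepdims=True).astype(float)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    return np.log1p(X * scale)


def percent(n: int, total: int, ndigits: int = 1) -> float:
    """100*n/total rounded to `ndigits` decimal places."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * n / total, ndigits)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum on per-sample summaries
# ---------------------------------------------------------------------------

_EXACT_MAX_PER_GROUP = 10


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def rank_sum_test(x, y, exact_max: int = _EXACT_MAX_PER_GROUP) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p-value.

    Uses exhaustive enumeration of the conditional permutation distribution
    of the Mann-Whitney U statistic (mid-ranks, so ties are handled exactly)
    whenever both groups have at most `exact_max` observations; otherwise a
    tie-corrected normal approximation with continuity correction.

    Two-sided p = P(|U' - n1*n2/2| >= |U - n1*n2/2|) under random relabeling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    if n1 <= exact_max and n2 <= exact_max:
        dev = abs(u - mu)
        total = 0
        hits = 0
        # enumerate all C(n1+n2, n1) assignments of the pooled mid-ranks
        for idx in itertools.combinations(range(n1 + n2), n1):
            rr = ranks[list(idx)].sum()
            uu = rr - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(uu - mu) >= dev - 1e-9:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Vectorised per-gene rank-sum (normal approximation, tie corrected)
# ---------------------------------------------------------------------------

def ranksum_genes(X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-value per gene (column) between two cell groups.

    Normal approximation with tie correction and continuity correction;
    intended for per-gene DE screens with dozens-to-thousands of cells per
    group. Zero-variance genes get p = 1.
    """
    Xa = X[mask_a]
    Xb = X[mask_b]
    n1, n2 = Xa.shape[0], Xb.shape[0]
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.vstack([Xa, Xb])
    n = n1 + n2
    ranks = stats.rankdata(pooled, method="average", axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene
    tie_term = np.zeros(pooled.shape[1])
    srt = np.sort(pooled, axis=0)
    for g in range(pooled.shape[1]):
        _, counts = np.unique(srt[:, g], return_counts=True)
        tie_term[g] = np.sum(counts.astype(float) ** 3 - counts)
    sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(pooled.shape[1])
    ok = sigma2 > 0
    z = (np.abs(u[ok] - mu) - 0.5) / np.sqrt(sigma2[ok])
    z = np.maximum(z, 0.0)
    p[ok] = 2.0 * stats.norm.sf(z)
    return np.minimum(p, 1.0)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Random-intercept linear mixed model (profiled maximum likelihood)
# ---------------------------------------------------------------------------
#
# Model: y = X beta + b_group + eps, b_group ~ N(0, s2b), eps ~ N(0, s2e).
# With lambda = s2b/s2e, V = s2e*(I + lambda*Z Z') is block diagonal and
# (I + lambda*J)^{-1} = I - lambda/(1+n_g*lambda) * J per group, so the GLS
# solution and the profiled log-likelihood are O(n) per lambda evaluation.
# lambda is optimised on a bounded interval including the boundary 0, which
# makes null (variance-zero) fits well defined rather than singular.


@dataclass
class RandomInterceptFit:
    llf: float
    beta: np.ndarray
    sigma2_e: float
    lam: float  # variance ratio s2b/s2e
    converged: bool


def _gls_pieces(lam: float, y: np.ndarray, X: np.ndarray, groups: list[np.ndarray]):
    p = X.shape[1]
    xtx = np.zeros((p, p))
    xty = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for idx in groups:
        Xg = X[idx]
        yg = y[idx]
        ng = idx.size
        c = lam / (1.0 + ng * lam)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        xtx += Xg.T @ Xg - c * np.outer(sx, sx)
        xty += Xg.T @ yg - c * sx * sy
        yty += yg @ yg - c * sy * sy
        logdet += np.log1p(ng * lam)
    return xtx, xty, yty, logdet


def _profile_nll(lam: float, y, X, groups) -> float:
    n = y.size
    xtx, xty, yty, logdet = _gls_pieces(lam, y, X, groups)
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(xtx, xty, rcond=None)
    rss = yty - 2 * beta @ xty + beta @ xtx @ beta
    rss = max(rss, 1e-300)
    s2 = rss / n
    return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)


def fit_random_intercept(y, X, group_labels) -> RandomInterceptFit:
    """ML fit of y = X beta + (random intercept per group) + noise."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    labels = np.asarray(group_labels)
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    res = None
    try:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            _profile_nll, args=(y, X, groups), bounds=(0.0, 1e4), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(res.x)
        # the bounded optimiser never probes the boundary exactly
        if _profile_nll(0.0, y, X, groups) <= res.fun:
            lam = 0.0
        converged = bool(res.success)
    except Exception:
        lam, converged = 0.0, False
    nll = _profile_nll(lam, y, X, groups)
    xtx, xty, yty, _ = _gls_pieces(lam, y, X, groups)
    try:
        beta = np.linalg.solve(xtx, xty)
    except np.linalg.LinAlgError:
        beta, *_ = np.linalg.lstsq(xtx, xty, rcond=None)
    rss = max(yty - 2 * beta @ xty + beta @ xtx @ beta, 1e-300)
    return RandomInterceptFit(
        llf=-nll, beta=beta, sigma2_e=rss / y.size, lam=lam, converged=converged
    )


def stage_lrt(y, stage, sample) -> tuple[float, float, bool]:
    """Likelihood-ratio test for an ordinal stage effect with sample random
    intercepts.

    Returns (stage coefficient, p-value, ok flag). Degenerate inputs
    (zero-variance gene, failed fit) give p = 1 with ok=False rather than
    raising.
    """
    y = np.asarray(y, dtype=float)
    stage = np.asarray(stage, dtype=float)
    if np.ptp(y) == 0:
        return 0.0, 1.0, False
    X1 = np.column_stack([np.ones_like(stage), stage])
    X0 = np.ones((y.size, 1))
    try:
        full = fit_random_intercept(y, X1, sample)
        null = fit_random_intercept(y, X0, sample)
        lr = max(2.0 * (full.llf - null.llf), 0.0)
        p = float(stats.chi2.sf(lr, df=1))
        return float(full.beta[1]), p, True
    except Exception:
        return 0.0, 1.0, False
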