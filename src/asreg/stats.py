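"""Shared statistical engines.

Small wrappers that pin down the exact conventions used throughout the
package: two-sided Wilcoxon rank-sum with an exact null for small samples,
probability-based two-sided Fisher's exact test with a conditional-MLE odds
ratio, Spearman correlation with an exact permutation p-value at small n,
and a Tukey-bisquare IRLS line fit with an LAD fallback.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.api import OLS, QuantReg, RLM, add_constant
from statsmodels.robust.norms import TukeyBiweight

EXACT_RANKSUM_MAX_N = 20
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    method: str  # "exact" or "normal"
    median_x: float
    median_y: float


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample size is at most 20 and
    the data carry no ties; otherwise the normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires two non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal"
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return RankSumResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        median_x=float(np.median(x)),
        median_y=float(np.median(y)),
    )


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # conditional maximum-likelihood estimate
    p_value: float


def fisher_exact_test(table) -> FisherResult:
    """Probability-based two-sided Fisher's exact test on a 2x2 table.

    p sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table cells must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    or_cmle = sps.contingency.odds_ratio(t, kind="conditional").statistic
    return FisherResult(odds_ratio=float(or_cmle), p_value=float(p))


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact-permutation" or "t-approx"


def _rank_average(v: np.ndarray) -> np.ndarray:
    return sps.rankdata(v, method="average")


def spearman_correlation(x, y) -> SpearmanResult:
    """Spearman rho with average-rank ties.

    Two-sided p from full permutation enumeration for n <= 9, else from the
    usual t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: Spearman correlation undefined")
    rx = _rank_average(x)
    ry = _rank_average(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        rho_null = (ry_c[perms] * rx_c).sum(axis=1) / denom
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
        return SpearmanResult(rho=rho, p_value=p, n=n, method="exact-permutation")
    res = sps.spearmanr(x, y)
    return SpearmanResult(rho=rho, p_value=float(res.pvalue), n=n, method="t-approx")


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    method: str  # "irls-tukey" or "lad"
    weights: np.ndarray

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def irls_line(x, y, *, tuning: float = 4.685, tol: float = 1e-8, maxiter: int = 50) -> TrendFit:
    """Robust straight-line fit by IRLS with Tukey bisquare weights.

    Falls back to a least-absolute-deviation fit (flagged in ``method``)
    if the IRLS iterations do not converge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points for a robust trend fit")
    X = add_constant(x)
    try:
        fit = RLM(y, X, M=TukeyBiweight(c=tuning)).fit(
            maxiter=maxiter, tol=tol, conv="coefs"
        )
        converged = getattr(fit, "fit_history", {}).get("iteration", maxiter) < maxiter
        if not np.all(np.isfinite(fit.params)):
            converged = False
    except Exception:
        converged = False
        fit = None
    if converged:
        return TrendFit(
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            method="irls-tukey",
            weights=np.asarray(fit.weights, dtype=float),
        )
    lad = QuantReg(y, X).fit(q=0.5)
    return TrendFit(
        slope=float(lad.params[1]),
        intercept=float(lad.params[0]),
        method="lad",
        weights=np.ones_like(x),
    )


def ols_line(x, y) -> TrendFit:
    """Plain least-squares line, used as the robust fit's cross-check."""
    x = np.asarray(x, dtype=float)
    fit = OLS(np.asarray(y, dtype=float), add_constant(x)).fit()
    return TrendFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        method="ols",
        weights=np.ones_like(x),
    )
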