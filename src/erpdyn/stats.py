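"""Nonparametric group statistics, multiple-testing control, correlations,
contingency tests and the a priori ANOVA power computation.

Kruskal-Wallis, Pearson correlation and the chi-square test delegate to
scipy; Dunn's post hoc z tests with Sidak adjustment, Benjamini-Hochberg
FDR, partial correlation and the noncentral-F sample-size search are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import InvalidArgumentError


@dataclass
class PairwiseComparison:
    pair: Tuple[int, int]
    z: float
    p: float
    p_adjusted: float


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    group_sizes: Optional[Tuple[int, ...]] = None
    pairwise: Optional[List[PairwiseComparison]] = None


def kruskal_wallis(groups: Sequence[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H test with tie correction; chi-square p, df = k - 1."""
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise InvalidArgumentError("need >= 2 groups, each with >= 1 observation")
    n_total = sum(len(g) for g in groups)
    if n_total < 3:
        raise InvalidArgumentError("need >= 3 observations in total")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all observations identical; returning p = 1", stacklevel=2)
        return TestResult(0.0, df, 1.0, tuple(len(g) for g in groups))
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), df, float(p), tuple(len(g) for g in groups))


def dunn_sidak(groups: Sequence[np.ndarray]) -> List[PairwiseComparison]:
    """Dunn's rank-based pairwise z tests with Sidak family-wise adjustment.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)), with
    tie correction T = sum(t^3 - t) / (12 (N - 1)); Sidak-adjusted
    p_adj = 1 - (1 - p)^m over the m = C(k, 2) comparisons, capped at 1.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise InvalidArgumentError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se < 1e-300:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, 1.0 - (1.0 - p) ** m)
        out.append(PairwiseComparison((i, j), float(z), float(p), float(p_adj)))
    return out


def kw_dunn(groups: Sequence[np.ndarray]) -> TestResult:
    """Kruskal-Wallis omnibus test bundled with Dunn-Sidak post hoc pairs."""
    res = kruskal_wallis(groups)
    res.pairwise = dunn_sidak(groups)
    return res


def fdr_bh(pvalues: Sequence[float], q: float = 0.05) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected flags, adjusted p-values).

    Adjusted p_(i) = min over j >= i of m * p_(j) / j (monotone, capped at 1);
    rejection iff adjusted p <= q.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must be finite and in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted <= q, adjusted


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r with the two-sided t-test p-value (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InvalidArgumentError("x and y must be equal-length 1-D with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidArgumentError("inputs must be finite")
    if np.std(x) < 1e-300 or np.std(y) < 1e-300:
        raise InvalidArgumentError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def partial_corr(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualised against the covariates (plus intercept)
    by least squares; p comes from the t distribution with
    df = n - 2 - n_covariates.  With no covariates this is pearson_corr.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        return pearson_corr(x, y)
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n = len(x)
    k = z.shape[1]
    if x.shape != y.shape or z.shape[0] != n:
        raise InvalidArgumentError("shape mismatch")
    if n < 3 + k:
        raise InvalidArgumentError(f"need n >= {3 + k} observations")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) < 1e-300 or np.std(ry) < 1e-300:
        raise InvalidArgumentError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clipped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clipped * np.sqrt(df / (1.0 - r_clipped**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def chi_square_contingency(table: np.ndarray, yates_2x2: bool = False) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction by
    default); df = (rows - 1)(cols - 1)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise InvalidArgumentError("table must be at least 2x2")
    if np.any(table < 0):
        raise InvalidArgumentError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InvalidArgumentError("zero marginal in contingency table")
    if yates_2x2 and table.shape != (2, 2):
        raise InvalidArgumentError("continuity correction applies to 2x2 tables only")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=yates_2x2)
    return TestResult(float(chi2), float(df), float(p))


def anova_power(n_total: int, f: float, alpha: float, k_groups: int) -> float:
    """Power of the one-way fixed-effects F test at total sample size n_total.

    Noncentrality lambda = f^2 * N, df1 = k - 1, df2 = N - k.
    """
    df1 = k_groups - 1
    df2 = n_total - k_groups
    if df2 < 1:
        return 0.0
    lam = f * f * n_total
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def anova_required_n(
    f: float,
    alpha: float = 0.05,
    power: float = 0.80,
    k_groups: int = 3,
    balanced: bool = True,
    max_n: int = 10**6,
) -> int:
    """Smallest total N reaching the target power for a one-way ANOVA.

    With ``balanced=True`` (default) the search walks multiples of k_groups,
    matching the equal-group-size designs produced by standard power
    software; ``balanced=False`` walks every integer N.
    """
    if f <= 0:
        raise InvalidArgumentError("effect size f must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise InvalidArgumentError("alpha and power must be in (0, 1)")
    if k_groups < 2:
        raise InvalidArgumentError("need k >= 2 groups")
    step = k_groups if balanced else 1
    n = k_groups + 2
    if balanced:
        n = ((n + k_groups - 1) // k_groups) * k_groups
    while n <= max_n:
        if anova_power(n, f, alpha, k_groups) >= power:
            return n
        n += step
    raise InvalidArgumentError(f"target power unreachable within N <= {max_n}")
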