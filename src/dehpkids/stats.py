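"""Nonparametric statistical battery for the cohort comparisons.

Two-group contrasts go through a Kolmogorov–Smirnov normality gate (t-test
when both samples look normal, Mann–Whitney otherwise); four-cell contrasts
(group × puberty) use Kruskal–Wallis with pairwise Mann–Whitney post hocs
under Bonferroni correction; associations are Spearman correlations over
pairwise-complete observations; the determinants of MEHP concentration are
assessed by a multiple linear regression with listwise deletion.

The exact small-sample Mann–Whitney p-value is computed here by full
permutation enumeration (it handles ties, unlike the usual exact recursion);
everything asymptotic is delegated to scipy/statsmodels.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _sps

#: Default cap on n_x + n_y for the enumerated exact Mann-Whitney p-value.
EXACT_MW_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # {"t", "mann_whitney", "kruskal_wallis", "ks", "spearman", "ols"}
    n_per_group: tuple[int, ...]
    adjusted: bool = False
    extra: dict = field(default_factory=dict)


def ks_normality(sample: Sequence[float]) -> TestResult:
    """One-sample KS test against a normal fitted to the sample (mean, SD)."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = _sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(float(stat), float(p), "ks", (x.size,))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for the first sample, via midranks (tie-safe)."""
    pooled = np.concatenate([x, y])
    ranks = _sps.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def exact_mann_whitney_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    Two-sided p is the fraction of the C(n_x+n_y, n_x) assignments whose U is
    at least as far from the null mean n_x·n_y/2 as the observed U.  Handles
    ties (midranks) correctly because the permutation distribution conditions
    on the observed pooled values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, n_x = pooled.size, x.size
    ranks = _sps.rankdata(pooled)
    mu = n_x * y.size / 2.0
    u_obs = float(ranks[:n_x].sum() - n_x * (n_x + 1) / 2.0)
    d_obs = abs(u_obs - mu)
    count = total = 0
    offset = n_x * (n_x + 1) / 2.0
    for idx in itertools.combinations(range(n), n_x):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= d_obs - 1e-12:
            count += 1
    return u_obs, count / total


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='auto'`` uses the enumerated exact p when n_x+n_y ≤ 12 and the
    pooled sample is tie-free, otherwise the tie-corrected normal
    approximation (no continuity correction).  ``'exact'`` and
    ``'asymptotic'`` force a branch; the exact branch tolerates ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if mode == "auto":
        mode = "exact" if (pooled.size <= EXACT_MW_MAX_N and tie_free) else "asymptotic"
    if mode == "exact":
        u, p = exact_mann_whitney_p(x, y)
    elif mode == "asymptotic":
        u, p = _sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        u, p = float(u), float(p)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(u, min(p, 1.0), "mann_whitney", (x.size, y.size))


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return min(1.0, p * n_comparisons)


def kruskal_wallis_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with Bonferroni pairwise post hocs.

    Post hocs are pairwise Mann-Whitney tests multiplied by the number of
    pairs; the result's ``extra`` carries ``pairwise`` (label pair → adjusted
    p) and ``significant`` (pairs with adjusted p < alpha, formatted
    "A vs B").
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("Kruskal-Wallis requires at least 3 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    if labels is None:
        labels = [chr(ord("A") + i) for i in range(len(groups))]
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        h, p = 0.0, 1.0
    else:
        h, p = _sps.kruskal(*groups)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for (i, gi), (j, gj) in itertools.combinations(enumerate(groups), 2):
        raw = mann_whitney(gi, gj).p_value
        pairwise[(labels[i], labels[j])] = bonferroni(raw, n_pairs)
    significant = [f"{a} vs {b}" for (a, b), q in pairwise.items() if q < alpha]
    return TestResult(
        float(h),
        float(p),
        "kruskal_wallis",
        tuple(g.size for g in groups),
        adjusted=True,
        extra={"pairwise": pairwise, "significant": significant},
    )


def compare_groups(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> TestResult:
    """Two-group comparison behind a KS normality gate.

    If either sample rejects normality at ``alpha`` the comparison routes to
    Mann-Whitney, otherwise to Welch's t-test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nonparametric = False
    for s in (x, y):
        try:
            if ks_normality(s).p_value < alpha:
                nonparametric = True
        except ValueError:
            nonparametric = True
    if nonparametric:
        return mann_whitney(x, y)
    stat, p = _sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(stat), float(p), "t", (x.size, y.size))


def spearman_matrix(
    table: pd.DataFrame,
    variables: Sequence[str],
    min_pairs: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p matrices over pairwise-complete observations.

    Cells with fewer than ``min_pairs`` complete pairs, or with a constant
    column, are NaN (with a warning for constants).  Matrices are symmetric
    with unit/zero diagonals.
    """
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pval = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, j in itertools.combinations(range(k), 2):
        a, b = variables[i], variables[j]
        pair = table[[a, b]].dropna()
        r = p = math.nan
        if len(pair) >= min_pairs:
            if pair[a].nunique() == 1 or pair[b].nunique() == 1:
                warnings.warn(f"constant column in pair ({a}, {b}); cell missing", stacklevel=2)
            else:
                res = _sps.spearmanr(pair[a], pair[b])
                r, p = float(res.statistic), float(res.pvalue)
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


@dataclass(frozen=True)
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    n_used: int


def ols_regression(
    table: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
) -> RegressionResult:
    """Multiple linear regression with intercept and listwise deletion.

    Rejects rank-deficient designs, naming the collinear columns.
    """
    cols = [response, *predictors]
    data = table[cols].dropna()
    n, p = len(data), len(predictors)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 complete rows; have n={n}, p={p}")
    X = sm.add_constant(data[list(predictors)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = []
        for name in predictors:
            reduced = X.drop(columns=[name]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(data[response].astype(float), X).fit()
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        n_used=n,
    )
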