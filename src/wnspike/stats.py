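"""Nonparametric statistics shared across the analysis modules.

Everything here wraps or thinly extends scipy/statsmodels primitives: the
Spearman permutation test (with a rank-residual partial variant), one-tailed
Mann-Whitney U and paired Wilcoxon tests, the G test of independence, exact
one-tailed binomial tests, and the upper-tail Poisson test.  All empirical
p values are strictly positive (add-one permutation counting), which the
geometric-mean aggregation upstream requires.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from ._core import derive_rng, spearman

__all__ = [
    "rank_corr_perm_test",
    "mannwhitney_one_tailed",
    "wilcoxon_one_tailed",
    "g_test",
    "binomial_one_tailed",
    "poisson_upper_tail",
]


def rank_corr_perm_test(
    x, y, n_perm: int = 1000, seed: int = 0, partial_on=None
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided permutation p value.

    With ``partial_on`` given, the partial rank correlation is used: ranks of
    x and y are each regressed on the covariate's ranks and the correlation
    of the residuals is tested (covariate rows are held fixed under
    permutation of y's residuals).

    p = (1 + #{|cc_perm| >= |cc|}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")

    if partial_on is not None:
        c = rankdata(np.asarray(partial_on, dtype=np.float64))
        A = np.column_stack([np.ones(len(c)), c])
        rx = rankdata(x) - A @ np.linalg.lstsq(A, rankdata(x), rcond=None)[0]
        ry = rankdata(y) - A @ np.linalg.lstsq(A, rankdata(y), rcond=None)[0]
        cc = _pearson(rx, ry)
        rng = derive_rng(seed, 41)
        exceed = 0
        for _ in range(n_perm):
            if abs(_pearson(rx, rng.permutation(ry))) >= abs(cc):
                exceed += 1
        return float(cc), (1.0 + exceed) / (n_perm + 1.0)

    cc = spearman(x, y)
    rng = derive_rng(seed, 41)
    rx = rankdata(x)
    ry = rankdata(y)
    exceed = 0
    for _ in range(n_perm):
        if abs(_pearson(rx, rng.permutation(ry))) >= abs(cc) - 1e-12:
            exceed += 1
    return float(cc), (1.0 + exceed) / (n_perm + 1.0)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def mannwhitney_one_tailed(x, y, alternative: str = "greater") -> tuple[float, float]:
    """One-tailed Mann-Whitney U test (unpaired); exact where scipy permits."""
    x, y = np.asarray(x), np.asarray(y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_one_tailed(x, y=None, alternative: str = "greater") -> tuple[float, float]:
    """One-tailed paired Wilcoxon signed-rank test.

    ``y`` omitted means ``x`` already holds the paired differences.
    All-zero differences are undefined and raise ValueError.
    """
    d = np.asarray(x, dtype=np.float64)
    if y is not None:
        d = d - np.asarray(y, dtype=np.float64)
    if len(d) == 0 or np.all(d == 0):
        raise ValueError("Wilcoxon test undefined for all-zero differences")
    res = stats.wilcoxon(d, alternative=alternative, zero_method="wilcox")
    return float(res.statistic), float(res.pvalue)


def g_test(table) -> tuple[float, float]:
    """G test (log-likelihood ratio) of independence on a contingency table."""
    table = np.asarray(table, dtype=np.float64)
    if np.any(table < 0) or table.sum() == 0:
        raise ValueError("table must be non-negative with a positive total")
    g, p, _, _ = stats.chi2_contingency(table, lambda_="log-likelihood", correction=False)
    return float(g), float(p)


def binomial_one_tailed(k: int, n: int, p: float, alternative: str = "greater") -> float:
    """Exact one-tailed binomial test p value."""
    return float(stats.binomtest(k, n, p, alternative=alternative).pvalue)


def poisson_upper_tail(count: int, expectation: float) -> float:
    """P(X >= count) for X ~ Poisson(expectation)."""
    if expectation < 0:
        raise ValueError("expectation must be non-negative")
    return float(stats.poisson.sf(count - 1, max(expectation, 1e-300)))
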