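"""Inferential layer: group contrasts, fold differences, single-covariate
regressions, all-subsets model search and LMG relative importance.

The LMG decomposition attributes a linear model's R^2 to its predictors by
averaging each predictor's sequential R^2 increase over all orderings in
which it can enter the model.  It is computed here from subset R^2 values
with the combinatorial weights |S|! (p - |S| - 1)! / p!, which is exactly
the all-orderings average without enumerating p! permutations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NumericalError

__all__ = [
    "group_contrast",
    "fold_difference",
    "simple_regression",
    "all_subsets",
    "lmg_importance",
    "RelativeImportanceResult",
    "correlation_matrix",
]


# ---------------------------------------------------------------------------
# Group contrasts and fold differences
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    test: str
    statistic: float
    p_value: float
    group_summaries: dict[str, float]    # group label -> mean or median
    fold_difference: float               # larger summary / smaller summary
    larger_group: str


def group_contrast(values: dict[str, np.ndarray], test: str = "welch_t"
                   ) -> ContrastResult:
    """Compare a quantity between two groups.

    ``welch_t``: Welch's unequal-variance t-test; the fold difference is
    the ratio of group means.  ``wilcoxon``: two-sided Wilcoxon rank-sum
    (Mann-Whitney) test, exact when sample sizes permit; the fold
    difference is the ratio of group medians.
    """
    if len(values) != 2:
        raise DataError(f"need exactly 2 groups, got {len(values)}")
    (name_a, a), (name_b, b) = [(k, np.asarray(v, dtype=float))
                                for k, v in values.items()]
    if len(a) < 2 or len(b) < 2:
        raise DataError("each group needs at least 2 observations")
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        summ = {name_a: float(np.mean(a)), name_b: float(np.mean(b))}
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        summ = {name_a: float(np.median(a)), name_b: float(np.median(b))}
    else:
        raise DataError(f"unknown test {test!r}")
    larger = max(summ, key=summ.get)
    smaller = min(summ, key=summ.get)
    if summ[smaller] == 0:
        fold = float("inf")
    else:
        fold = summ[larger] / summ[smaller]
    return ContrastResult(test=test, statistic=float(res.statistic),
                          p_value=float(res.pvalue), group_summaries=summ,
                          fold_difference=float(fold), larger_group=larger)


def fold_difference(values: dict[str, float] | pd.Series
                    ) -> tuple[float, str, str]:
    """Max/min ratio across labelled positive values; returns
    (ratio, argmax_label, argmin_label)."""
    s = pd.Series(values, dtype=float)
    if (s <= 0).any():
        bad = s.index[s <= 0].tolist()
        raise DataError(f"fold difference needs positive values; "
                        f"non-positive at {bad}")
    return float(s.max() / s.min()), str(s.idxmax()), str(s.idxmin())


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def simple_regression(y, x) -> RegressionResult:
    """Ordinary least squares of y on a single covariate; R^2 is the
    squared Pearson correlation and the p-value the two-sided test of zero
    slope (equivalently the model F-test)."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise DataError("constant covariate")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            p_value=float(res.pvalue), n=len(x))


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...]) -> float:
    """R^2 of the OLS fit of y on the given predictor columns (with
    intercept); least-squares via pseudo-inverse, so perfectly collinear
    designs still return a well-defined fit."""
    n = len(y)
    design = np.column_stack([np.ones(n)] + [X[:, c] for c in cols])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise NumericalError("response is constant")
    return float(1.0 - np.sum(resid ** 2) / tss)


@dataclass
class AllSubsetsResult:
    table: pd.DataFrame                  # subset, k, r2, adj_r2, aic
    best_subset: tuple[str, ...]
    best_r2: float
    best_adj_r2: float
    warnings: list[str] = field(default_factory=list)


def all_subsets(y, predictors: pd.DataFrame) -> AllSubsetsResult:
    """Fit every non-empty predictor subset (2^p - 1 models).

    Best model = highest adjusted R^2, ties broken by fewer predictors and
    then lexicographic subset order.  AIC is the Gaussian-likelihood form
    n ln(RSS/n) + 2(k + 2) (k slopes, plus intercept and error variance).
    Exactly collinear predictor pairs are recorded as warnings; their
    subsets are still fit through the pseudo-inverse.
    """
    y = np.asarray(y, dtype=float)
    names = list(predictors.columns)
    p = len(names)
    if not 1 <= p <= 12:
        raise DataError(f"need 1..12 predictors, got {p}")
    n = len(y)
    if n <= p + 1:
        raise DataError(f"need n > p + 1 observations (n={n}, p={p})")
    X = predictors.to_numpy(dtype=float)

    warnings = []
    for i, j in itertools.combinations(range(p), 2):
        r = np.corrcoef(X[:, i], X[:, j])[0, 1]
        if np.isclose(abs(r), 1.0, atol=1e-12):
            warnings.append(f"predictors {names[i]!r} and {names[j]!r} are "
                            "perfectly collinear")

    tss = np.sum((y - y.mean()) ** 2)
    rows = []
    for k in range(1, p + 1):
        for cols in itertools.combinations(range(p), k):
            r2 = _subset_r2(y, X, cols)
            adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
            rss = max((1.0 - r2) * tss, 1e-300)
            aic = n * np.log(rss / n) + 2 * (k + 2)
            rows.append((tuple(names[c] for c in cols), k, r2, adj, aic))
    table = pd.DataFrame(rows, columns=["subset", "k", "r2", "adj_r2",
                                        "aic"])
    order = sorted(range(len(rows)),
                   key=lambda i: (-rows[i][3], rows[i][1], rows[i][0]))
    best = rows[order[0]]
    return AllSubsetsResult(table=table, best_subset=best[0],
                            best_r2=best[2], best_adj_r2=best[3],
                            warnings=warnings)


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

@dataclass
class RelativeImportanceResult:
    response: str
    predictors: tuple[str, ...]
    full_r2: float
    shares: dict[str, float]             # absolute LMG shares, sum = R^2
    percentages: dict[str, float]        # shares / R^2 * 100


def lmg_importance(y, predictors: pd.DataFrame, response_name: str = "y"
                   ) -> RelativeImportanceResult:
    """LMG decomposition of the full-model R^2 over the given predictors.

    share_k = sum over subsets S not containing k of
    |S|! (p-|S|-1)! / p! * (R^2(S + k) - R^2(S)); shares sum to the
    full-model R^2 and are invariant to predictor input order.
    """
    y = np.asarray(y, dtype=float)
    names = list(predictors.columns)
    p = len(names)
    if not 1 <= p <= 8:
        raise DataError(f"LMG enumeration supports 1..8 predictors, got {p}")
    X = predictors.to_numpy(dtype=float)
    if len(y) <= p + 1:
        raise NumericalError(f"need n > p + 1 observations (n={len(y)}, "
                             f"p={p})")
    if any(np.ptp(X[:, j]) == 0 for j in range(p)):
        raise NumericalError("singular design: constant predictor column")

    fact = [float(math.factorial(i)) for i in range(p + 1)]
    r2_cache: dict[tuple[int, ...], float] = {(): 0.0}
    for k in range(1, p + 1):
        for cols in itertools.combinations(range(p), k):
            r2_cache[cols] = _subset_r2(y, X, cols)

    shares = dict.fromkeys(names, 0.0)
    for k_idx, name in enumerate(names):
        others = [i for i in range(p) if i != k_idx]
        for size in range(p):
            weight = fact[size] * fact[p - size - 1] / fact[p]
            for S in itertools.combinations(others, size):
                with_k = tuple(sorted(S + (k_idx,)))
                shares[name] += weight * (r2_cache[with_k] - r2_cache[S])

    full_r2 = r2_cache[tuple(range(p))]
    total = sum(shares.values())
    percentages = {k: (v / total * 100.0 if total > 0 else float("nan"))
                   for k, v in shares.items()}
    return RelativeImportanceResult(
        response=response_name, predictors=tuple(names), full_r2=full_r2,
        shares=shares, percentages=percentages)


# ---------------------------------------------------------------------------
# Correlation matrix
# ---------------------------------------------------------------------------

def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between numeric columns.

    Constant columns yield NaN entries (flagged in
    ``result.attrs['undefined_columns']`` rather than silently zeroed);
    every pair must share at least 3 complete rows.
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise DataError("need at least 2 numeric columns")
    for a, b in itertools.combinations(num.columns, 2):
        if (num[[a, b]].dropna().shape[0]) < 3:
            raise DataError(f"fewer than 3 complete rows for pair "
                            f"({a}, {b})")
    corr = num.corr(method="pearson", min_periods=3)
    undefined = [c for c in num.columns
                 if num[c].dropna().nunique() <= 1]
    for c in undefined:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    for c in undefined:
        corr.loc[c, c] = np.nan
    corr.attrs["undefined_columns"] = undefined
    return corr
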