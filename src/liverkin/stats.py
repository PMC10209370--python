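"""Statistical comparison toolkit for kinetic-parameter studies.

Covers the analyses the study design calls for: Pearson correlation
with a Fisher-z confidence interval (protocol agreement), Passing-
Bablok regression (method-comparison bias), ROC/AUC via the
Mann-Whitney identity (group discrimination), and per-group summary
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tac import DomainError

__all__ = [
    "MethodComparisonResult",
    "GroupComparisonResult",
    "pearson_ci",
    "passing_bablok",
    "roc_auc",
    "group_summary",
]


@dataclass(frozen=True)
class MethodComparisonResult:
    """Pearson + Passing-Bablok comparison of two measurement methods."""

    pearson_r: float
    r_ci_low: float
    r_ci_high: float
    p_value: float
    pb_slope: float
    pb_slope_ci: tuple[float, float]
    pb_intercept: float
    pb_intercept_ci: tuple[float, float]
    n: int


@dataclass(frozen=True)
class GroupComparisonResult:
    """Two-group discrimination summary for one parameter."""

    auc: float
    p_value: float
    summary: pd.DataFrame


def pearson_ci(x, y) -> tuple[float, tuple[float, float], float]:
    """Sample Pearson r with 95% Fisher-z CI and two-sided t-test p.

    Requires n >= 3 finite pairs with nonzero variance in both
    variables; the CI needs n >= 4 and is reported as (nan, nan) at
    n = 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise DomainError("need n >= 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if n >= 4 and abs(r) < 1.0:
        z = np.arctanh(r)
        hw = sps.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - hw)), float(np.tanh(z + hw)))
    elif abs(r) >= 1.0:
        ci = (r, r)
    else:
        ci = (float("nan"), float("nan"))
    return r, ci, p


def _pb_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All pairwise slopes (y_j - y_i)/(x_j - x_i), x ties skipped."""
    n = x.size
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    keep = dx != 0
    return dy[keep] / dx[keep]


def passing_bablok(
    x, y
) -> tuple[float, tuple[float, float], float, tuple[float, float]]:
    """Passing-Bablok regression of y on x.

    The slope is the shifted median of all pairwise slopes: slopes equal
    to -1 are excluded and the median index is offset by K, the number
    of pairwise slopes below -1, which makes the estimate invariant to
    swapping x and y.  The slope CI uses the rank-based normal
    approximation; the intercept is median(y - slope*x) with its CI
    evaluated at the slope CI endpoints.  Fewer than 10 pairs triggers
    a warning; identical x throughout is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d arrays of equal length")
    n = x.size
    if np.all(x == x[0]):
        raise DomainError("all x values identical")
    if n < 10:
        warnings.warn(
            f"Passing-Bablok with n = {n} < 10 is unreliable", stacklevel=2
        )
    s = _pb_slopes(x, y)
    K = int(np.sum(s < -1.0))
    s = np.sort(s[s != -1.0])
    N = s.size
    if N == 0:
        raise DomainError("no valid pairwise slopes")
    if N % 2 == 1:
        slope = float(s[(N + 1) // 2 + K - 1])
    else:
        slope = float(0.5 * (s[N // 2 + K - 1] + s[N // 2 + K]))
    # rank-based CI (normal approximation on the concordance counts)
    w = sps.norm.ppf(0.975) * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(np.round((N - w) / 2.0))
    m2 = N - m1 + 1
    lo_i = int(np.clip(m1 + K - 1, 0, N - 1))
    hi_i = int(np.clip(m2 + K - 1, 0, N - 1))
    slope_ci = (float(s[lo_i]), float(s[hi_i]))
    intercept = float(np.median(y - slope * x))
    int_ci = (
        float(np.median(y - slope_ci[1] * x)),
        float(np.median(y - slope_ci[0] * x)),
    )
    return slope, slope_ci, intercept, (min(int_ci), max(int_ci))


def compare_methods(x, y) -> MethodComparisonResult:
    """Bundle Pearson and Passing-Bablok into one comparison record."""
    r, r_ci, p = pearson_ci(x, y)
    slope, slope_ci, intercept, int_ci = passing_bablok(x, y)
    return MethodComparisonResult(
        pearson_r=r, r_ci_low=r_ci[0], r_ci_high=r_ci[1], p_value=p,
        pb_slope=slope, pb_slope_ci=slope_ci,
        pb_intercept=intercept, pb_intercept_ci=int_ci,
        n=int(np.asarray(x).size),
    )


def roc_auc(labels, values) -> tuple[float, float]:
    """AUC via the Mann-Whitney U identity, with tie correction.

    ``labels`` are binary (1 = positive); AUC = U1/(n1*n0) where U1 is
    the rank-sum statistic of the positive class, so ties contribute
    1/2.  The p-value comes from the normal-approximated two-sided
    Mann-Whitney test.
    """
    lab = np.asarray(labels).astype(bool)
    val = np.asarray(values, dtype=float)
    if lab.shape != val.shape or lab.ndim != 1:
        raise DomainError("labels and values must be 1-d arrays of equal length")
    pos = val[lab]
    neg = val[~lab]
    if pos.size == 0 or neg.size == 0:
        raise DomainError("both classes must be present")
    res = sps.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = float(res.statistic) / (pos.size * neg.size)
    return auc, float(res.pvalue)


def group_summary(
    table: pd.DataFrame, parameter: str, group_col: str = "group"
) -> pd.DataFrame:
    """Per-group mean, SD (n-1), median and n of one parameter column.

    An SD is reported as NaN (missing) for single-value groups; an
    empty group is an error.
    """
    if parameter not in table.columns:
        raise DomainError(f"no column {parameter!r} in table")
    if group_col not in table.columns:
        raise DomainError(f"no column {group_col!r} in table")
    out = []
    for g, sub in table.groupby(group_col, sort=True):
        v = sub[parameter].to_numpy(dtype=float)
        if v.size == 0:  # pragma: no cover - groupby drops empty groups
            raise DomainError(f"empty group {g!r}")
        out.append(
            {
                group_col: g,
                "n": int(v.size),
                "mean": float(np.mean(v)),
                "sd": float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
                "median": float(np.median(v)),
            }
        )
    return pd.DataFrame(out)


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    group_col: str = "group",
    positive: str | None = None,
) -> GroupComparisonResult:
    """ROC discrimination plus summary table for one parameter."""
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise DomainError(f"need exactly 2 groups, got {groups}")
    positive = positive or groups[0]
    labels = (table[group_col] == positive).to_numpy()
    auc, p = roc_auc(labels, table[parameter].to_numpy(dtype=float))
    return GroupComparisonResult(
        auc=auc, p_value=p, summary=group_summary(table, parameter, group_col)
    )
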