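"""Shared statistics: Mann-Whitney comparisons with star notation,
boxplot summaries (1.5 x IQR whiskers), Gaussian KDE, and Pearson
correlation for validation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: significance stars: (exclusive lower bound, inclusive upper bound) on p
STAR_THRESHOLDS = [
    (1.00e-04, "****"),
    (1.00e-03, "***"),
    (1.00e-02, "**"),
    (5.00e-02, "*"),
]


def star_code(p: float) -> str:
    if p <= 1.00e-04:
        return "****"
    if p <= 1.00e-03:
        return "***"
    if p <= 1.00e-02:
        return "**"
    if p <= 5.00e-02:
        return "*"
    return "ns"


@dataclass
class BoxplotSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray
    n: int


@dataclass
class ComparisonResult:
    label_a: str
    label_b: str
    u_statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int
    summary_a: BoxplotSummary
    summary_b: BoxplotSummary
    method: str


def boxplot_summary(values) -> BoxplotSummary:
    """Median, quartiles, whiskers at the most extreme points within
    1.5 x IQR of the box, and outliers beyond them."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=v[(v < lo_lim) | (v > hi_lim)],
        n=len(v),
    )


def mann_whitney(
    a, b, label_a: str = "a", label_b: str = "b"
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact U distribution when min(n, m) <= 8 and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(a), len(b)) <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(
        label_a=label_a,
        label_b=label_b,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        stars=star_code(float(res.pvalue)),
        n_a=len(a),
        n_b=len(b),
        summary_a=boxplot_summary(a),
        summary_b=boxplot_summary(b),
        method=method,
    )


def kde(values, grid: np.ndarray | None = None, n_grid: int = 256):
    """Gaussian KDE with Scott's-rule bandwidth; returns (grid, density).

    Zero-variance input gets a floored bandwidth (with a warning) so a
    single repeated value still yields a unimodal bump.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("KDE needs at least 2 values")
    if np.std(v) == 0:
        warnings.warn("zero-variance sample: applying bandwidth floor")
        scale = max(abs(v[0]), 1.0)
        v = v + np.random.default_rng(0).normal(0, 1e-3 * scale, size=len(v))
    k = stats.gaussian_kde(v, bw_method="scott")
    if grid is None:
        pad = 3.0 * v.std()
        grid = np.linspace(v.min() - pad, v.max() + pad, n_grid)
    return grid, k(grid)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance sample: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def ks_observed_vs_control(observed, control) -> tuple[float, float]:
    """Two-sample KS statistic between observed and control distributions.

    Extension beyond the visual comparison: reported alongside the KDEs.
    """
    res = stats.ks_2samp(np.asarray(observed, float), np.asarray(control, float))
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons over a long-format table."""
    groups = {k: g[value_col].dropna().to_numpy() for k, g in table.groupby(group_col)}
    if pairs is None:
        keys = list(groups)
        pairs = [(keys[i], keys[j]) for i in range(len(keys)) for j in range(i + 1, len(keys))]
    rows = []
    for la, lb in pairs:
        res = mann_whitney(groups[la], groups[lb], str(la), str(lb))
        rows.append(
            {
                "group_a": la,
                "group_b": lb,
                "U": res.u_statistic,
                "p": res.p_value,
                "stars": res.stars,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "median_a": res.summary_a.median,
                "median_b": res.summary_b.median,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
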