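"""Two-scale statistical change detection on indicator surfaces.

Large-scale change is a Kruskal–Wallis rank test between cell-level
indicator values at the endpoint years (2020 versus 2095); fine-scale
change is a per-cell Kendall's tau-b trend over the 5-year projection
steps, with a normal-approximation two-sided p-value and a direction
assigned only where p < alpha.  Both are rank-based and nonparametric,
matching skewed indicator distributions, and tau also detects smooth
nonlinear monotone change.  No multiplicity correction is applied across
cells by default; Benjamini–Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass
class LargeScaleTest:
    """Kruskal–Wallis comparison of an indicator between two endpoint years."""

    indicator: str
    scope: str
    h_statistic: float
    df: int
    p_value: float
    median_change: float

    @property
    def direction(self) -> str:
        if self.p_value >= DEFAULT_ALPHA or self.median_change == 0:
            return "none"
        return "increasing" if self.median_change > 0 else "decreasing"


def kruskal_wallis_change(values_a, values_b, indicator: str = "",
                          scope: str = "") -> LargeScaleTest:
    """Rank-based H test (with tie correction) between two years' cell values.

    NaN cells are dropped per year.  Identical pooled values give H=0, p=1.
    The sign of the median difference (b - a) is reported alongside, since H
    itself is directionless.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two valid cells per year")
    med = float(np.median(b) - np.median(a))
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return LargeScaleTest(indicator, scope, 0.0, 1, 1.0, med)
    h, p = stats.kruskal(a, b)
    return LargeScaleTest(indicator, scope, float(h), 1, float(p), med)


@dataclass
class TrendCell:
    """Kendall tau-b trend of one cell's indicator series."""

    tau: float
    p_value: float
    n: int
    direction: str  # increasing | decreasing | none


def kendall_trend(series, years=None, alpha: float = DEFAULT_ALPHA) -> TrendCell:
    """Tau-b rank correlation of an indicator series against time.

    Requires >=3 non-NaN time points; a constant series has undefined tau
    (NaN, direction 'none').  Direction is set only when the two-sided
    normal-approximation p-value is below ``alpha``.
    """
    v = np.asarray(series, dtype=float)
    t = np.asarray(years, dtype=float) if years is not None else np.arange(len(v), dtype=float)
    ok = ~np.isnan(v)
    v, t = v[ok], t[ok]
    if len(v) < 3:
        raise ValueError("need at least 3 time points")
    if np.all(v == v[0]):
        return TrendCell(float("nan"), float("nan"), len(v), "none")
    res = stats.kendalltau(t, v, variant="b", method="asymptotic")
    tau, p = float(res.statistic), float(res.pvalue)
    direction = "none"
    if p < alpha:
        direction = "increasing" if tau > 0 else "decreasing"
    return TrendCell(tau, p, len(v), direction)


def trend_map(stack: np.ndarray, years=None, alpha: float = DEFAULT_ALPHA,
              bh_correct: bool = False) -> pd.DataFrame:
    """Per-cell Kendall trends over a (n_years, ny, nx) indicator stack.

    Returns a tidy frame (y, x, tau, p, n, direction).  Cells with fewer
    than 3 valid time points are omitted.  With ``bh_correct`` the p-values
    are Benjamini–Hochberg adjusted across cells before directions are set.
    """
    stack = np.asarray(stack, dtype=float)
    n_years, ny, nx = stack.shape
    rows = []
    for y in range(ny):
        for x in range(nx):
            series = stack[:, y, x]
            if np.sum(~np.isnan(series)) < 3:
                continue
            c = kendall_trend(series, years, alpha=alpha)
            rows.append({"y": y, "x": x, "tau": c.tau, "p": c.p_value,
                         "n": c.n, "direction": c.direction})
    out = pd.DataFrame(rows)
    if bh_correct and len(out):
        from statsmodels.stats.multitest import multipletests

        valid = ~out["p"].isna()
        adj = out["p"].copy()
        adj.loc[valid] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
        out["p_adj"] = adj
        sig = valid & (out["p_adj"] < alpha)
        out["direction"] = "none"
        out.loc[sig & (out["tau"] > 0), "direction"] = "increasing"
        out.loc[sig & (out["tau"] < 0), "direction"] = "decreasing"
    return out


def trend_summary(trends: pd.DataFrame) -> dict[str, float]:
    """% of valid cells with a significant increasing / decreasing trend."""
    n = len(trends)
    if n == 0:
        return {"pct_increasing": 0.0, "pct_decreasing": 0.0, "n_cells": 0}
    inc = float((trends["direction"] == "increasing").mean() * 100.0)
    dec = float((trends["direction"] == "decreasing").mean() * 100.0)
    return {"pct_increasing": inc, "pct_decreasing": dec, "n_cells": n}
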