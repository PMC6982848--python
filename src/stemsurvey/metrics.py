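"""Accuracy statistics for paired device-vs-reference measurements.

Given device values d_j and reference values d_jr matched by tree:

    BIAS    = mean(d_j − d_jr)
    relBIAS = mean(d_j/d_jr − 1) · 100%
    RMSE    = sqrt(mean((d_j − d_jr)²))
    relRMSE = sqrt(mean((d_j/d_jr − 1)²)) · 100%
    MAPE    = mean(|d_j/d_jr − 1|) · 100%

and for positions the per-tree Euclidean distance error
Ed_j = sqrt((x_j − x_jr)² + (y_j − y_jr)²), summarised alongside per-axis
BIAS/RMSE.  Per-plot summaries pool all trees for the Total row (RMSE over
the pooled errors, not the mean of per-plot RMSEs).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError

__all__ = [
    "bias", "rel_bias", "rmse", "rel_rmse", "mape",
    "dbh_statistics", "position_errors", "correlation", "per_plot_summary",
]


def _paired(d, d_r, relative: bool = False):
    d = np.asarray(d, dtype=float)
    d_r = np.asarray(d_r, dtype=float)
    if d.shape != d_r.shape:
        raise UndefinedStatisticError(f"length mismatch: {d.shape} vs {d_r.shape}")
    if d.size == 0:
        raise UndefinedStatisticError("empty sample")
    if relative and np.any(d_r == 0):
        raise UndefinedStatisticError("zero reference value in relative statistic")
    return d, d_r


def bias(d, d_r) -> float:
    d, d_r = _paired(d, d_r)
    return float(np.mean(d - d_r))


def rel_bias(d, d_r) -> float:
    d, d_r = _paired(d, d_r, relative=True)
    return float(np.mean(d / d_r - 1.0) * 100.0)


def rmse(d, d_r) -> float:
    d, d_r = _paired(d, d_r)
    return float(np.sqrt(np.mean((d - d_r) ** 2)))


def rel_rmse(d, d_r) -> float:
    d, d_r = _paired(d, d_r, relative=True)
    return float(np.sqrt(np.mean((d / d_r - 1.0) ** 2)) * 100.0)


def mape(d, d_r) -> float:
    d, d_r = _paired(d, d_r, relative=True)
    return float(np.mean(np.abs(d / d_r - 1.0)) * 100.0)


def dbh_statistics(d, d_r) -> dict[str, float]:
    """All five DBH accuracy statistics in one pass (units of the input)."""
    return {
        "BIAS": bias(d, d_r),
        "relBIAS_pct": rel_bias(d, d_r),
        "RMSE": rmse(d, d_r),
        "relRMSE_pct": rel_rmse(d, d_r),
        "MAPE_pct": mape(d, d_r),
    }


def position_errors(x, y, x_r, y_r) -> dict:
    """Per-axis BIAS/RMSE, axis-error correlation, and Ed summary (cm).

    Returns the Ed vector plus the summary used in per-plot position tables:
    mean/max/min/std of Ed and the Pearson correlation of x- and y-errors.
    """
    x, x_r = _paired(x, x_r)
    y, y_r = _paired(y, y_r)
    ex, ey = x - x_r, y - y_r
    ed = np.hypot(ex, ey)
    out = {
        "BIAS_x": float(np.mean(ex)),
        "BIAS_y": float(np.mean(ey)),
        "RMSE_x": float(np.sqrt(np.mean(ex ** 2))),
        "RMSE_y": float(np.sqrt(np.mean(ey ** 2))),
        "Ed": ed,
        "Ed_mean": float(np.mean(ed)),
        "Ed_max": float(np.max(ed)),
        "Ed_min": float(np.min(ed)),
        "Ed_std": float(np.std(ed, ddof=1)) if ed.size > 1 else 0.0,
        "rho_xy": correlation(ex, ey) if ed.size >= 3 and np.std(ex) > 0 and np.std(ey) > 0 else float("nan"),
    }
    return out


def correlation(u, v) -> float:
    """Pearson product-moment correlation coefficient of two vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.size != v.size or u.size < 3:
        raise UndefinedStatisticError("correlation needs two equal-length vectors, n >= 3")
    if np.std(u) == 0 or np.std(v) == 0:
        raise UndefinedStatisticError("zero variance in correlation input")
    r, _ = stats.pearsonr(u, v)
    return float(r)


def per_plot_summary(df: pd.DataFrame, value: str = "dbh_mm",
                     reference: str = "dbh_ref_mm", group: str = "plot_id") -> pd.DataFrame:
    """Per-plot DBH accuracy table with a pooled Total row.

    ``df`` must carry one row per tree with estimate and reference columns.
    The Total row recomputes every statistic over all trees pooled — for
    RMSE this differs from averaging the per-plot rows.
    """
    if df.empty:
        raise UndefinedStatisticError("empty evaluation table")
    rows = []
    for key, sub in df.groupby(group, sort=True):
        rows.append({group: key, "n": len(sub),
                     **dbh_statistics(sub[value], sub[reference])})
    rows.append({group: "Total", "n": len(df),
                 **dbh_statistics(df[value], df[reference])})
    return pd.DataFrame(rows)


def per_plot_position_summary(df: pd.DataFrame, group: str = "plot_id") -> pd.DataFrame:
    """Per-plot position accuracy table (x/y BIAS+RMSE, rho_xy, Ed summary).

    Expects columns x_cm, y_cm, x_ref_cm, y_ref_cm; pooled Total row as above.
    """
    if df.empty:
        raise UndefinedStatisticError("empty evaluation table")

    def row(sub):
        r = position_errors(sub["x_cm"], sub["y_cm"], sub["x_ref_cm"], sub["y_ref_cm"])
        r.pop("Ed")
        return r

    rows = [{group: key, "n": len(sub), **row(sub)} for key, sub in df.groupby(group, sort=True)]
    rows.append({group: "Total", "n": len(df), **row(df)})
    return pd.DataFrame(rows)
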