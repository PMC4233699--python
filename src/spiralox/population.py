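"""Proliferation and viability summaries per construct region and day.

Resazurin (Alamar blue) absorbance is converted to cell number through a
linear standard curve; proliferation is reported as cell number in percent
of the day-1 outer-region baseline.  Live/dead co-staining yields percent
viability ``100 * live / (live + dead)``.  Both are aggregated per
region x day as mean +/- standard error over replicates, the quantities the
figure-level summaries plot.  Significance testing (ANOVA) is left to any
standard statistics facility; the per-replicate tables emitted here are its
input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "absorbance_to_cells",
    "viability_percent",
    "relative_difference",
    "proliferation_percent",
    "viability_summary",
]

VIABILITY_COLUMNS = ["region", "day", "replicate", "live_count", "dead_count"]
PROLIFERATION_COLUMNS = ["region", "day", "replicate", "absorbance"]
CALIBRATION_COLUMNS = ["cells", "absorbance"]
REGIONS = ("core", "middle", "outer")
DAY_SCHEDULE = (0, 1, 3, 5, 7, 10)


@dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance -> cell-number calibration.

    ``cells = slope * absorbance + intercept`` with ``slope > 0``;
    ``residual_se`` is the standard error of the regression residuals.
    """

    slope: float
    intercept: float
    residual_se: float
    n_points: int

    def to_cells(self, absorbance) -> np.ndarray | float:
        a = np.asarray(absorbance, dtype=float)
        cells = np.maximum(self.slope * a + self.intercept, 0.0)
        return float(cells) if np.ndim(absorbance) == 0 else cells


def fit_standard_curve(points: pd.DataFrame) -> StandardCurve:
    """Ordinary least-squares standard curve from calibration pairs.

    ``points`` needs columns ``cells`` and ``absorbance`` with at least two
    distinct absorbance values.
    """
    missing = [c for c in CALIBRATION_COLUMNS if c not in points.columns]
    if missing:
        raise ValidationError(f"calibration table missing columns: {missing}")
    a = points["absorbance"].to_numpy(float)
    c = points["cells"].to_numpy(float)
    if a.size < 2 or np.unique(a).size < 2:
        raise ValidationError(
            "standard curve needs at least 2 distinct absorbance values"
        )
    res = stats.linregress(a, c)
    if res.slope <= 0:
        raise ValidationError(
            f"standard curve slope must be positive, got {res.slope:g}"
        )
    fitted = res.slope * a + res.intercept
    dof = max(a.size - 2, 1)
    rse = float(np.sqrt(np.sum((c - fitted) ** 2) / dof))
    return StandardCurve(float(res.slope), float(res.intercept), rse, int(a.size))


def absorbance_to_cells(curve: StandardCurve, a: float) -> float:
    """Cell number for one absorbance reading (floored at zero)."""
    return curve.to_cells(a)


def viability_percent(live: float, dead: float) -> float:
    """Live cells as a percentage of total (live + dead)."""
    if live < 0 or dead < 0:
        raise ValidationError("counts must be non-negative")
    total = live + dead
    if total <= 0:
        raise DomainError("live + dead must be positive")
    return 100.0 * live / total


def relative_difference(p_ref: float, p_other: float) -> float:
    """How much lower ``p_other`` is than ``p_ref``, in percent of ``p_ref``."""
    if p_ref <= 0:
        raise DomainError(f"reference percentage must be > 0, got {p_ref:g}")
    return 100.0 * (p_ref - p_other) / p_ref


def _check_table(table: pd.DataFrame, columns: list[str], name: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValidationError(f"{name} table missing columns: {missing}")


def proliferation_percent(
    table: pd.DataFrame, curve: StandardCurve
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell number in percent of the day-1 outer-region baseline.

    The baseline is the mean converted cell number over day-1 outer
    replicates (so the baseline cell count itself evaluates to exactly
    100%).  Returns ``(per_replicate, summary)`` where the summary holds
    mean and standard error per region x day.
    """
    _check_table(table, PROLIFERATION_COLUMNS, "proliferation")
    df = table.copy()
    df["cells"] = curve.to_cells(df["absorbance"].to_numpy(float))
    base_rows = df[(df["region"] == "outer") & (df["day"] == 1)]
    if base_rows.empty:
        raise ValidationError(
            "proliferation table has no day-1 outer rows to use as baseline"
        )
    baseline = float(base_rows["cells"].mean())
    if baseline <= 0:
        raise ValidationError("day-1 outer baseline cell number must be positive")
    df["percent_of_baseline"] = 100.0 * df["cells"] / baseline
    summary = (
        df.groupby(["region", "day"])["percent_of_baseline"]
        .agg(mean="mean", sem="sem", n="count")
        .reset_index()
        .fillna({"sem": 0.0})
    )
    return df, summary


def viability_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent viability per replicate plus mean +/- SE per region x day."""
    _check_table(table, VIABILITY_COLUMNS, "viability")
    df = table.copy()
    live = df["live_count"].to_numpy(float)
    dead = df["dead_count"].to_numpy(float)
    if np.any(live < 0) or np.any(dead < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(live + dead <= 0):
        raise ValidationError("live + dead must be positive in every row")
    df["viability_pct"] = 100.0 * live / (live + dead)
    summary = (
        df.groupby(["region", "day"])["viability_pct"]
        .agg(mean="mean", sem="sem", n="count")
        .reset_index()
        .fillna({"sem": 0.0})
    )
    return df, summary
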