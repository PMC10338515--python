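"""Statistical post-processing of a pattern sweep.

Subgroup box statistics (median/quartiles/whiskers with the 1.5-IQR
outlier rule), two-tailed Pearson correlations between tidal volume and
the pattern parameters, plateau-onset detection along the frequency or
width axis, and a tabular interpolated (frequency, width) -> tidal-volume
surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import isotonic_regression

__all__ = [
    "SubgroupSummary",
    "CorrelationResult",
    "PlateauResult",
    "subgroup_boxstats",
    "pearson",
    "plateau_onset",
    "correlation_table",
    "box_table",
    "surface_table",
]

#: a pattern-mean counts as "on the plateau" at this fraction of the axis max
PLATEAU_FRACTION = 0.95


@dataclass(frozen=True)
class SubgroupSummary:
    """Box-plot statistics of per-pattern mean tidal volumes (mL/kg)."""

    subgroup: str
    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple


def subgroup_boxstats(values: Sequence[float], subgroup: str = "") -> SubgroupSummary:
    """Quartiles by linear interpolation of order statistics, whiskers at
    the extrema of non-outliers, outliers beyond 1.5 IQR from the box."""
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least four records for box statistics")
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo) & (values <= hi)]
    outliers = values[(values < lo) | (values > hi)]
    return SubgroupSummary(
        subgroup=subgroup,
        n=len(values),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=tuple(sorted(float(v) for v in outliers)),
    )


@dataclass(frozen=True)
class CorrelationResult:
    """Two-tailed Pearson correlation between a parameter and V_T,bw."""

    pair: tuple
    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float],
            pair: tuple = ("x", "y")) -> CorrelationResult:
    """Product-moment correlation with the two-tailed p-value from the
    t-transform on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for a constant series")
    res = stats.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(res.statistic),
                             p=float(res.pvalue), n=len(x))


@dataclass(frozen=True)
class PlateauResult:
    """Detected saturation onset on one parameter axis."""

    axis: str
    onset: float
    reached: bool
    means: tuple  # (grid value, mean V_T,bw) in axis order


_AXIS_COLUMNS = {"frequency": "pulse_frequency_hz", "width": "pulse_width_ms"}


def plateau_onset(
    records: pd.DataFrame,
    axis: str,
    other_value: float,
    expected_grid: Optional[Sequence[float]] = None,
    fraction: float = PLATEAU_FRACTION,
) -> PlateauResult:
    """Smallest grid value whose mean V_T,bw reaches ``fraction`` of the
    axis maximum.

    ``records`` holds one subgroup's non-baseline records with columns
    ``pulse_frequency_hz``, ``pulse_width_ms`` and ``mean_vt_ml_per_kg``;
    the other axis is filtered at ``other_value``.  If the level is first
    reached at the last grid value the result carries ``reached=False``
    (no plateau inside the measured range).  The rule is invariant to
    positive rescaling of the volume axis.

    The response is monotone saturating by construction, so the rule is
    applied to the isotonic (non-decreasing least-squares) fit of the
    means: thresholding on the raw maximum of noisy per-pattern means is
    upward biased and can push the detected onset past the true plateau.
    On monotone data the fit is the identity, so noise-free detection is
    unchanged.
    """
    if axis not in _AXIS_COLUMNS:
        raise ValueError(f"axis must be one of {sorted(_AXIS_COLUMNS)}")
    col = _AXIS_COLUMNS[axis]
    other_col = _AXIS_COLUMNS["width" if axis == "frequency" else "frequency"]
    sel = records[np.isclose(records[other_col], other_value)]
    sel = sel.sort_values(col)
    values = sel[col].to_numpy(dtype=float)
    if len(values) == 0 or len(np.unique(values)) != len(values):
        raise ValueError(
            f"records do not form a single {axis} axis at "
            f"{other_col}={other_value}"
        )
    if expected_grid is not None and not np.array_equal(
        np.sort(np.asarray(expected_grid, dtype=float)), values
    ):
        raise ValueError(f"incomplete {axis} axis: found {values.tolist()}")
    means = sel["mean_vt_ml_per_kg"].to_numpy(dtype=float)
    fitted = isotonic_regression(means, increasing=True).x
    threshold = fraction * fitted.max()
    idx = int(np.argmax(fitted >= threshold))
    return PlateauResult(
        axis=axis,
        onset=float(values[idx]),
        reached=idx < len(values) - 1,
        means=tuple(zip(values.tolist(), means.tolist())),
    )


def _pattern_frame(sweep_df: pd.DataFrame) -> pd.DataFrame:
    df = sweep_df[~sweep_df["is_baseline"]]
    # the baseline pattern sits inside one subgroup but off the canonical
    # width grid; keep it for box stats, exclude it from axis analyses
    return df


def correlation_table(sweep_df: pd.DataFrame) -> pd.DataFrame:
    """Per-subgroup two-tailed Pearson correlations of mean V_T,bw against
    pulse frequency and pulse width."""
    df = _pattern_frame(sweep_df)
    rows = []
    for subgroup, g in df.groupby("subgroup", sort=True):
        for name, col in (("f_p", "pulse_frequency_hz"), ("T_pw", "pulse_width_ms")):
            res = pearson(g[col], g["mean_vt_ml_per_kg"], pair=(name, "V_T,bw"))
            rows.append(
                {"subgroup": subgroup, "parameter": name, "r": res.r,
                 "p": res.p, "n": res.n}
            )
    return pd.DataFrame(rows)


def box_table(sweep_df: pd.DataFrame) -> pd.DataFrame:
    """Box statistics of per-pattern mean V_T,bw for every subgroup."""
    df = _pattern_frame(sweep_df)
    rows = []
    for subgroup, g in df.groupby("subgroup", sort=True):
        s = subgroup_boxstats(g["mean_vt_ml_per_kg"], subgroup)
        rows.append(
            {
                "subgroup": s.subgroup, "n": s.n, "median": s.median,
                "q1": s.q1, "q3": s.q3, "whisker_low": s.whisker_low,
                "whisker_high": s.whisker_high,
                "n_outliers": len(s.outliers),
                "outliers": ";".join(f"{v:.3f}" for v in s.outliers),
            }
        )
    return pd.DataFrame(rows)


def surface_table(
    sweep_df: pd.DataFrame,
    subgroup: str,
    n_freq: int = 25,
    n_width: int = 25,
) -> pd.DataFrame:
    """Bilinear (frequency, width) -> mean V_T,bw interpolation table.

    Tabular stand-in for a 3-D response surface: the grid means are
    interpolated onto a regular refinement of the measured axes.
    """
    df = _pattern_frame(sweep_df)
    g = df[df["subgroup"] == subgroup]
    freqs = np.sort(g["pulse_frequency_hz"].unique())
    widths = np.sort(g["pulse_width_ms"].unique())
    pivot = g.pivot_table(index="pulse_width_ms", columns="pulse_frequency_hz",
                          values="mean_vt_ml_per_kg")
    pivot = pivot.reindex(index=widths, columns=freqs)
    if pivot.isna().any().any():
        # drop off-grid widths (e.g. the baseline pattern's 4 ms row)
        pivot = pivot.dropna(axis=0)
        widths = pivot.index.to_numpy()
    interp = RegularGridInterpolator((widths, freqs), pivot.to_numpy(),
                                     method="linear")
    wq = np.linspace(widths.min(), widths.max(), n_width)
    fq = np.linspace(freqs.min(), freqs.max(), n_freq)
    ww, ff = np.meshgrid(wq, fq, indexing="ij")
    vt = interp(np.column_stack([ww.ravel(), ff.ravel()]))
    return pd.DataFrame(
        {
            "pulse_width_ms": ww.ravel(),
            "pulse_frequency_hz": ff.ravel(),
            "mean_vt_ml_per_kg": vt,
        }
    )
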