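"""Concentric zone masks and per-zone engineered symmetry features.

Peripheral grid cells are contaminated by the limbus, eyelids, nose
shadow and extrapolation artifacts, so difference maps are masked to the
central 6.0 mm zone, further subdivided into concentric 2.0, 3.0, 4.0
and 5.0 mm zones.  With the inclusive boundary rule (cell center within
the zone radius) the zones contain exactly 317, 709, 1257, 1961 and 2821
grid points — lattice-point counts inside circles of radius 10, 15, 20,
25 and 30 grid units.

Each zone's flattened values are summarized into 17 features: skewness,
absolute skewness, excess kurtosis, mean, sample SD, absolute mean,
median, absolute median, min, max, absolute max, range, central 95%
range (P97.5 - P2.5), and the negative / positive / total volumes and
volume difference (signed sums times the 0.01 mm^2 cell area).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import CELL_AREA_MM2, GRID_SIZE, coordinate_grids
from .symmetry import DifferenceMap

DEFAULT_ZONE_DIAMETERS: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0)

#: feature names in reporting order
FEATURE_NAMES: tuple[str, ...] = (
    "skew", "abs_skew", "kurtosis", "mean", "sd", "abs_mean",
    "median", "abs_median", "min", "max", "abs_max", "range",
    "central95_range", "neg_volume", "pos_volume", "total_volume",
    "volume_diff",
)

#: features measuring dispersion; undefined for a single observation
_DISPERSION_FEATURES = ("sd", "skew", "abs_skew", "kurtosis")


class EmptyZoneError(ValueError):
    """Raised when a zone contains no valid (non-missing) values."""


@dataclass(frozen=True)
class ZoneMask:
    """Boolean selection of grid cells within a central circular zone."""

    diameter: float  # mm
    mask: np.ndarray
    point_count: int


def build_zone_mask(diameter: float) -> ZoneMask:
    """Mask of cells with x^2 + y^2 <= (diameter/2)^2, boundary inclusive."""
    if not 0 < diameter <= 14.0:
        raise ValueError(f"zone diameter must be in (0, 14.0] mm, got {diameter}")
    X, Y = coordinate_grids()
    r2 = (diameter / 2.0) ** 2
    # integer-squared comparison avoids float round-off at the boundary
    Xi = np.rint(X * 10).astype(np.int64)
    Yi = np.rint(Y * 10).astype(np.int64)
    mask = (Xi * Xi + Yi * Yi) * 1.0 <= r2 * 100.0 + 1e-9
    return ZoneMask(diameter=diameter, mask=mask, point_count=int(mask.sum()))


def extract_zone_values(
    diff: DifferenceMap, mask: ZoneMask
) -> tuple[np.ndarray, int, int]:
    """Flatten the non-missing values at masked cells, row-major.

    Returns ``(values, n_valid, n_missing)``.
    """
    selected = diff.grid[mask.mask]
    valid = np.isfinite(selected)
    values = selected[valid]
    return values, int(valid.sum()), int((~valid).sum())


def summarize_zone(
    values: Sequence[float] | np.ndarray, cell_area: float = CELL_AREA_MM2
) -> dict[str, float]:
    """Compute the 17 engineered features for one zone's flattened values.

    Volumes are in um.mm^2 (1e-3 mm^3).  Skewness is the Fisher-Pearson
    third standardized moment and kurtosis the excess fourth moment,
    both bias-uncorrected; for constant input the 0/0 moment ratios are
    resolved to 0.  SD is the sample standard deviation (ddof=1).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n == 0:
        raise EmptyZoneError("zone contains no valid values")

    out: dict[str, float] = {}
    out["mean"] = float(v.mean())
    out["median"] = float(np.median(v))
    out["abs_mean"] = float(np.abs(v).mean())
    out["abs_median"] = float(np.median(np.abs(v)))
    out["min"] = float(v.min())
    out["max"] = float(v.max())
    out["abs_max"] = float(max(out["max"], abs(out["min"])))
    out["range"] = out["max"] - out["min"]
    p_lo, p_hi = np.percentile(v, [2.5, 97.5])  # linear interpolation
    out["central95_range"] = float(p_hi - p_lo)

    if n == 1:
        warnings.warn(
            "single-value zone: dispersion features reported as 0", stacklevel=2
        )
        for name in _DISPERSION_FEATURES:
            out[name] = 0.0
    else:
        out["sd"] = float(v.std(ddof=1))
        if np.ptp(v) == 0.0:
            out["skew"] = 0.0
            out["kurtosis"] = 0.0
        else:
            out["skew"] = float(stats.skew(v, bias=True))
            out["kurtosis"] = float(stats.kurtosis(v, fisher=True, bias=True))
        out["abs_skew"] = abs(out["skew"])

    neg = v[v < 0]
    pos = v[v > 0]
    out["neg_volume"] = float(abs(neg.sum()) * cell_area)
    out["pos_volume"] = float(pos.sum() * cell_area)
    out["total_volume"] = out["neg_volume"] + out["pos_volume"]
    out["volume_diff"] = abs(out["pos_volume"] - out["neg_volume"])
    out["n_valid"] = float(n)
    return out


def signed_mean_abs(values: Sequence[float] | np.ndarray) -> float:
    """|mean| of a zone's values — the alternative reading of "absolute
    mean"; kept for comparison with the default mean-of-absolute-values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise EmptyZoneError("zone contains no valid values")
    return float(abs(v.mean()))


def zone_column(diameter: float, feature: str) -> str:
    """Canonical flattened column name for a (zone, feature) pair."""
    return f"{diameter:.1f}mm_{feature}"


def featurize_case(
    diff: DifferenceMap,
    diameters: Sequence[float] = DEFAULT_ZONE_DIAMETERS,
    masks: Mapping[float, ZoneMask] | None = None,
) -> dict[str, float]:
    """One flattened feature row for a case: every (zone, feature) column."""
    if not diameters:
        raise ValueError("at least one zone diameter is required")
    row: dict[str, float] = {}
    for d in diameters:
        mask = masks[d] if masks is not None else build_zone_mask(d)
        values, n_valid, _ = extract_zone_values(diff, mask)
        summary = summarize_zone(values)
        for feat in FEATURE_NAMES:
            row[zone_column(d, feat)] = summary[feat]
        row[zone_column(d, "n_valid")] = float(n_valid)
    return row


def featurize_cohort(
    diffs: Iterable[DifferenceMap],
    diameters: Sequence[float] = DEFAULT_ZONE_DIAMETERS,
) -> pd.DataFrame:
    """Feature table: one row per case, indexed by case id."""
    masks = {d: build_zone_mask(d) for d in diameters}
    rows = {}
    for diff in diffs:
        if diff.case_id in rows:
            raise ValueError(f"duplicate case id {diff.case_id!r} in cohort")
        rows[diff.case_id] = featurize_case(diff, diameters, masks)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "case_id"
    return table


def cumulative_within_range(
    case_values: Mapping[str, np.ndarray],
    thresholds: Sequence[float],
) -> list[float]:
    """Fraction of cases whose every zone value lies within +/- t, per t.

    ``case_values`` maps case id to that case's flattened zone values.
    Equivalent to the empirical CDF of the per-case absolute maximum
    evaluated at each threshold; non-decreasing in t.
    """
    if not case_values:
        raise ValueError("cumulative_within_range needs at least one case")
    t = np.asarray(thresholds, dtype=float)
    if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) < 0):
        raise ValueError("thresholds must be positive and ascending")
    abs_max = np.array(
        [
            np.abs(np.asarray(v, dtype=float)[np.isfinite(np.asarray(v, dtype=float))]).max(initial=0.0)
            for v in case_values.values()
        ]
    )
    return [float(np.mean(abs_max <= ti)) for ti in t]


# ---------------------------------------------------------------------------
# table IO


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=True)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col="case_id")
    if table.index.duplicated().any():
        raise ValueError("feature table has duplicate case ids")
    return table


def write_arff(table: pd.DataFrame, path: str | Path,
               relation: str = "fellow_eye_symmetry") -> Path:
    """Export the feature table as ARFF for WEKA-style tools."""
    path = Path(path)
    lines = [f"@RELATION {relation}", "", "@ATTRIBUTE case_id STRING"]
    for col in table.columns:
        lines.append(f"@ATTRIBUTE {col} NUMERIC")
    lines.extend(["", "@DATA"])
    for case_id, row in table.iterrows():
        toks = [str(case_id)] + [
            "?" if not np.isfinite(x) else f"{x:.10g}" for x in row.to_numpy(float)
        ]
        lines.append(",".join(toks))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
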