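"""Symmetry-pattern taxonomy for fellow-eye difference maps.

Visual review of difference colormaps distinguishes five recurring
patterns: *flat* (monochrome near-zero disk: excellent mirror symmetry),
*tilt* (opposing positive/negative semicircles separated by a zero band:
an axis difference between the eyes), *cone* (one cornea steeper, the
gap growing from center to periphery: the central-keratoconus
signature), *4-leaf* (steep in one meridian and flat in the
perpendicular one: direct rather than mirror symmetry with
astigmatism), and *irregular* (none of the above).

This module makes the taxonomy operational: the masked zone values are
least-squares fitted on the first six Zernike-style surfaces over the
zone disk — piston (1), tilt (rho cos/sin theta), defocus (2 rho^2 - 1)
and astigmatism (rho^2 cos/sin 2 theta) — and the label follows from
which component group dominates the non-piston signal energy.  The
thresholds are package choices, configurable, not measured quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .grid import coordinate_grids
from .symmetry import DifferenceMap
from .zones import ZoneMask, build_zone_mask


class PatternLabel(str, Enum):
    FLAT = "FLAT"
    TILT = "TILT"
    CONE = "CONE"
    FOUR_LEAF = "FOUR_LEAF"
    IRREGULAR = "IRREGULAR"


class CoverageError(ValueError):
    """Raised when too few valid points remain in the classification zone."""


@dataclass(frozen=True)
class PatternThresholds:
    """Decision thresholds of the pattern rule.

    flat_rms : um
        Zone RMS below which the map is FLAT (near-zero everywhere).
    dominant_fraction : unitless
        Minimum share of non-piston signal energy the leading component
        group must carry for a single-mode label.
    residual_fraction : unitless
        Maximum share the low-order fit residual may carry.
    min_coverage : unitless
        Minimum fraction of zone points that must be valid.
    """

    flat_rms: float = 2.0
    dominant_fraction: float = 0.6
    residual_fraction: float = 0.35
    min_coverage: float = 0.5


DEFAULT_THRESHOLDS = PatternThresholds()


@dataclass
class PatternResult:
    """Classification outcome with the amplitudes that justify it.

    Amplitudes are coefficients of the unnormalized surfaces, in um:
    ``tilt_magnitude`` is the peak-at-zone-edge magnitude of the fitted
    plane, ``defocus`` the coefficient of 2 rho^2 - 1 (sign: positive
    means the left cornea's sag grows faster), ``astig_magnitude`` the
    zone-edge amplitude of the rho^2 cos 2 theta saddle.  Axes in
    degrees, counterclockwise from the +x (temporal-for-OD) direction;
    the astigmatic axis is meaningful modulo 180.
    """

    label: PatternLabel
    piston: float
    tilt_magnitude: float
    tilt_axis: float
    defocus: float
    astig_magnitude: float
    astig_axis: float
    residual_rms: float
    dominant_fraction: float
    total_rms: float = 0.0
    n_valid: int = 0
    energies: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.tilt_magnitude < 0 or self.astig_magnitude < 0 or self.residual_rms < 0:
            raise ValueError("magnitudes and residual RMS must be non-negative")
        if not 0.0 <= self.dominant_fraction <= 1.0:
            raise ValueError("dominant_fraction must lie in [0, 1]")


def _design_matrix(mask: ZoneMask, valid: np.ndarray) -> np.ndarray:
    X, Y = coordinate_grids()
    radius = mask.diameter / 2.0
    x = X[mask.mask][valid] / radius
    y = Y[mask.mask][valid] / radius
    rho2 = x * x + y * y
    # columns: piston, tilt-x, tilt-y, defocus, astig-0/90, astig-45
    return np.column_stack([
        np.ones_like(x), x, y, 2.0 * rho2 - 1.0,
        x * x - y * y,          # rho^2 cos 2theta
        2.0 * x * y,            # rho^2 sin 2theta
    ])


def decompose_low_order(
    diff: DifferenceMap,
    zone_diameter: float = 6.0,
    min_coverage: float = 0.5,
) -> PatternResult:
    """Fit the six low-order surfaces to the masked zone of a difference map.

    Returns a :class:`PatternResult` with label IRREGULAR as a
    placeholder; :func:`classify_pattern` applies the decision rule.
    Component energies are evaluated on the actual grid samples, so
    discrete-lattice non-orthogonality of the basis is accounted for.
    """
    mask = build_zone_mask(zone_diameter)
    zone_vals = diff.grid[mask.mask]
    valid = np.isfinite(zone_vals)
    n_valid = int(valid.sum())
    if n_valid < min_coverage * mask.point_count:
        raise CoverageError(
            f"only {n_valid}/{mask.point_count} valid points in the "
            f"{zone_diameter} mm zone (need >= {min_coverage:.0%})"
        )
    v = zone_vals[valid]
    A = _design_matrix(mask, valid)
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    fitted = A @ coef
    resid = v - fitted

    piston = float(coef[0])
    tilt_mag = float(np.hypot(coef[1], coef[2]))
    tilt_axis = float(np.degrees(np.arctan2(coef[2], coef[1])) % 360.0)
    if tilt_axis >= 360.0 - 1e-9:
        tilt_axis = 0.0
    defocus = float(coef[3])
    astig_mag = float(np.hypot(coef[4], coef[5]))
    astig_axis = float((np.degrees(np.arctan2(coef[5], coef[4])) / 2.0) % 180.0)
    if astig_axis >= 180.0 - 1e-9:
        astig_axis = 0.0

    # per-group mean-square energy on the sampled points
    e_tilt = float(np.mean((A[:, 1:3] @ coef[1:3]) ** 2))
    e_defocus = float(np.mean((A[:, 3] * coef[3]) ** 2))
    e_astig = float(np.mean((A[:, 4:6] @ coef[4:6]) ** 2))
    e_resid = float(np.mean(resid**2))
    nonpiston = e_tilt + e_defocus + e_astig + e_resid
    dominant = max(e_tilt, e_defocus, e_astig) / nonpiston if nonpiston > 0 else 0.0

    return PatternResult(
        label=PatternLabel.IRREGULAR,
        piston=piston,
        tilt_magnitude=tilt_mag,
        tilt_axis=tilt_axis,
        defocus=defocus,
        astig_magnitude=astig_mag,
        astig_axis=astig_axis,
        residual_rms=float(np.sqrt(e_resid)),
        dominant_fraction=float(dominant),
        total_rms=float(np.sqrt(np.mean(v**2))),
        n_valid=n_valid,
        energies={
            PatternLabel.TILT: e_tilt,
            PatternLabel.CONE: e_defocus,
            PatternLabel.FOUR_LEAF: e_astig,
            "residual": e_resid,
        },
    )


def classify_pattern(
    diff: DifferenceMap,
    zone_diameter: float = 6.0,
    thresholds: PatternThresholds = DEFAULT_THRESHOLDS,
) -> PatternResult:
    """Assign a symmetry-pattern label to a difference map.

    Rule: FLAT if the zone RMS is at or below ``flat_rms``; otherwise
    the non-piston energy is split among tilt, defocus, astigmatism and
    residual, and a single-mode label (TILT / CONE / FOUR_LEAF) is
    assigned when the leading group carries at least
    ``dominant_fraction`` of it while the residual stays at or below
    ``residual_fraction``; anything else is IRREGULAR.  Defocus sign is
    ignored for CONE (either cornea may be the steeper one).
    """
    res = decompose_low_order(diff, zone_diameter, thresholds.min_coverage)
    if res.total_rms <= thresholds.flat_rms:
        res.label = PatternLabel.FLAT
        return res

    energies = {
        lab: res.energies[lab]
        for lab in (PatternLabel.TILT, PatternLabel.CONE, PatternLabel.FOUR_LEAF)
    }
    e_resid = res.energies["residual"]
    nonpiston = sum(energies.values()) + e_resid
    if nonpiston <= 0:
        # above-threshold RMS carried entirely by a uniform offset
        res.label = PatternLabel.IRREGULAR
        return res
    top_label, top_energy = max(energies.items(), key=lambda kv: kv[1])
    if (
        top_energy / nonpiston >= thresholds.dominant_fraction
        and e_resid / nonpiston <= thresholds.residual_fraction
    ):
        res.label = top_label
    else:
        res.label = PatternLabel.IRREGULAR
    return res


def classify_batch(
    diffs: Sequence[DifferenceMap],
    zone_diameter: float = 6.0,
    thresholds: PatternThresholds = DEFAULT_THRESHOLDS,
):
    """Classify many maps; returns a DataFrame (one row per case)."""
    import pandas as pd

    rows = []
    for diff in diffs:
        r = classify_pattern(diff, zone_diameter, thresholds)
        rows.append(
            {
                "case_id": diff.case_id,
                "label": r.label.value,
                "piston": r.piston,
                "tilt_magnitude": r.tilt_magnitude,
                "tilt_axis": r.tilt_axis,
                "defocus": r.defocus,
                "astig_magnitude": r.astig_magnitude,
                "astig_axis": r.astig_axis,
                "residual_rms": r.residual_rms,
                "dominant_fraction": r.dominant_fraction,
                "total_rms": r.total_rms,
            }
        )
    return pd.DataFrame(rows).set_index("case_id")
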