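"""Synthetic bilateral cornea generator.

Produces paired OD/OS anterior elevation grids with controlled mirror
symmetry for testing and method validation, standing in for cohort data
that is not publicly available.  The base cornea is a sphere of radius
7.8 mm (a typical anterior corneal radius) whose sag from the
apex-tangent plane gives the elevation in um; cells beyond the sphere's
footprint are missing, as they are in real exports.

The right eye is the base surface plus measurement noise.  The left eye
is the mirror image of the base surface plus an injected asymmetry
field plus independent noise, so the fellow-eye difference map recovers
exactly the injected field (plus noise).  Available asymmetry modes
mirror the difference-colormap taxonomy:

* TILT — a plane ``g * x`` (axis misalignment between the eyes),
* CONE — a centered Gaussian bump (one cornea steeper centrally),
* FOUR_LEAF — a ``rho^2 cos 2 theta`` saddle (meridional steep/flat
  mismatch),
* MIXED — a seeded combination.

Optional corruptions: i.i.d. Gaussian cell noise, uniformly random
missing cells (dropout), and large artifacts confined to outside the
central 6.0 mm zone (limbus / eyelid / shadow surrogates) which zone
masking must remove.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import GRID_SIZE, coordinate_grids
from .io import CasePair, ElevationMap, Eye, FormatDialect, DEFAULT_DIALECT, write_elevation_file


class AsymmetryMode(str, Enum):
    NONE = "none"
    TILT = "tilt"
    CONE = "cone"
    FOUR_LEAF = "four_leaf"
    MIXED = "mixed"


@dataclass(frozen=True)
class SyntheticParams:
    """Generation parameters for one bilateral case.

    Amplitudes are in um; ``tilt_amplitude`` and ``astig_amplitude`` are
    the peak value of their field at the 6.0 mm zone edge (3 mm from the
    apex), so modes of equal amplitude are visually comparable.
    ``noise_sd`` of 1 um matches typical central Scheimpflug elevation
    repeatability; ``cone_sigma`` of 1.5 mm gives a paracentral cone
    footprint.
    """

    case_id: str = "SYN0000"
    base_radius: float = 7.8  # mm
    asymmetry_mode: AsymmetryMode = AsymmetryMode.NONE
    tilt_amplitude: float = 20.0  # um at the 6.0 mm zone edge
    tilt_axis: float = 0.0  # deg
    cone_amplitude: float = 20.0  # um
    cone_sigma: float = 1.5  # mm
    astig_amplitude: float = 20.0  # um at the 6.0 mm zone edge
    astig_axis: float = 0.0  # deg
    noise_sd: float = 1.0  # um
    dropout_fraction: float = 0.02
    peripheral_artifact_amplitude: float = 0.0  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        for name in ("cone_sigma", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1]")


ZONE_EDGE_MM = 3.0  # radius of the 6.0 mm display zone


def base_surface(radius: float = 7.8, case_id: str = "BASE", eye: Eye = Eye.OD) -> ElevationMap:
    """Spherical sag surface: elevation from the apex-tangent plane, um.

    ``z(x, y) = 1000 * (R - sqrt(R^2 - x^2 - y^2))`` inside the sphere's
    footprint; cells with ``x^2 + y^2 >= R^2`` are missing.  The apex
    value is exactly 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    X, Y = coordinate_grids()
    r2 = X * X + Y * Y
    with np.errstate(invalid="ignore"):
        grid = 1000.0 * (radius - np.sqrt(radius * radius - r2))
    grid[r2 >= radius * radius] = np.nan
    return ElevationMap(case_id=case_id, eye=eye, grid=grid)


def asymmetry_field(params: SyntheticParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """The injected interocular asymmetry field on the grid, in um."""
    X, Y = coordinate_grids()
    mode = params.asymmetry_mode
    if mode is AsymmetryMode.NONE:
        return np.zeros_like(X)
    if mode is AsymmetryMode.TILT:
        ax = np.radians(params.tilt_axis)
        u = X * np.cos(ax) + Y * np.sin(ax)
        return (params.tilt_amplitude / ZONE_EDGE_MM) * u
    if mode is AsymmetryMode.CONE:
        r2 = X * X + Y * Y
        return params.cone_amplitude * np.exp(-r2 / (2.0 * params.cone_sigma**2))
    if mode is AsymmetryMode.FOUR_LEAF:
        rho2 = (X * X + Y * Y) / ZONE_EDGE_MM**2
        theta = np.arctan2(Y, X)
        return params.astig_amplitude * rho2 * np.cos(2.0 * (theta - np.radians(params.astig_axis)))
    # MIXED: seeded random weights over the three single modes
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    weights = rng.dirichlet(np.ones(3))
    parts = [
        asymmetry_field(replace(params, asymmetry_mode=m), rng)
        for m in (AsymmetryMode.TILT, AsymmetryMode.CONE, AsymmetryMode.FOUR_LEAF)
    ]
    return sum(w * p for w, p in zip(weights, parts))


def _apply_dropout(grid: np.ndarray, fraction: float, rng: np.random.Generator) -> None:
    if fraction <= 0:
        return
    drop = rng.random(grid.shape) < fraction
    grid[drop] = np.nan


def generate_pair(params: SyntheticParams) -> CasePair:
    """Generate one bilateral case, fully reproducible from ``params.seed``.

    right = base + noise; left = mirror(base + asymmetry) + noise.  The
    fellow-eye difference map (flip-left minus right) then equals the
    asymmetry field plus the two noise fields.  Peripheral artifacts are
    added outside the 6.0 mm zone only.
    """
    rng = np.random.default_rng(params.seed)
    base = base_surface(params.base_radius).grid
    asym = asymmetry_field(params, rng)

    right = base.copy()
    left = (base + asym)[:, ::-1].copy()  # mirror about the vertical axis

    if params.noise_sd > 0:
        right = right + rng.normal(0.0, params.noise_sd, right.shape)
        left = left + rng.normal(0.0, params.noise_sd, left.shape)

    if params.peripheral_artifact_amplitude > 0:
        from .zones import build_zone_mask

        # complement of the display-zone mask, so the boundary cells the
        # mask includes are never touched
        outside = ~build_zone_mask(2 * ZONE_EDGE_MM).mask
        artifact = params.peripheral_artifact_amplitude * rng.uniform(-1.0, 1.0, right.shape)
        right = np.where(outside, right + artifact, right)

    _apply_dropout(right, params.dropout_fraction, rng)
    _apply_dropout(left, params.dropout_fraction, rng)

    return CasePair(
        case_id=params.case_id,
        right=ElevationMap(case_id=params.case_id, eye=Eye.OD, grid=right),
        left=ElevationMap(case_id=params.case_id, eye=Eye.OS, grid=left),
    )


DEFAULT_MODE_MIX: dict[AsymmetryMode, float] = {
    AsymmetryMode.NONE: 0.80,
    AsymmetryMode.TILT: 0.07,
    AsymmetryMode.CONE: 0.07,
    AsymmetryMode.FOUR_LEAF: 0.04,
    AsymmetryMode.MIXED: 0.02,
}


def generate_cohort(
    n: int,
    mode_mix: dict[AsymmetryMode, float] | None = None,
    amplitude_range: tuple[float, float] = (15.0, 40.0),
    noise_sd: float = 1.0,
    dropout_fraction: float = 0.02,
    seed: int = 0,
) -> tuple[list[CasePair], pd.DataFrame]:
    """Generate ``n`` cases with per-case sampled modes and amplitudes.

    Returns the pairs and a ground-truth table (case_id, mode and the
    sampled parameters).  Amplitudes are drawn uniformly from
    ``amplitude_range``; axes uniformly over their period.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    mix = mode_mix if mode_mix is not None else DEFAULT_MODE_MIX
    modes = list(mix)
    probs = np.array([mix[m] for m in modes], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("mode proportions must sum to 1")

    rng = np.random.default_rng(seed)
    drawn = rng.choice(len(modes), size=n, p=probs)
    pairs: list[CasePair] = []
    truth_rows = []
    for i in range(n):
        mode = modes[drawn[i]]
        amp = float(rng.uniform(*amplitude_range))
        params = SyntheticParams(
            case_id=f"SYN{i:04d}",
            asymmetry_mode=mode,
            tilt_amplitude=amp,
            cone_amplitude=amp,
            astig_amplitude=amp,
            tilt_axis=float(rng.uniform(0.0, 360.0)),
            astig_axis=float(rng.uniform(0.0, 180.0)),
            noise_sd=noise_sd,
            dropout_fraction=dropout_fraction,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pairs.append(generate_pair(params))
        truth_rows.append(
            {
                "case_id": params.case_id,
                "mode": mode.value,
                "amplitude_um": amp if mode is not AsymmetryMode.NONE else 0.0,
                "tilt_axis_deg": params.tilt_axis,
                "astig_axis_deg": params.astig_axis,
                "noise_sd_um": noise_sd,
                "seed": params.seed,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("case_id")
    return pairs, truth


def generate_screening_cohort(
    n: int,
    fractions: tuple[float, float, float] = (0.80, 0.15, 0.05),
    moderate_range: tuple[float, float] = (5.0, 15.0),
    large_range: tuple[float, float] = (30.0, 80.0),
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[CasePair], pd.DataFrame]:
    """Cohort with a screening-like severity structure.

    ``fractions`` of cases are symmetric (no injected asymmetry),
    moderately asymmetric, and largely asymmetric; asymmetric cases get
    a random single mode with amplitude drawn from the matching range.
    Ground truth labels the severity group.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("severity fractions must sum to 1")
    rng = np.random.default_rng(seed)
    severities = rng.choice(3, size=n, p=np.asarray(fractions, dtype=float))
    single_modes = [AsymmetryMode.TILT, AsymmetryMode.CONE, AsymmetryMode.FOUR_LEAF]
    pairs: list[CasePair] = []
    rows = []
    for i in range(n):
        sev = int(severities[i])
        if sev == 0:
            mode, amp = AsymmetryMode.NONE, 0.0
        else:
            mode = single_modes[int(rng.integers(0, 3))]
            amp = float(rng.uniform(*(moderate_range if sev == 1 else large_range)))
        params = SyntheticParams(
            case_id=f"SYN{i:04d}",
            asymmetry_mode=mode,
            tilt_amplitude=amp,
            cone_amplitude=amp,
            astig_amplitude=amp,
            tilt_axis=float(rng.uniform(0.0, 360.0)),
            astig_axis=float(rng.uniform(0.0, 180.0)),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pairs.append(generate_pair(params))
        rows.append(
            {
                "case_id": params.case_id,
                "severity": ["symmetric", "moderate", "large"][sev],
                "mode": mode.value,
                "amplitude_um": amp,
            }
        )
    truth = pd.DataFrame(rows).set_index("case_id")
    return pairs, truth


def write_cohort(
    pairs: Sequence[CasePair],
    truth: pd.DataFrame,
    directory: str | Path,
    dialect: FormatDialect = DEFAULT_DIALECT,
) -> Path:
    """Write a cohort as elevation files plus a ground-truth CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for pair in pairs:
        for emap in (pair.right, pair.left):
            write_elevation_file(emap, directory / f"{emap.case_id}_{emap.eye.value}.csv", dialect)
    truth.to_csv(directory / "ground_truth.csv")
    return directory
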