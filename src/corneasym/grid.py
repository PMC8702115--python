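"""Canonical grid geometry for Pentacam-style anterior elevation exports.

Every elevation map handled by this package lives on the same lattice: a
141 x 141 grid with 0.1 mm pitch covering 14 x 14 mm, centered on the
corneal apex.  The apex sits at grid index (70, 70).  Grid index
``(row i, col j)`` maps to physical coordinates

    x = (j - 70) * 0.1 mm      (increases rightward)
    y = (70 - i) * 0.1 mm      (increases upward; row 0 is the top)

Missing cells are represented as NaN throughout the package.
"""

from __future__ import annotations

import numpy as np

GRID_SIZE: int = 141
SPACING_MM: float = 0.1
CENTER_INDEX: int = 70
EXTENT_MM: float = GRID_SIZE * SPACING_MM  # 14.1 mm span of cell centers +/- half cell
CELL_AREA_MM2: float = SPACING_MM * SPACING_MM  # 0.01 mm^2


def x_coords() -> np.ndarray:
    """Physical x coordinate (mm) of every column, shape (141,)."""
    return (np.arange(GRID_SIZE) - CENTER_INDEX) * SPACING_MM


def y_coords() -> np.ndarray:
    """Physical y coordinate (mm) of every row, shape (141,)."""
    return (CENTER_INDEX - np.arange(GRID_SIZE)) * SPACING_MM


def coordinate_grids() -> tuple[np.ndarray, np.ndarray]:
    """Full (X, Y) coordinate arrays in mm, each shaped (141, 141)."""
    X, Y = np.meshgrid(x_coords(), y_coords())
    return X, Y


def radius_grid() -> np.ndarray:
    """Distance of every cell center from the apex, in mm."""
    X, Y = coordinate_grids()
    return np.hypot(X, Y)
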