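"""Fellow-eye difference matrices.

Normal fellow corneas are approximately mirror (enantiomorphic) images of
each other.  Flipping the left-eye elevation grid about its vertical axis
brings anatomically corresponding points (nasal/temporal) into register
with the right eye; subtracting the right-eye grid from the flipped
left-eye grid then uses the contralateral cornea as the reference
surface.  A perfectly mirror-symmetric pair yields an all-zero
difference map.

Sign convention: ``difference = flipped_left - right``, so positive
values mean the left cornea is more elevated at that mirrored location.
No pre-registration (apex alignment or iterative closest point) is
applied: raw corresponding-point subtraction is the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GRID_SIZE, SPACING_MM
from .io import CasePair, ElevationMap, Eye


@dataclass
class DifferenceMap:
    """Interocular elevation difference grid (um), flipped-left minus right.

    A cell is NaN wherever either source cell is missing.
    """

    case_id: str
    grid: np.ndarray
    spacing: float = SPACING_MM
    flipped: bool = True  # False when built with direct (unflipped) symmetry

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(
                f"difference grid must be {GRID_SIZE}x{GRID_SIZE}, got {self.grid.shape}"
            )
        if np.isinf(self.grid).any():
            raise ValueError("difference values must be finite or NaN")

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.grid).sum())

    def to_elevation_map(self) -> ElevationMap:
        """View as an :class:`ElevationMap` for serialization (DIFF flag set)."""
        return ElevationMap(
            case_id=self.case_id, eye=Eye.OD, grid=self.grid.copy(), is_difference=True
        )

    @classmethod
    def from_elevation_map(cls, emap: ElevationMap) -> "DifferenceMap":
        return cls(case_id=emap.case_id, grid=emap.grid.copy())


def flip_horizontal(emap: ElevationMap) -> ElevationMap:
    """Mirror a map about its vertical axis: output (i, j) = input (i, 140 - j).

    This is the 180-degree rotation about the map's Y axis that aligns a
    left eye with its fellow right eye.  An up-down flip would have no
    anatomical meaning here.
    """
    return ElevationMap(
        case_id=emap.case_id,
        eye=emap.eye,
        grid=emap.grid[:, ::-1].copy(),
        flipped=not emap.flipped,
        is_difference=emap.is_difference,
    )


def difference_map(pair: CasePair, flip: bool = True) -> DifferenceMap:
    """Build the fellow-eye difference matrix for a bilateral case.

    Parameters
    ----------
    pair : CasePair
        Matched OD/OS elevation maps.
    flip : bool
        Mirror the left eye first (the method's default).  ``flip=False``
        performs direct, unflipped subtraction — useful only for
        exploring direct-symmetry cases such as the 4-leaf pattern.
    """
    left = flip_horizontal(pair.left) if flip else pair.left
    with np.errstate(invalid="ignore"):
        grid = left.grid - pair.right.grid
    return DifferenceMap(case_id=pair.case_id, grid=grid, flipped=flip)


def swap_eyes(pair: CasePair) -> CasePair:
    """Exchange the roles of the two eyes (relabelling OD<->OS).

    Useful for the antisymmetry identity: if D is the difference map of a
    pair, the swapped pair's difference map is exactly -flip(D).
    """
    right = pair.left.copy()
    right.eye = Eye.OD
    left = pair.right.copy()
    left.eye = Eye.OS
    return CasePair(case_id=pair.case_id, right=right, left=left,
                    right_meta=pair.left_meta, left_meta=pair.right_meta)
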