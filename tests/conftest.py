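import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from corneasym import CasePair, ElevationMap, Eye
from corneasym.grid import GRID_SIZE
from corneasym.symmetry import DifferenceMap


def make_map(grid, case_id="C1", eye=Eye.OD) -> ElevationMap:
    return ElevationMap(case_id=case_id, eye=eye, grid=np.asarray(grid, dtype=float))


def make_diff(grid, case_id="C1") -> DifferenceMap:
    return DifferenceMap(case_id=case_id, grid=np.asarray(grid, dtype=float))


def random_map(rng, case_id="C1", eye=Eye.OD, missing_fraction=0.0, scale=10.0) -> ElevationMap:
    grid = rng.normal(0.0, scale, (GRID_SIZE, GRID_SIZE))
    if missing_fraction > 0:
        grid[rng.random(grid.shape) < missing_fraction] = np.nan
    return make_map(grid, case_id, eye)


def random_pair(rng, case_id="C1", missing_fraction=0.0) -> CasePair:
    return CasePair(
        case_id=case_id,
        right=random_map(rng, case_id, Eye.OD, missing_fraction),
        left=random_map(rng, case_id, Eye.OS, missing_fraction),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
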