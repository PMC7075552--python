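import numpy as np
import pytest
from hypothesis import settings

from vinespread.kernel import DEFAULT_CONSTRAINTS, calibrate_kernel
from vinespread.landscape import GridSpec, OccupancyGrid

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_kernel():
    """Kernel calibrated to the default (30 m, 90%) / (1610 m, 0.05%) pair."""
    return calibrate_kernel(*DEFAULT_CONSTRAINTS)


@pytest.fixture
def line_grid():
    """A 1x8 strip of 500 m cells; handy for controlled source/target setups."""
    return GridSpec(n_rows=1, n_cols=8, cell_size_m=500.0)


def make_occupancy(spec, occupied, masked):
    """Build an OccupancyGrid from lists of (row, col) indices."""
    cells = np.zeros(spec.shape, dtype=np.uint8)
    mask = np.zeros(spec.shape, dtype=np.uint8)
    for rc in masked:
        mask[rc] = 1
    for rc in occupied:
        cells[rc] = 1
    return OccupancyGrid(spec=spec, cells=cells, mask=mask)
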