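import warnings

import numpy as np
import pytest

import pyrogrid as pg


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Generator/fit warnings (dropped records, floored precip) are expected."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def small_grid() -> pg.GridSpec:
    """5x5 one-degree lattice for impulse/assignment tests."""
    return pg.make_grid((0.0, 5.0, 0.0, 5.0))


@pytest.fixture(scope="session")
def default_world() -> pg.World:
    """One shared synthetic world under the default study conditions."""
    return pg.make_world(seed=1234)


def impulse_field(grid: pg.GridSpec, cell_id: int, amount: float = 100.0,
                  year: int = 2000) -> pg.AnnualField:
    values = np.zeros((grid.n_cells, 1))
    values[cell_id, 0] = amount
    return pg.AnnualField(grid, [year], values, name="AAB", units="ha")
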