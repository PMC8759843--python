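import numpy as np
import pytest

import ecofrac as ef


@pytest.fixture(scope="session")
def case1():
    return ef.default_case(0.5)


@pytest.fixture(scope="session")
def traj_case1(case1):
    return ef.solve_case(case1)


@pytest.fixture(scope="session")
def split101():
    return ef.split_indices(101, seed=1)


@pytest.fixture(scope="session")
def sin_trajectory():
    """Smooth single-output fitting target on the standard 101-point grid."""
    grid = ef.Grid(t0=0.0, h=0.01, n_steps=100)
    states = np.sin(2 * np.pi * grid.times)[:, None]
    return ef.Trajectory(grid=grid, states=states)
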