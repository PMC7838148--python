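import numpy as np
import pytest

import glioextent as ge
from glioextent.scenarios import gaussian_ic


@pytest.fixture(scope="session")
def forward_1d_reference():
    """Nondimensional 1D forward run at the reference resolution.

    Domain [0, 200] with 1000 elements, rho = D = 1, centered unit
    Gaussian of sd 1, implicit Euler dt = 0.1 to t = 20, checkpoints at
    unit times.  Shared by the front-speed and stationalization tests.
    """
    grid = ge.build_grid((200.0,), (1000,))
    field = ge.homogeneous_field(grid, 1.0)
    ic = gaussian_ic(grid, 1.0, 1.0)
    controls = ge.TimeControls(
        t_end=20.0, dt=0.1, checkpoints=tuple(float(k) for k in range(1, 21))
    )
    trajectory, report = ge.solve_forward(grid, field, ge.ModelParams(), ic, controls)
    return grid, field, trajectory, report


@pytest.fixture(scope="session")
def stationary_1d_reference(forward_1d_reference):
    """Stationary estimate pinned at theta = 0.16 from the t = 20 forward
    solution of the reference 1D run."""
    grid, field, trajectory, _ = forward_1d_reference
    u_pin = trajectory[-1][1]
    constraints = ge.extract_constraints(u_pin, 0.16)
    u_s, report = ge.solve_stationary(grid, field, ge.ModelParams(), constraints)
    return grid, u_pin, u_s, constraints, report


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
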