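import numpy as np
import pytest

import theatresmoke as ts
from theatresmoke.solver import SolverSettings


@pytest.fixture(scope="session")
def default_calib():
    return ts.CalibrationSet()


@pytest.fixture(scope="session")
def coarse_mesh():
    """The standard desk-scale grid (0.2 m cells)."""
    return ts.build_mesh(ts.TheatreScene(), (40, 30, 15))


@pytest.fixture(scope="session")
def small_mesh():
    return ts.build_mesh(ts.TheatreScene(), (20, 15, 9))


@pytest.fixture(scope="session")
def unforced_isothermal_state(small_mesh):
    """Zero-source room with exterior walls at inlet temperature: the pure
    ventilation downflow, used by several conservation/limit tests."""
    bc = ts.BoundaryConditionSet(wall_exterior_temp=27.0)
    return ts.solve_steady(small_mesh, bc, None,
                           SolverSettings(tolerance=1e-4, max_iterations=2500))


@pytest.fixture(scope="session")
def hot_case_small(small_mesh):
    """A converged 500 degC case on the small grid, shared by the
    dispersed-phase and exposure tests."""
    spec = ts.make_source_spec(500.0)
    return ts.solve_steady(small_mesh, ts.BoundaryConditionSet(), spec,
                           SolverSettings(tolerance=1e-3, max_iterations=2500))
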