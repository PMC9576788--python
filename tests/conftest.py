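import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import osmoengine as oe

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return oe.default_parameters()


@pytest.fixture(scope="session")
def opts32():
    return oe.SolverOptions(grid_size=32)


@pytest.fixture(scope="session")
def baseline32(params, opts32):
    """Converged baseline steady state at N=32, shared across the suite."""
    return oe.solve_steady(params, opts32)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def smooth_profiles(params, n):
    """Smooth synthetic field profiles for residual/oracle tests.

    Not a solution of the model; strictly positive concentrations with
    nontrivial gradients everywhere.
    """
    L = params.cell_length
    x = np.linspace(0.0, L, n)
    s = np.sin(np.pi * x / L)
    s2 = np.sin(2 * np.pi * x / L)
    c = np.cos(np.pi * x / L)
    return oe.FieldProfiles(
        x=x,
        p=200.0 * s + 30000.0,
        v_n=0.01 * c,
        theta_n=0.3 + 0.1 * s2,
        theta_c=0.25 - 0.05 * s,
        c_na=35.0 + 3.0 * s,
        c_k=100.0 + 5.0 * c,
        c_cl=35.0 - 4.0 * s2,
        ph=7.2 + 0.1 * s,
        c_a=65.0 + 5.0 * c,
        c_buf=25.0 + 2.0 * s,
        phi=-45.0 + 5.0 * s2,
        v_c=2.0e-4,
    )
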