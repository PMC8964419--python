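import pytest

from strandlogic.kinetic_network import KineticParams
from strandlogic.ode_engine import SolverSettings, default_grid


@pytest.fixture(scope="session")
def params() -> KineticParams:
    """Calibrated default parameter set shared across tests."""
    return KineticParams()


@pytest.fixture()
def fast_settings() -> SolverSettings:
    """Looser tolerances for tests that don't probe conservation accuracy."""
    return SolverSettings(rtol=1e-7, atol=1e-10)


@pytest.fixture()
def short_settings() -> SolverSettings:
    return SolverSettings(rtol=1e-7, atol=1e-10, t_grid=default_grid(60))
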