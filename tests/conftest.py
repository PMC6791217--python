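import numpy as np
import pytest

from oncodelay import integrate
from oncodelay.scenarios import preset
from oncodelay.solver import SolverConfig


@pytest.fixture(scope="session")
def fig3():
    return preset("fig3")


@pytest.fixture(scope="session")
def fig4():
    return preset("fig4")


@pytest.fixture(scope="session")
def fig5():
    return preset("fig5")


@pytest.fixture(scope="session")
def fig7():
    return preset("fig7")


@pytest.fixture(scope="session")
def fig3_traj_full(fig3):
    """Subthreshold scenario integrated over the full 2000-day horizon."""
    return integrate(fig3.params, fig3.history, fig3.solver)


@pytest.fixture(scope="session")
def fig4_traj_full(fig4):
    """Endemic multi-delay scenario over the full 2000-day horizon."""
    return integrate(fig4.params, fig4.history, fig4.solver)


@pytest.fixture(scope="session")
def fig3_traj_short(fig3):
    return integrate(fig3.params, fig3.history, SolverConfig(t_end=300.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
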