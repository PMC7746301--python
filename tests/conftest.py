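import numpy as np
import pytest

from loopstate.model_core import als_network, unit_parameterization
from loopstate.scenario import reference_parameterization
from loopstate.structural_analysis import interaction_matrix


@pytest.fixture(scope="session")
def als_net():
    return als_network()


@pytest.fixture(scope="session")
def S_als(als_net):
    return interaction_matrix(als_net)


@pytest.fixture(scope="session")
def fixture_params():
    """The pinned bistable instance (unit parameters, hill 4, u=2, mu=1.3)."""
    return reference_parameterization()


@pytest.fixture(scope="session")
def unit_params():
    return unit_parameterization(hill=4.0, u=0.0, mu=1.0)


@pytest.fixture(scope="session")
def fixture_equilibria(fixture_params):
    from loopstate.dynamics import find_equilibria

    return find_equilibria(fixture_params, n_starts=64, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
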