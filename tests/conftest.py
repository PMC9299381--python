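import numpy as np
import pytest

from lactonet import CellParams, SimulationConfig, make_multi_arm, make_pair


@pytest.fixture(scope="session")
def params():
    return CellParams()


@pytest.fixture(scope="session")
def pair():
    return make_pair()


@pytest.fixture(scope="session")
def multiarm():
    return make_multi_arm()


@pytest.fixture
def short_config():
    """Cheap integration protocol for smoke tests (not asymptotic)."""
    return SimulationConfig(t_total=20_000.0, t_analysis=10_000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
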