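import numpy as np
import pytest

from mscsim import DifferentiationParams, MechanicsParams, OxygenEnvironment


@pytest.fixture(scope="session")
def diff_params():
    return DifferentiationParams()


@pytest.fixture(scope="session")
def mech():
    return MechanicsParams()


@pytest.fixture(scope="session")
def env5(diff_params):
    return OxygenEnvironment.from_percent(5.0, diff_params)


@pytest.fixture(scope="session")
def env20(diff_params):
    return OxygenEnvironment.from_percent(20.0, diff_params)


@pytest.fixture(scope="session")
def env_anoxic(diff_params):
    """pO2 = 0: the Hill response vanishes and the noise is state-independent."""
    return OxygenEnvironment.from_percent(0.0, diff_params)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
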