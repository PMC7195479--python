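import numpy as np
import pytest
from hypothesis import settings

from clicknorm.task import TaskProtocol, generate_click_train
from clicknorm.divnorm import DivNormParams

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def proto() -> TaskProtocol:
    return TaskProtocol()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def train(proto, rng):
    """One fixed random 20-click train under the default protocol."""
    return generate_click_train(proto, "L", rng)


@pytest.fixture
def exemplar_params() -> DivNormParams:
    """The published exemplar dynamics parameters (tau in seconds)."""
    return DivNormParams(tau_R=2.27, tau_G=11.10, omega_I=36.20)
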