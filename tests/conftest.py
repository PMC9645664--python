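import numpy as np
import pytest

from reachadapt import lqg
from reachadapt.plant import build_plant


@pytest.fixture(scope="session")
def plant():
    """Default deterministic plant (filter noise floors still active)."""
    return build_plant(dt=0.01, mass=1.0, actuator_tau=0.1, obs_noise_scale=1e-3)


@pytest.fixture(scope="session")
def weights():
    return lqg.CostWeights()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
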