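import numpy as np
import pytest

from smalex import FluorophoreState, SimulationConfig

NO_BACKGROUND = (0.0, 0.0, 0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_config(e_app=0.58, s_app=0.5, alpha=1.0, seed=0, **kwargs):
    """Single-state simulation config with background off unless requested."""
    state = FluorophoreState("state", e_app, s_app, pife_alpha=alpha)
    kwargs.setdefault("background_rates", NO_BACKGROUND)
    return SimulationConfig(states=(state,), weights=(1.0,), seed=seed, **kwargs)


@pytest.fixture
def single_state_config():
    return make_config()
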