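import numpy as np
import pytest

from facemix.mesh import make_neutral_mesh
from facemix.motion import ActorMotionParams


@pytest.fixture(scope="session")
def toy_mesh():
    return make_neutral_mesh("toy", 64)


@pytest.fixture(scope="session")
def small_mesh():
    return make_neutral_mesh("toy", 16)


@pytest.fixture
def quiet_params():
    """Motion with every stochastic/noise component switched off."""
    return ActorMotionParams(
        head_rot_amp=(0.0, 0.0, 0.0),
        head_trans_amp=(0.0, 0.0, 0.0),
        walk_sd=0.0,
        head_gesture_rate=0.0,
        action_rate=0.0,
        blink_amp=0.0,
        mouth_amp=0.0,
        noise_sd=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
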