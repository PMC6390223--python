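import numpy as np
import pytest

from graspbias import ObjectPose, SimConfig
from graspbias.config import START_POSITION

START = np.asarray(START_POSITION)


@pytest.fixture
def pose_150():
    return ObjectPose(theta=150.0)


@pytest.fixture
def pose_60():
    return ObjectPose(theta=60.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20190224)


def make_sim(**kw) -> SimConfig:
    """Study-design simulation config with keyword overrides."""
    return SimConfig(**kw)
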