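import numpy as np
import pytest

from beltquest import QuestParams


@pytest.fixture
def default_params() -> QuestParams:
    """Study defaults: log-scale staircase, prior mode 0.1 m/s."""
    return QuestParams()


@pytest.fixture
def linear_params() -> QuestParams:
    """Linear-scale variant (Weibull argument in plain m/s)."""
    return QuestParams(scale="linear")


@pytest.fixture
def coarse_linear_params() -> QuestParams:
    """Coarse linear grid (~112 points) for brute-force posterior oracles."""
    return QuestParams(scale="linear", grid_step=0.008)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
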