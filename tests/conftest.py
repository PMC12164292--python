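import numpy as np
import pytest

from digitclock.clock_sim import ClockParams, RenderConfig
from digitclock.core_phenotype import ClockWindow, DigitID


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def window():
    return ClockWindow()


def digit(index=3, limb="forelimb"):
    return DigitID(limb, index)


@pytest.fixture
def params5(window):
    """A clawed 5-phalanx digit covering the whole window."""
    return ClockParams(digit=digit(4), phalanx_count=5, window=window)


@pytest.fixture
def noiseless_cfg():
    return RenderConfig(profile_length_px=500, noise_sd=0.0, seed=7)
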