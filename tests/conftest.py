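import numpy as np
import pytest

from resmtunet import ResMTUNet, SynthSpec, make_roi_dataset, make_slide, tiny_config


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_net():
    """1/8-width model for a 64px input, shared across read-only tests."""
    return ResMTUNet(tiny_config(input_size=64, seed=1))


@pytest.fixture(scope="session")
def roi_samples():
    return make_roi_dataset(SynthSpec(seed=7, canvas=64), 8)


@pytest.fixture(scope="session")
def small_slide():
    """1024px synthetic slide: fast to build, exercises every class."""
    return make_slide(SynthSpec(seed=3, slide_size=1024))
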