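import numpy as np
import pytest
from hypothesis import settings

from periquant import ImagingConfig

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cfg():
    """Short-acquisition imaging config for fast unit tests."""
    return ImagingConfig(n_frames=40, seed=7)


@pytest.fixture
def cfg_full():
    """Default full-length acquisition (250 frames at 30 Hz)."""
    return ImagingConfig(seed=7)
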