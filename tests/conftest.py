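import numpy as np
import pytest

from dffpipe import AnalysisWindow, ImageSequence, SurrogateConfig, generate_recording


@pytest.fixture
def window():
    """Standard 40-frame analysis window: onset 11, response 14..26 (0-based)."""
    return AnalysisWindow(
        onset=11, a=14, b=26, pre_start=6, lowpass_width=5, pre_average_width=5
    )


@pytest.fixture
def small_cfg():
    """Small surrogate geometry used throughout the unit tests."""
    return SurrogateConfig(width=64, height=48, magnitude=0.02, noise_level=0.05, seed=0)


@pytest.fixture
def small_recording(small_cfg):
    return generate_recording(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sequence(frames, **kw):
    return ImageSequence(frames=np.asarray(frames, dtype=float), **kw)
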