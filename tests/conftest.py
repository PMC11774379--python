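import numpy as np
import pytest

from waveclean.config import PipelineConfig, slide_windows


@pytest.fixture
def small_config() -> PipelineConfig:
    """Compact blink instantiation: 1 s windows at 128 Hz (128 samples,
    7 levels, 64 columns), 4-window buffer, 64-vector sub-samples."""
    return PipelineConfig(
        sampling_rate=128.0,
        buffer_capacity=4,
        if_subsample=64,
        if_trees=30,
        expansion_step=5,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_windows(small_config, rng):
    """Six consecutive windows of Gaussian noise."""
    signal = rng.standard_normal(6 * small_config.samples_per_window)
    return slide_windows(signal, small_config)
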