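import numpy as np
import pytest

from slidekin import TrajectorySimConfig, default_calibration


@pytest.fixture(scope="session")
def calib():
    return default_calibration()


@pytest.fixture
def clean_config():
    """Noiseless, photophysics-free config for exact-recovery tests."""
    return TrajectorySimConfig(
        n_frames=600,
        noise_sd=0.0,
        bleach_mean_s=None,
        blink_rate_per_s=0.0,
        backtrack_prob=0.0,
        step1_bp_sd=0.0,
        step2plus_bp_sd=0.0,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
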