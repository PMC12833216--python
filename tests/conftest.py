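import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from orientnn.simulate import GaitSimConfig, generate_trial


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_trial():
    """Short uncorrupted trial: sensors equal segments, angles exact."""
    cfg = GaitSimConfig(duration_s=20.0, mounting_offset_deg=0.0,
                        soft_tissue_amp_deg=0.0, meas_noise_deg=0.0, seed=3)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def offsets_trial():
    """Short trial with static mounting offsets only (exactly solvable)."""
    cfg = GaitSimConfig(duration_s=60.0, soft_tissue_amp_deg=0.0,
                        meas_noise_deg=0.0, seed=5)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def corrupted_trial():
    """Short trial with all corruption mechanisms at their defaults."""
    cfg = GaitSimConfig(duration_s=60.0, seed=7)
    return generate_trial(cfg)
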