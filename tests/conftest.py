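import numpy as np
import pytest

from freshnir import GeneratorConfig, generate_dataset
from freshnir.synthetic_data import recovery_config


@pytest.fixture(scope="session")
def default_dataset():
    """Full-scale default synthetic study (180 samples x 1921 channels)."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale dataset for fast stage tests (60 samples x 120 channels)."""
    cfg = GeneratorConfig(
        seed=7, n_samples_per_group_day=1, n_channels=120,
        wavelength_step_nm=1920.0 / 119,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def recovery_dataset():
    """Selector-recovery benchmark: 8 comparably informative bands, SNR~20."""
    cfg = recovery_config(seed=3)
    return cfg, generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
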