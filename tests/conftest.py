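import numpy as np
import pytest

from stentropy import (
    EmotiveEEGSpec,
    ExtractionConfig,
    band_series_tensors,
    make_emotive_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Compact three-class dataset with a strong Gamma-band effect."""
    return EmotiveEEGSpec(
        n_channels=16,
        n_epochs_per_class=15,
        effect_gain=6.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return make_emotive_dataset(small_spec)


@pytest.fixture(scope="session")
def small_band_series(small_dataset):
    """Band magnitude tensors for the small dataset (expensive; shared)."""
    cfg = ExtractionConfig()
    return band_series_tensors(small_dataset, cfg)


@pytest.fixture(scope="session")
def small_labels(small_dataset):
    return np.array([ep.label for ep in small_dataset], dtype=int)
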