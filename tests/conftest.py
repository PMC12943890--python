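import numpy as np
import pytest

from motiontape.classify import ClassifierConfig
from motiontape.generate import CVAEConfig, DiffusionConfig
from motiontape.preprocess import process_cohort
from motiontape.simdata import CohortConfig, make_cohort


@pytest.fixture(scope="session")
def tiny_config():
    """2 subjects, T=32, light noise: 36 trials."""
    return CohortConfig(n_subjects=2, duration=0.64, noise_sd=0.02, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return make_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_processed(tiny_cohort):
    processed, _ = process_cohort(tiny_cohort)
    return processed


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, zero-overlap cohort for separability checks (T=64)."""
    return CohortConfig(
        n_subjects=3, duration=1.28, noise_sd=0.0, class_overlap=0.0, seed=21
    )


@pytest.fixture(scope="session")
def clean_processed(clean_config):
    processed, _ = process_cohort(make_cohort(clean_config))
    return processed


@pytest.fixture(scope="session")
def fast_cvae():
    return CVAEConfig(epochs=30, seed=5)


@pytest.fixture(scope="session")
def fast_diffusion():
    return DiffusionConfig(epochs=10, sampling_steps=20, hidden_dim=32, decoder_layers=4, seed=5)


@pytest.fixture(scope="session")
def fast_cnn_lstm():
    return ClassifierConfig(
        kind="cnn_lstm",
        lstm_hidden=24,
        conv_channels=(8, 16),
        epochs=25,
        early_stop_patience=8,
        seed=5,
    )


@pytest.fixture(scope="session")
def fast_transformer():
    return ClassifierConfig(kind="transformer", encoder_layers=2, epochs=25, seed=5)


@pytest.fixture(scope="session")
def fast_gbt():
    return ClassifierConfig(kind="gbt", gbt_n_estimators=60, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
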