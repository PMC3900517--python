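import numpy as np
import pytest

from popdecode.preprocess import make_seeds
from popdecode.synth import GeneratorConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def endo_dataset():
    """Moderate-SNR endogenous dataset: 40 cells, 12 attention-selective."""
    cfg = GeneratorConfig(
        n_cells=40, fraction_visual=0.6, fraction_attention=0.3,
        n_trials_mean=80, n_trials_sd=10, rng_seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def endo_seeds(endo_dataset):
    return make_seeds(endo_dataset, 101, n_seeds=4)


@pytest.fixture(scope="session")
def noise_dataset():
    """Pure-noise population: every cell unselective, labels carry nothing."""
    cfg = GeneratorConfig(
        n_cells=10, fraction_visual=0.0, fraction_attention=0.0,
        trial_duration=320, n_trials_mean=60, n_trials_sd=0, rng_seed=5,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, widely separated classes: 20 cells, 60 trials/condition."""
    cfg = GeneratorConfig(
        n_cells=20, fraction_visual=0.0, fraction_attention=1.0,
        attention_gain=40.0, baseline_rate=5.0, noise="none",
        trial_duration=420, n_trials_mean=60, n_trials_sd=0, rng_seed=3,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_seeds(clean_dataset):
    return make_seeds(clean_dataset, 42, n_seeds=2)
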