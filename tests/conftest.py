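import numpy as np
import pytest

from ricenc import SyntheticConfig, generate_trial


@pytest.fixture(scope="session")
def noise_free_trial():
    """Noise-free 29-group trial sharing one true curve (3.36, 0.30)."""
    cfg = SyntheticConfig(
        pop_mean_a=3.36, pop_mean_b=0.30, pop_sd_a=0.0, pop_sd_b=0.0,
        dw_noise_sd=0.0, n_noise_sd=0.0, seed=11,
    )
    samples, truth = generate_trial(cfg)
    return cfg, samples, truth


@pytest.fixture(scope="session")
def default_trial():
    """Default study conditions: 29 groups with population-drawn curves."""
    cfg = SyntheticConfig(seed=42)
    samples, truth = generate_trial(cfg)
    return cfg, samples, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
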