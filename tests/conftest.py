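import numpy as np
import pytest

from nmfrank import SyntheticSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy synthetic dataset with 3 planted components."""
    return generate(SyntheticSpec(k0=3, m=30, n=60, seed=42))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Exactly rank-3 non-negative matrix (no noise, no fold)."""
    return generate(SyntheticSpec(k0=3, m=30, n=60, noise_sd_frac=0.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
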