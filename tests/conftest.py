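import numpy as np
import pytest

from actiseq import SyntheticConfig, simulate_sequence


@pytest.fixture(scope="session")
def blobs():
    """Well-separated 3-class Gaussian blobs with sticky Markov labels."""
    cfg = SyntheticConfig(
        n_classes=3, n_features=4, n_windows=120, stickiness=0.9,
        separation=8.0, variance=0.25, seed=42,
    )
    X, y, lengths = simulate_sequence(cfg)
    return X, y, lengths


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
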