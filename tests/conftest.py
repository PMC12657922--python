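import numpy as np
import pytest

from laglayer import (
    EncodingConfig,
    SyntheticConfig,
    generate_neural_dataset,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale chain-regime generator config used across tests."""
    return SyntheticConfig(
        n_words=200,
        n_layers=8,
        embed_dim=32,
        n_electrodes=2,
        sampling_rate=256.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_neural_dataset(small_config)


@pytest.fixture(scope="session")
def small_encoding_config():
    return EncodingConfig(
        lag_min=-300.0, lag_max=600.0, lag_step=25.0, window=200.0, pca_k=20
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
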