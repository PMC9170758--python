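import numpy as np
import pytest

from pulse import ModelConfig, SyntheticConfig, generate_dataset, train
from pulse.seqdata import encode_samples


@pytest.fixture(scope="session")
def small_dataset():
    """Planted-motif benchmark at reduced size for session-wide reuse."""
    return generate_dataset(SyntheticConfig(n_pos=500, n_neg=500, seed=7))


@pytest.fixture(scope="session")
def trained_small_model(small_dataset):
    """Model trained on the small benchmark (capped at 20 epochs)."""
    X, y = encode_samples(small_dataset)
    return train((X, y), None, ModelConfig(seed=1, max_epochs=20))


@pytest.fixture(scope="session")
def tiny_config():
    """A miniature architecture for fast structural/error-path tests."""
    return ModelConfig(
        conv1_filters=8, conv2_filters=4, fc_units=(8,),
        batch_size=16, max_epochs=3, seed=0,
    )
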