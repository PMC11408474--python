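import numpy as np
import pytest

from gaitphase import SyntheticSpec, generate_dataset
from gaitphase.transformer import ModelConfig, init_params


@pytest.fixture(scope="session")
def tiny_config():
    return ModelConfig(n_channels=3, window_len=20, patch_len=5, embed_dim=8,
                       n_heads=2, n_layers=2, dropout=0.0)


@pytest.fixture(scope="session")
def tiny_params(tiny_config):
    return init_params(tiny_config, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """~200 noiseless windows of the default 6-channel synthetic recording."""
    spec = SyntheticSpec(n_strides=3, stride_len_mean=100,
                         stride_len_jitter=0.0, seed=7)
    return generate_dataset(spec, window_len=100, stride=1, label_source="exact")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
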