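import numpy as np
import pytest

from metapathlink.config import ModelConfig, TrainingConfig
from metapathlink.synthetic import SyntheticSpec, fixture_small, generate_synthetic


@pytest.fixture
def small_net():
    """8-node hand-built network: 3 microbes, 2 drugs, 3 diseases."""
    return fixture_small()


@pytest.fixture(scope="session")
def tiny_synth():
    """Small planted-block network for fast training tests."""
    spec = SyntheticSpec(n_m=45, n_c=12, n_d=24, n_blocks=3,
                         p_in=0.35, p_out=0.03, seed=7)
    net, blocks = generate_synthetic(spec)
    return net


@pytest.fixture
def tiny_model_cfg():
    """Small architecture so unit tests stay fast."""
    return ModelConfig(hidden_dim=8, heads=2, attention_dim=6, neighbors=30,
                       layers=2, dropout=0.5)


@pytest.fixture
def fast_train_cfg():
    return TrainingConfig(seed=0, epochs=4, patience=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
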