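import numpy as np
import pytest

from aampnn.data_prep import generate_fixture
from aampnn.encoder import EncoderConfig, init_encoder_params
from aampnn.featurization import featurize_molecule


@pytest.fixture(scope="session")
def fixture_smiles():
    """1000 synthetic drug-like molecules (shared, read-only)."""
    return generate_fixture(1000, seed=42)["smiles"].tolist()


@pytest.fixture(scope="session")
def fixture_graphs(fixture_smiles):
    return [featurize_molecule(s) for s in fixture_smiles]


@pytest.fixture
def small_config():
    return EncoderConfig(hidden_dim=16, message_iterations=3,
                         n_attention_heads=2)


@pytest.fixture
def small_params(small_config):
    rng = np.random.Generator(np.random.PCG64(123))
    return init_encoder_params(rng, small_config)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(7))
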