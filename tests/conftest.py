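import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from kcrnet.embedding import EmbeddingMatrix, build_vocabulary
from kcrnet.network import ModelConfig
from kcrnet.synthetic import SyntheticConfig, generate
from kcrnet.windows import AMINO_ACIDS, PAD_SYMBOL, UNKNOWN_SYMBOL


@pytest.fixture(scope="session")
def full_vocab():
    corpus = [list(AMINO_ACIDS)]
    return build_vocabulary(corpus)


@pytest.fixture(scope="session")
def random_embedding(full_vocab):
    rng = np.random.default_rng(0)
    return EmbeddingMatrix(
        weights=rng.standard_normal((len(full_vocab), 80)), vocabulary=full_vocab
    )


@pytest.fixture(scope="session")
def motif_dataset():
    """300 + 300 windows with a deterministic strong motif."""
    return generate(SyntheticConfig(n_pos=300, n_neg=300, motif_strength=1.0, seed=11))


@pytest.fixture
def tiny_model_config():
    """A scaled-down architecture for fast training tests."""
    return ModelConfig(
        n_blocks=2, layers_per_block=1, growth_rate=8, input_channels=16,
        reduction_ratio=4, fc_sizes=[16], dropout=0.2,
    )
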