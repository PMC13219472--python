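import numpy as np
import pytest

from chemxdl.memory import VectorStore
from chemxdl.providers import HashEmbeddingProvider


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def embedder():
    return HashEmbeddingProvider(dim=256, seed=0)


@pytest.fixture
def store(embedder):
    return VectorStore(embedder)
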