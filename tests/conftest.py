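import numpy as np
import pytest

from semsuggest import (
    EmbeddingModel,
    SynonymSpec,
    TrainingConfig,
    build_huffman,
    build_vocabulary,
    generate_synonym_corpus,
    generate_toy_ontology,
    train,
)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small planted-synonym corpus (3 groups) shared across tests."""
    groups = tuple(frozenset(f"syn{g}_{i}" for i in range(3)) for g in range(3))
    spec = SynonymSpec(groups=groups, n_docs=300, seed=7)
    docs = generate_synonym_corpus(spec)
    return spec, [d.text.split() for d in docs]


@pytest.fixture(scope="session")
def tiny_model(tiny_corpus):
    """A small Skip-gram model trained on the tiny corpus."""
    _, tokens = tiny_corpus
    vocab = build_vocabulary(tokens, min_count=1)
    tree = build_huffman(vocab)
    config = TrainingConfig(architecture="skipgram", dim=16, window=3,
                            epochs=3, seed=11)
    model = train(tokens, vocab, tree, config)
    return vocab, tree, model


@pytest.fixture()
def random_model():
    """Factory for random float32 models with given |V| and dim."""

    def make(n_words: int, dim: int, seed: int = 0) -> EmbeddingModel:
        rng = np.random.default_rng(seed)
        words = [f"w{i:04d}" for i in range(n_words)]
        matrix = rng.normal(size=(n_words, dim)).astype(np.float32)
        return EmbeddingModel(words, matrix)

    return make


@pytest.fixture(scope="session")
def toy_ontology():
    graph, freq = generate_toy_ontology(depth=4, branching=2, seed=3)
    return graph, freq
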