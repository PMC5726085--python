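import numpy as np
import pytest

import citescreen as cs


@pytest.fixture(scope="session")
def small_synth() -> cs.SyntheticCorpus:
    """A small clustered corpus shared by oracle-equivalence tests."""
    return cs.generate_corpus(
        cs.GeneratorParams(
            n=150, m=200, ratio=0.1, n_topics=5, doc_length=60,
            scatter_frac=0.0, rng_seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_features(small_synth):
    vocab = cs.build_vocabulary(small_synth.corpus)
    X = cs.tfidf_matrix(small_synth.corpus, vocab)
    norm = cs.row_normalize(X)
    return X, norm


@pytest.fixture(scope="session")
def small_embedding(small_features):
    _, norm = small_features
    return cs.spectral_embed(norm, p=20, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
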