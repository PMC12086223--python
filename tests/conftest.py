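import numpy as np
import pytest

from lexdrift.embedding import EmbeddingModel, EmbedParams, train_embedding
from lexdrift.preprocess import build_year_corpora
from lexdrift.simulate import SyntheticConfig, generate_corpus


def make_model(year: int, term_vectors: dict[str, list[float]]) -> EmbeddingModel:
    """Hand-built embedding model from explicit vectors (no training)."""
    terms = list(term_vectors)
    vectors = np.asarray([term_vectors[t] for t in terms], dtype=float)
    params = EmbedParams(dim=vectors.shape[1])
    return EmbeddingModel(year=year, terms=terms, vectors=vectors, params=params)


@pytest.fixture(scope="session")
def small_corpus():
    """One-year synthetic corpus small enough for fast unit-level training."""
    cfg = SyntheticConfig(
        years=[2015],
        notes_per_year=500,
        vocab_size=240,
        assoc_schedule={2015: 0.5},
        n_patients=100,
        seed=123,
    )
    notes, _ = generate_corpus(cfg)
    return build_year_corpora(notes)[2015]


@pytest.fixture(scope="session")
def small_model(small_corpus):
    """A trained model with a vocabulary of a couple hundred terms."""
    return train_embedding(
        small_corpus, EmbedParams(dim=50, epochs=3, min_count=5, seed=9)
    )
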