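"""CBOW training contracts, cosine geometry and neighbour queries."""

import numpy as np
import pytest

from lexdrift.association import group_target_similarity
from lexdrift.embedding import (
    EmbeddingModel,
    EmbedParams,
    cosine,
    nearest_neighbors,
    train_embedding,
)
from lexdrift.errors import ConfigurationError, TrainingError, VocabularyError
from lexdrift.preprocess import YearCorpus, count_vocab
from lexdrift.simulate import SyntheticConfig, generate_corpus
from lexdrift.preprocess import build_year_corpora

from conftest import make_model


class TestCosine:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, -1.2, 4.0])
        assert cosine(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)

    def test_forced_geometry(self):
        assert cosine(np.array([1.0, 1.0]), np.array([1.0, 0.0])) == pytest.approx(
            1 / np.sqrt(2)
        )

    def test_zero_vector_is_domain_error(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(3), np.ones(3))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cosine(np.ones(2), np.ones(3))


class TestParams:
    def test_dim_floor(self):
        with pytest.raises(ConfigurationError):
            EmbedParams(dim=1)

    def test_min_count_floor(self):
        with pytest.raises(ConfigurationError):
            EmbedParams(min_count=0)


class TestTraining:
    def test_empty_vocab_error_names_year(self):
        corpus = YearCorpus(2017, [["hapax", "words", "only"]], count_vocab([["hapax", "words", "only"]]))
        with pytest.raises(TrainingError, match="2017"):
            train_embedding(corpus, EmbedParams(min_count=5))

    def test_deterministic_given_seed(self, small_corpus):
        params = EmbedParams(dim=30, epochs=2, seed=4)
        m1 = train_embedding(small_corpus, params)
        m2 = train_embedding(small_corpus, params)
        assert m1.terms == m2.terms
        assert np.array_equal(m1.vectors, m2.vectors)

    def test_vocabulary_floor(self, small_corpus, small_model):
        for t in small_model.terms:
            assert small_corpus.vocab_counts[t] >= small_model.params.min_count

    def test_finite_vectors_of_right_dim(self, small_model):
        assert small_model.vectors.shape == (len(small_model), small_model.params.dim)
        assert np.all(np.isfinite(small_model.vectors))

    def test_planted_association_strengthens_embedding_similarity(self):
        """Base-centroid/target cosine must be larger under strong planted
        co-occurrence than under none, in at least 4 of 5 seeds."""
        wins = 0
        for seed in range(5):
            sims = {}
            for rho in (0.0, 0.9):
                cfg = SyntheticConfig(
                    years=[2013],
                    notes_per_year=800,
                    vocab_size=300,
                    assoc_schedule={2013: rho},
                    n_patients=200,
                    seed=50 + seed,  # same background per seed, both rho arms
                )
                notes, _ = generate_corpus(cfg)
                corpus = build_year_corpora(notes)[2013]
                model = train_embedding(corpus, EmbedParams(dim=60, epochs=4, seed=seed))
                base = [b for b in ("metastatic", "mets", "metastasis", "metastasized") if b in model]
                sims[rho] = group_target_similarity(model, base, "palliative", "centroid").estimate
            wins += sims[0.9] > sims[0.0]
        assert wins >= 4

    def test_save_load_roundtrip(self, small_model, tmp_path):
        path = tmp_path / "model_2015.txt"
        small_model.save(path)
        loaded = EmbeddingModel.load(path)
        assert loaded.terms == small_model.terms
        assert loaded.year == small_model.year
        assert loaded.params == small_model.params
        np.testing.assert_allclose(loaded.vectors, small_model.vectors, rtol=0, atol=1e-15)


class TestNearestNeighbors:
    def test_two_word_vocab_returns_the_other(self):
        model = make_model(2013, {"a": [1.0, 0.0], "b": [0.5, 0.5]})
        assert [t for t, _ in nearest_neighbors(model, "a", 1)] == ["b"]

    def test_capped_at_vocab_with_warning(self, caplog):
        model = make_model(2013, {"a": [1.0, 0.1], "b": [0.5, 0.5], "c": [0.0, 1.0]})
        with caplog.at_level("WARNING"):
            out = nearest_neighbors(model, "a", 50)
        assert len(out) == 2
        assert "exceeds vocabulary size" in caplog.text

    def test_oov_query_names_term_and_year(self, small_model):
        with pytest.raises(VocabularyError, match=r"zzz.*2015"):
            nearest_neighbors(small_model, "zzz", 5)

    def test_full_vocabulary_query(self, small_model):
        out = nearest_neighbors(small_model, small_model.terms[0], len(small_model) - 1)
        assert sorted(t for t, _ in out) == sorted(small_model.terms[1:])

    def test_agrees_with_exhaustive_scan(self, small_model):
        """Independent oracle: cosine to every vocabulary term, one at a time."""
        assert len(small_model) >= 150
        for query in small_model.terms[:3] + small_model.terms[-2:]:
            qv = small_model.vector(query)
            brute = sorted(
                ((t, cosine(small_model.vector(t), qv)) for t in small_model.terms if t != query),
                key=lambda pair: (-pair[1], pair[0]),
            )[:20]
            fast = nearest_neighbors(small_model, query, 20)
            assert [t for t, _ in fast] == [t for t, _ in brute]
            np.testing.assert_allclose(
                [s for _, s in fast], [s for _, s in brute], atol=1e-10
            )

    def test_cosines_invariant_under_common_rotation(self, small_model):
        """Why per-year models need no cross-year alignment."""
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(small_model.params.dim,) * 2))
        rotated = EmbeddingModel(
            year=small_model.year,
            terms=small_model.terms,
            vectors=small_model.vectors @ q,
            params=small_model.params,
        )
        idx = rng.integers(len(small_model), size=(40, 2))
        for i, j in idx:
            a = cosine(small_model.vectors[i], small_model.vectors[j])
            b = cosine(rotated.vectors[i], rotated.vectors[j])
            assert a == pytest.approx(b, abs=1e-8)
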