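"""Per-year CBOW embedding models: training, lookups, similarity queries.

One model is trained per calendar year, on that year's documents only. All
downstream statistics are within-year cosines, which are invariant under any
common orthogonal rotation of a model's vectors — the reason no cross-year
alignment (e.g. Procrustes) is needed or performed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._cbow import train_cbow
from .errors import ConfigurationError, TrainingError, VocabularyError
from .preprocess import YearCorpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbedParams:
    """CBOW hyperparameters. ``workers`` above 1 is accepted but training is
    always single-threaded so that a seed fully determines the vectors."""

    dim: int = 100
    window: int = 5
    min_count: int = 5
    epochs: int = 5
    negative_samples: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    sample: float = 1e-3  # frequent-word subsampling threshold; 0 disables
    seed: int = 0
    workers: int = 1

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ConfigurationError("dim must be >= 2")
        if self.min_count < 1:
            raise ConfigurationError("min_count must be >= 1")
        if self.window < 1 or self.epochs < 1:
            raise ConfigurationError("window and epochs must be positive")
        if self.negative_samples < 0:
            raise ConfigurationError("negative_samples must be non-negative")


@dataclass
class EmbeddingModel:
    """A year's trained term vectors (the word2vec input matrix)."""

    year: int
    terms: list[str]
    vectors: np.ndarray  # (V, dim)
    params: EmbedParams
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {t: i for i, t in enumerate(self.terms)}

    def __contains__(self, term: str) -> bool:
        return term in self._index

    def __len__(self) -> int:
        return len(self.terms)

    def vector(self, term: str) -> np.ndarray:
        try:
            return self.vectors[self._index[term]]
        except KeyError:
            raise VocabularyError(
                f"term {term!r} not in the year-{self.year} vocabulary"
            ) from None

    def save(self, path: str | Path) -> None:
        """Plain-text vectors (term + floats per line) with a JSON sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            for term, vec in zip(self.terms, self.vectors):
                fh.write(term + " " + " ".join(f"{x:.17g}" for x in vec) + "\n")
        sidecar = {"year": self.year, **self.params.__dict__}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        year = meta.pop("year")
        terms, rows = [], []
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                terms.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(year=year, terms=terms, vectors=np.asarray(rows), params=EmbedParams(**meta))


def train_embedding(
    corpus: YearCorpus,
    params: EmbedParams,
    doc_weights: np.ndarray | None = None,
) -> EmbeddingModel:
    """Train one year's CBOW model; deterministic given the seed.

    The vocabulary keeps terms with count >= ``params.min_count``, ordered by
    descending count then lexicographically; rarer tokens are dropped from the
    documents before training. ``doc_weights`` (one per document) scales each
    document's learning-rate contribution; the Bayesian-bootstrap resampler
    uses it to reweight documents without discarding any.
    """
    kept = sorted(
        (t for t, c in corpus.vocab_counts.items() if c >= params.min_count),
        key=lambda t: (-corpus.vocab_counts[t], t),
    )
    if not kept:
        raise TrainingError(
            f"year {corpus.year}: vocabulary empty after min_count={params.min_count} pruning"
        )
    if params.workers != 1:
        logger.warning("workers=%d requested; training runs single-threaded", params.workers)
    index = {t: i for i, t in enumerate(kept)}
    counts = np.array([corpus.vocab_counts[t] for t in kept], dtype=np.float64)
    doc_ids = [
        np.array([index[t] for t in doc if t in index], dtype=np.int64)
        for doc in corpus.docs
    ]
    if doc_weights is not None:
        if len(doc_weights) != len(doc_ids):
            raise ConfigurationError("doc_weights length must match document count")
        doc_weights = np.asarray(
            [w for d, w in zip(doc_ids, doc_weights) if d.size > 0], dtype=np.float64
        )
    doc_ids = [d for d in doc_ids if d.size > 0]
    vectors = train_cbow(
        doc_ids,
        len(kept),
        counts,
        dim=params.dim,
        window=params.window,
        epochs=params.epochs,
        negative=params.negative_samples,
        alpha0=params.alpha,
        min_alpha=params.min_alpha,
        sample=params.sample,
        seed=params.seed,
        doc_weights=doc_weights,
    )
    return EmbeddingModel(year=corpus.year, terms=kept, vectors=vectors, params=params)


def train_yearly(
    corpora: dict[int, YearCorpus], params: EmbedParams, seed_by_year: bool = True
) -> dict[int, "EmbeddingModel"]:
    """Train one model per year; each year gets a distinct derived seed."""
    models = {}
    for i, (year, corpus) in enumerate(sorted(corpora.items())):
        p = replace(params, seed=(params.seed + i) & 0x7FFFFFFF) if seed_by_year else params
        models[year] = train_embedding(corpus, p)
    return models


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; zero vectors are a domain error."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def nearest_neighbors(
    model: EmbeddingModel, term: str, k: int
) -> list[tuple[str, float]]:
    """Top-k highest-cosine vocabulary terms (query excluded), descending;
    ties broken lexicographically. k beyond V-1 is capped with a warning."""
    if k < 0:
        raise ConfigurationError("k must be non-negative")
    query = model.vector(term)  # raises VocabularyError if absent
    if k == 0:
        return []
    norms = np.linalg.norm(model.vectors, axis=1)
    norms[norms == 0.0] = 1.0
    sims = (model.vectors @ query) / (norms * np.linalg.norm(query))
    order = sorted(
        (i for i in range(len(model)) if model.terms[i] != term),
        key=lambda i: (-sims[i], model.terms[i]),
    )
    if k > len(order):
        logger.warning(
            "k=%d exceeds vocabulary size %d for %r (year %d); returning %d",
            k, len(model), term, model.year, len(order),
        )
        k = len(order)
    return [(model.terms[i], float(sims[i])) for i in order[:k]]
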