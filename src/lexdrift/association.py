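"""Group-vs-target cosine association statistics with bootstrap uncertainty.

The primary statistic of the analysis: for each year, how contextually close
is the group of base terms (e.g. the metastatic family) to one target term
(e.g. "palliation")? Three estimators are provided:

``centroid``
    cosine(mean of base-term vectors, target vector) — the headline statistic.
``mean``
    arithmetic mean over base terms of cosine(base, target).
``precision_weighted``
    inverse-variance-weighted mean of the per-term cosines, with each term's
    variance estimated from the spread of its bootstrap replicates. Without a
    bootstrap context it degrades to the plain mean, with a warning.

Uncertainty comes from percentile bootstrap (2.5/97.5) at the document
level with model retraining — by default the Bayesian bootstrap (Exp(1)
document weights), which keeps every distinct document in each replicate;
classical with-replacement resampling and a cheap base-term resampling
screen are also available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import EmbeddingModel, EmbedParams, cosine, train_embedding
from .errors import BootstrapError, VocabularyError
from .preprocess import YearCorpus, count_vocab

logger = logging.getLogger(__name__)

METHODS = ("centroid", "mean", "precision_weighted")
_VAR_FLOOR = 1e-12


@dataclass
class SimilarityEstimate:
    """One year's association estimate for one target term."""

    year: int
    target: str
    method: str
    estimate: float
    ci_low: float = math.nan
    ci_high: float = math.nan
    n_boot: int = 0
    per_term: dict[str, float] = field(default_factory=dict)
    boot_seed: int | None = None

    @property
    def n_base_terms_used(self) -> int:
        return len(self.per_term)


@dataclass
class SimilaritySeries:
    """Per-year estimates for one target, with explicit gaps for years in
    which the target (or the whole base group) was out of vocabulary."""

    target: str
    method: str
    estimates: list[SimilarityEstimate]
    gaps: list[int] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        return [e.year for e in self.estimates]


def _available_base(model: EmbeddingModel, base_terms: Sequence[str]) -> list[str]:
    available = [t for t in base_terms if t in model]
    dropped = [t for t in base_terms if t not in model]
    if dropped:
        logger.warning(
            "base terms %s absent from the year-%d model; using %d of %d",
            dropped, model.year, len(available), len(base_terms),
        )
    return available


def _point_value(
    model: EmbeddingModel,
    base: Sequence[str],
    target: str,
    method: str,
    term_variances: Mapping[str, float] | None,
) -> tuple[float, dict[str, float]]:
    tvec = model.vector(target)
    per_term = {b: cosine(model.vector(b), tvec) for b in base}
    if method == "centroid":
        centroid = np.mean([model.vector(b) for b in base], axis=0)
        value = cosine(centroid, tvec)
    elif method == "mean":
        value = float(np.mean(list(per_term.values())))
    elif method == "precision_weighted":
        if term_variances is None:
            logger.warning(
                "precision_weighted requested without bootstrap variances; "
                "falling back to the arithmetic mean"
            )
            value = float(np.mean(list(per_term.values())))
        else:
            w = np.array([1.0 / max(term_variances.get(b, _VAR_FLOOR), _VAR_FLOOR) for b in base])
            c = np.array([per_term[b] for b in base])
            value = float(np.sum(w * c) / np.sum(w))
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return value, per_term


def group_target_similarity(
    model: EmbeddingModel,
    base_terms: Sequence[str],
    target: str,
    method: str = "centroid",
    term_variances: Mapping[str, float] | None = None,
) -> SimilarityEstimate:
    """Point estimate of the base-group / target association for one year."""
    if target not in model:
        raise VocabularyError(f"target {target!r} not in the year-{model.year} vocabulary")
    base = _available_base(model, base_terms)
    if not base:
        raise VocabularyError(
            f"no base term of {list(base_terms)} in the year-{model.year} vocabulary"
        )
    value, per_term = _point_value(model, base, target, method, term_variances)
    return SimilarityEstimate(
        year=model.year, target=target, method=method, estimate=value, per_term=per_term
    )


def _document_replicates(
    corpus: YearCorpus,
    params: EmbedParams,
    n_boot: int,
    boot_seed: int,
    replicate_epochs: int | None,
    bayesian: bool = False,
) -> tuple[list[EmbeddingModel], int]:
    """Resample documents with replacement and retrain; replicate r resamples
    with RNG seed boot_seed + r. Training keeps the full-data model's seed
    (a conditional bootstrap): replicates then differ from the point estimate
    only through the resampled data, so the replicate distribution is centred
    on the full-data statistic rather than smeared and shifted by independent
    optimiser noise.

    ``bayesian=True`` draws Exp(1) document weights (Rubin's Bayesian
    bootstrap) instead of multinomial duplication: every document stays in
    the replicate corpus with a random weight scaling its learning-rate
    contribution. Classical with-replacement resampling leaves ~37% of
    distinct documents out of each replicate, and an embedding statistic
    trained on less distinct evidence is systematically biased; weighting
    keeps the evidence base intact. Returns the replicate models and the
    discard count."""
    n = corpus.n_docs
    models: list[EmbeddingModel] = []
    discarded = 0
    rep_params = replace(params, epochs=replicate_epochs or params.epochs)
    for r in range(n_boot):
        rng = np.random.default_rng((boot_seed + r) & 0x7FFFFFFF)
        try:
            if bayesian:
                weights = rng.exponential(size=n)
                weights *= n / weights.sum()
                models.append(train_embedding(corpus, rep_params, doc_weights=weights))
            else:
                idx = rng.integers(n, size=n)
                docs = [corpus.docs[i] for i in idx]
                rep_corpus = YearCorpus(
                    year=corpus.year, docs=docs, vocab_counts=count_vocab(docs)
                )
                models.append(train_embedding(rep_corpus, rep_params))
        except Exception:
            discarded += 1
            logger.warning("replicate %d discarded: training failed", r)
    return models, discarded


def bootstrap_year_estimates(
    corpus: YearCorpus,
    params: EmbedParams,
    base_terms: Sequence[str],
    targets: Sequence[str],
    methods: Sequence[str] = METHODS,
    n_boot: int = 100,
    boot_seed: int = 0,
    mode: str = "bayesian",
    replicate_epochs: int | None = None,
    model: EmbeddingModel | None = None,
) -> dict[tuple[str, str], SimilarityEstimate]:
    """Bootstrap one year once, sharing replicate models across every
    (target, method) statistic. Returns estimates keyed by (target, method).

    ``mode="bayesian"`` (default) reweights documents with Exp(1) draws and
    retrains the year's model per replicate; ``mode="documents"`` is the
    classical with-replacement document resample (its replicates see fewer
    distinct documents, which biases embedding statistics down — see
    :func:`_document_replicates`). ``replicate_epochs`` can shorten replicate
    training, at the cost of a replicate distribution that no longer matches
    the full-epochs point statistic — leave unset for calibrated CIs.
    ``mode="terms"`` resamples the base-term set over the fixed model, a
    cheap screen. Replicates in which a target or the whole base group falls
    out of vocabulary are discarded for that statistic; more than 20%
    discards is an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if mode not in ("bayesian", "documents", "terms"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    if model is None:
        model = train_embedding(corpus, params)
    base = _available_base(model, base_terms)
    if not base:
        raise VocabularyError(
            f"no base term of {list(base_terms)} in the year-{model.year} vocabulary"
        )
    for target in targets:
        if target not in model:
            raise VocabularyError(
                f"target {target!r} not in the year-{model.year} vocabulary"
            )

    out: dict[tuple[str, str], SimilarityEstimate] = {}

    if mode == "terms":
        for target in targets:
            tvec = model.vector(target)
            per_term = {b: cosine(model.vector(b), tvec) for b in base}
            for method in methods:
                rng = np.random.default_rng(boot_seed)
                reps: list[float] = []
                for _ in range(n_boot):
                    sample = [base[i] for i in rng.integers(len(base), size=len(base))]
                    if method == "centroid":
                        centroid = np.mean([model.vector(b) for b in sample], axis=0)
                        reps.append(cosine(centroid, tvec))
                    else:
                        reps.append(float(np.mean([per_term[b] for b in sample])))
                point, per_term_pt = _point_value(model, base, target, method, None)
                lo, hi = np.percentile(reps, [2.5, 97.5])
                out[(target, method)] = SimilarityEstimate(
                    year=model.year, target=target, method=method, estimate=point,
                    ci_low=float(lo), ci_high=float(hi), n_boot=len(reps),
                    per_term=per_term_pt, boot_seed=boot_seed,
                )
        return out

    rep_models, discarded = _document_replicates(
        corpus, params, n_boot, boot_seed, replicate_epochs, bayesian=(mode == "bayesian")
    )
    for target in targets:
        # per-target discards: replicates where the target or base group vanished
        records: list[dict[str, float]] = []
        centroid_reps: list[float] = []
        t_discarded = discarded
        for rep_model in rep_models:
            rep_base = [b for b in base if b in rep_model]
            if target not in rep_model or not rep_base:
                t_discarded += 1
                logger.warning(
                    "year %d: replicate discarded for %r (out of vocabulary)",
                    corpus.year, target,
                )
                continue
            tvec = rep_model.vector(target)
            records.append({b: cosine(rep_model.vector(b), tvec) for b in rep_base})
            centroid = np.mean([rep_model.vector(b) for b in rep_base], axis=0)
            centroid_reps.append(cosine(centroid, tvec))
        if t_discarded > 0.2 * n_boot:
            raise BootstrapError(
                f"{t_discarded}/{n_boot} bootstrap replicates discarded "
                f"for year {corpus.year}, target {target!r}"
            )
        per_term_reps = {b: [rec[b] for rec in records if b in rec] for b in base}
        term_variances = {
            b: float(np.var(v, ddof=1)) if len(v) > 1 else _VAR_FLOOR
            for b, v in per_term_reps.items()
            if v
        }
        for method in methods:
            if method == "centroid":
                reps = centroid_reps
            elif method == "mean":
                reps = [float(np.mean(list(rec.values()))) for rec in records]
            elif method == "precision_weighted":
                reps = []
                for rec in records:
                    w = np.asarray(
                        [1.0 / max(term_variances.get(b, _VAR_FLOOR), _VAR_FLOOR) for b in rec]
                    )
                    c = np.asarray(list(rec.values()))
                    reps.append(float(np.sum(w * c) / np.sum(w)))
            else:
                raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
            point, per_term = _point_value(model, base, target, method, term_variances)
            if reps:
                # recentred percentile interval: retraining on reweighted or
                # duplicated documents reduces the effective evidence, which
                # biases every replicate statistic downward at small corpus
                # sizes; percentiles are therefore taken of the replicate
                # deviations around their mean, anchored at the full-data
                # point estimate.
                shifted = np.asarray(reps) - np.mean(reps) + point
                lo, hi = np.percentile(shifted, [2.5, 97.5])
            else:
                lo = hi = math.nan
            out[(target, method)] = SimilarityEstimate(
                year=model.year, target=target, method=method, estimate=point,
                ci_low=float(lo), ci_high=float(hi), n_boot=len(reps),
                per_term=per_term, boot_seed=boot_seed,
            )
    return out


def bootstrap_ci(
    corpus: YearCorpus,
    params: EmbedParams,
    base_terms: Sequence[str],
    target: str,
    method: str = "centroid",
    n_boot: int = 100,
    boot_seed: int = 0,
    mode: str = "bayesian",
    replicate_epochs: int | None = None,
    model: EmbeddingModel | None = None,
) -> SimilarityEstimate:
    """Percentile-bootstrap CI around the full-data point estimate for a
    single (target, method); see :func:`bootstrap_year_estimates`."""
    return bootstrap_year_estimates(
        corpus, params, base_terms, [target], [method],
        n_boot=n_boot, boot_seed=boot_seed, mode=mode,
        replicate_epochs=replicate_epochs, model=model,
    )[(target, method)]


def similarity_series(
    corpora: Mapping[int, YearCorpus],
    models: Mapping[int, EmbeddingModel],
    base_terms: Sequence[str],
    target: str,
    method: str = "centroid",
    n_boot: int = 0,
    boot_seed: int = 0,
    mode: str = "bayesian",
    replicate_epochs: int | None = None,
) -> SimilaritySeries:
    """One estimate per analysed year, in year order; a year in which the
    target or the whole base group is out of vocabulary becomes an explicit
    gap, never a silently dropped point."""
    estimates: list[SimilarityEstimate] = []
    gaps: list[int] = []
    for year in sorted(models):
        model = models[year]
        if target not in model or not any(b in model for b in base_terms):
            logger.warning("year %d: target %r or base group unavailable; recording gap", year, target)
            gaps.append(year)
            continue
        if n_boot > 0:
            est = bootstrap_ci(
                corpora[year],
                model.params,
                base_terms,
                target,
                method=method,
                n_boot=n_boot,
                boot_seed=boot_seed + year,
                mode=mode,
                replicate_epochs=replicate_epochs,
                model=model,
            )
        else:
            est = group_target_similarity(model, base_terms, target, method=method)
        estimates.append(est)
    return SimilaritySeries(target=target, method=method, estimates=estimates, gaps=gaps)


def series_table(series_list: Sequence[SimilaritySeries]) -> pd.DataFrame:
    """Long-format table of all series (one row per year x target x method)."""
    rows = []
    for s in series_list:
        for e in s.estimates:
            rows.append(
                {
                    "year": e.year,
                    "target": e.target,
                    "method": e.method,
                    "estimate": e.estimate,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n_boot": e.n_boot,
                    "n_base_terms_used": e.n_base_terms_used,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "year", "target", "method", "estimate",
            "ci_low", "ci_high", "n_boot", "n_base_terms_used",
        ],
    )
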