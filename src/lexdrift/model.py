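"""Model/Results interface tying the pipeline together.

``TemporalAssociation`` is built from data (year-partitioned notes or
already-tokenized year corpora) plus the analysis configuration: seed term
families, expansion depth, presence floor, reviewed exclusions and embedding
hyperparameters. ``fit()`` runs embedding training, lexicon refinement, the
per-year association statistics (optionally bootstrapped) and the trend
tests, returning a ``TemporalAssociationResults`` object that carries the
estimates, their uncertainties and a ``summary()`` table, statsmodels-style.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .association import (
    METHODS,
    SimilaritySeries,
    bootstrap_year_estimates,
    group_target_similarity,
    series_table,
)
from .embedding import EmbeddingModel, EmbedParams, train_yearly
from .errors import ConfigurationError
from .lexicon import (
    CandidateSet,
    Lexicon,
    audit_report,
    expand_lexicon,
    finalize_lexicon,
    presence_filter,
)
from .preprocess import YearCorpus, build_year_corpora, subset_by_codes
from .simulate import Note
from .trend import TrendResult, fit_trend, trend_report, trend_table


class TemporalAssociation:
    """Diachronic base-group vs target-term association model.

    Parameters
    ----------
    corpora
        year -> tokenized, phrase-merged corpus.
    base_seeds, target_seeds
        Seed terms for the two concept families; each family is expanded to
        its top-``expansion_k`` contextual neighbours in every yearly model.
    exclude
        Reviewed exclusion list, term -> reason (the manual QC step as
        declarative input).
    assignment
        Reviewed concept-family map, term -> "base"/"target". When given,
        survivors outside the map are excluded as not retained by review.
    min_per_year
        Presence floor: lexicon terms must occur at least this often in every
        analysed year.
    """

    def __init__(
        self,
        corpora: Mapping[int, YearCorpus],
        base_seeds: Sequence[str],
        target_seeds: Sequence[str],
        embed_params: EmbedParams | None = None,
        expansion_k: int = 50,
        min_per_year: int = 5,
        exclude: Mapping[str, str] | None = None,
        assignment: Mapping[str, str] | None = None,
    ):
        if not corpora:
            raise ConfigurationError("at least one year corpus is required")
        if not base_seeds or not target_seeds:
            raise ConfigurationError("base and target seed lists must be non-empty")
        self.corpora = dict(sorted(corpora.items()))
        self.base_seeds = list(base_seeds)
        self.target_seeds = list(target_seeds)
        self.embed_params = embed_params or EmbedParams()
        self.expansion_k = expansion_k
        self.min_per_year = min_per_year
        self.exclude = dict(exclude or {})
        self.assignment = dict(assignment) if assignment is not None else None

    @classmethod
    def from_notes(
        cls,
        notes: Sequence[Note],
        base_seeds: Sequence[str],
        target_seeds: Sequence[str],
        code_table: Sequence[tuple[str, str]] | None = None,
        code_list: Sequence[str] | None = None,
        phrase_min_count: int = 5,
        phrase_threshold: float = 10.0,
        phrase_passes: int = 2,
        **kwargs,
    ) -> "TemporalAssociation":
        """Build from raw notes; optionally subset to a diagnosis-code cohort
        first (patient-level selection)."""
        if code_list is not None:
            if code_table is None:
                raise ConfigurationError("code_list given without a code table")
            notes = subset_by_codes(notes, code_table, code_list)
        corpora = build_year_corpora(
            notes,
            phrase_min_count=phrase_min_count,
            phrase_threshold=phrase_threshold,
            phrase_passes=phrase_passes,
        )
        return cls(corpora, base_seeds, target_seeds, **kwargs)

    def fit(
        self,
        n_boot: int = 0,
        boot_seed: int = 0,
        bootstrap_mode: str = "bayesian",
        replicate_epochs: int | None = None,
        methods: Sequence[str] = METHODS,
    ) -> "TemporalAssociationResults":
        """Train yearly models, refine the lexicon, estimate the per-year
        association for every final target term and fit its trend."""
        models = train_yearly(self.corpora, self.embed_params)
        vocab_counts = {y: c.vocab_counts for y, c in self.corpora.items()}

        base_cand = expand_lexicon(models, self.base_seeds, k=self.expansion_k)
        target_cand = expand_lexicon(models, self.target_seeds, k=self.expansion_k)
        base_surv = presence_filter(base_cand, vocab_counts, self.min_per_year)
        target_surv = presence_filter(target_cand, vocab_counts, self.min_per_year)
        merged_expanded = {**base_cand.provenance, **target_cand.provenance}
        lexicon = finalize_lexicon(
            base_surv,
            target_surv,
            self.exclude,
            assignment=self.assignment,
            seeds=self.base_seeds + self.target_seeds,
            expanded=merged_expanded,
        )
        if not lexicon.final_base_terms:
            raise ConfigurationError("no base term survived lexicon refinement")
        if not lexicon.final_target_terms:
            raise ConfigurationError("no target term survived lexicon refinement")

        # one bootstrap per year, replicate models shared across targets/methods
        base_group = lexicon.final_base_terms
        estimates: dict[tuple[str, str], list] = {
            (t, m): [] for t in lexicon.final_target_terms for m in methods
        }
        gaps: dict[str, list[int]] = {t: [] for t in lexicon.final_target_terms}
        for year in sorted(models):
            model_y = models[year]
            base_ok = any(b in model_y for b in base_group)
            avail = [t for t in lexicon.final_target_terms if t in model_y and base_ok]
            for t in lexicon.final_target_terms:
                if t not in avail:
                    gaps[t].append(year)
            if not avail:
                continue
            if n_boot > 0:
                year_ests = bootstrap_year_estimates(
                    self.corpora[year],
                    model_y.params,
                    base_group,
                    avail,
                    methods,
                    n_boot=n_boot,
                    boot_seed=boot_seed + year,
                    mode=bootstrap_mode,
                    replicate_epochs=replicate_epochs,
                    model=model_y,
                )
                for key, est in year_ests.items():
                    estimates[key].append(est)
            else:
                for t in avail:
                    for m in methods:
                        estimates[(t, m)].append(
                            group_target_similarity(model_y, base_group, t, method=m)
                        )
        series_list: list[SimilaritySeries] = []
        trends: list[TrendResult] = []
        for target in lexicon.final_target_terms:
            for method in methods:
                s = SimilaritySeries(
                    target=target,
                    method=method,
                    estimates=estimates[(target, method)],
                    gaps=gaps[target],
                )
                series_list.append(s)
                if len(s.estimates) >= 2:
                    trends.append(fit_trend(s))
        return TemporalAssociationResults(
            model=self,
            embeddings=models,
            lexicon=lexicon,
            candidates={"base": base_cand, "target": target_cand},
            series=series_list,
            trends=trends,
        )


@dataclass
class TemporalAssociationResults:
    """Fitted estimates: lexicon, per-year similarity series, trends."""

    model: TemporalAssociation
    embeddings: dict[int, EmbeddingModel]
    lexicon: Lexicon
    candidates: dict[str, CandidateSet]
    series: list[SimilaritySeries]
    trends: list[TrendResult] = field(default_factory=list)

    def similarity_table(self) -> pd.DataFrame:
        return series_table(self.series)

    def trend_table(self) -> pd.DataFrame:
        return trend_table(self.trends)

    def audit_table(self) -> pd.DataFrame:
        vocab_counts = {y: c.vocab_counts for y, c in self.model.corpora.items()}
        frames = [
            audit_report(cand, self.lexicon, vocab_counts)
            for cand in self.candidates.values()
        ]
        return pd.concat(frames, ignore_index=True)

    def get_series(self, target: str, method: str = "centroid") -> SimilaritySeries:
        for s in self.series:
            if s.target == target and s.method == method:
                return s
        raise KeyError(f"no series for target={target!r}, method={method!r}")

    def summary(self) -> str:
        """Human-readable report of the fitted association trends."""
        lines = []
        years = sorted(self.model.corpora)
        lines.append("Temporal lexical association results")
        lines.append("=" * 60)
        lines.append(f"years analysed:     {years[0]}-{years[-1]} ({len(years)} models)")
        lines.append(f"base group ({len(self.lexicon.final_base_terms)}):  "
                     + ", ".join(self.lexicon.final_base_terms))
        lines.append(f"targets ({len(self.lexicon.final_target_terms)}):      "
                     + ", ".join(self.lexicon.final_target_terms))
        if self.lexicon.excluded_terms:
            unreviewed = sum(
                1 for r in self.lexicon.excluded_terms.values()
                if r == "not retained by lexicon review"
            )
            parts = [
                f"{t} ({r})"
                for t, r in self.lexicon.excluded_terms.items()
                if r != "not retained by lexicon review"
            ]
            if unreviewed:
                parts.append(f"{unreviewed} candidates not retained by review")
            lines.append(f"excluded by QC:     {'; '.join(parts)}")
        lines.append("-" * 60)
        lines.append(f"{'target':<16}{'method':<20}{'slope/yr':>10}{'p':>9}{'r2':>7}")
        for r in self.trends:
            star = " *" if r.significant else ""
            p = "   n/a" if pd.isna(r.p_value) else f"{r.p_value:8.4f}"
            lines.append(
                f"{r.target:<16}{r.method:<20}{r.slope:>10.5f}{p:>9}{r.r_squared:>7.3f}{star}"
            )
        lines.append("-" * 60)
        lines.append("* p < 0.05, two-sided t-test on the OLS slope (no multiplicity correction)")
        return "\n".join(lines)

    def plot(self, out_dir: str | Path) -> pd.DataFrame:
        return trend_report(self.trends, self.series, out_dir=out_dir)

    def save(self, out_dir: str | Path, seed: int | None = None) -> None:
        """Write similarity/trend/audit TSVs plus a provenance manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.similarity_table().to_csv(out_dir / "similarity.tsv", sep="\t", index=False)
        self.trend_table().to_csv(out_dir / "trend.tsv", sep="\t", index=False)
        self.audit_table().to_csv(out_dir / "lexicon_audit.tsv", sep="\t", index=False)
        config = {
            "years": sorted(self.model.corpora),
            "base_seeds": self.model.base_seeds,
            "target_seeds": self.model.target_seeds,
            "expansion_k": self.model.expansion_k,
            "min_per_year": self.model.min_per_year,
            "exclude": self.model.exclude,
            "assignment": self.model.assignment,
            "embed_params": self.model.embed_params.__dict__,
        }
        manifest = {
            "package_version": __version__,
            "config_sha256": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()
            ).hexdigest(),
            "config": config,
            "seed": seed,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
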