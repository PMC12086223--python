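"""Lexicon refinement: seed expansion, presence filtering, finalization.

The refinement mirrors a mixed automatic/manual procedure: seed terms are
expanded to their top-k contextual neighbours in every yearly model (union
across seeds and years, with provenance); candidates must then occur at least
a floor number of times in every analysed year; finally a reviewed exclusion
list — each entry carrying a human-entered reason — removes terms judged
off-concept. The judgment step is declarative configuration, not code, so a
partly manual process stays reproducible. A re-expansion report (neighbours
of each survivor) is generated for human audit rather than filtered
automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .embedding import EmbeddingModel, nearest_neighbors
from .errors import VocabularyError
from .preprocess import filter_terms

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Expansion output: candidate terms with (year, rank) provenance and the
    seed(s) each candidate came from. Seeds are themselves candidates."""

    seeds: list[str]
    provenance: dict[str, set[tuple[int, int]]] = field(default_factory=dict)
    origins: dict[str, set[str]] = field(default_factory=dict)

    @property
    def terms(self) -> list[str]:
        return sorted(self.provenance)


@dataclass
class Lexicon:
    """Audited base/target term sets with the full expansion trail."""

    seed_terms: list[str]
    expanded_candidates: dict[str, set[tuple[int, int]]]
    surviving_terms: list[str]
    excluded_terms: dict[str, str]
    final_base_terms: list[str]
    final_target_terms: list[str]


def expand_lexicon(
    models: Mapping[int, EmbeddingModel] | Sequence[EmbeddingModel],
    seeds: Sequence[str],
    k: int = 50,
) -> CandidateSet:
    """Union of top-k neighbours of every seed across all yearly models.

    Provenance records every (year, rank) at which a candidate surfaced;
    rank is 1-based. A seed missing from every model is an error.
    """
    if not isinstance(models, Mapping):
        models = {m.year: m for m in models}
    out = CandidateSet(seeds=list(seeds))
    for seed in seeds:
        out.provenance.setdefault(seed, set())
        out.origins.setdefault(seed, set()).add(seed)
    for seed in seeds:
        hit = False
        for year in sorted(models):
            model = models[year]
            if seed not in model:
                continue
            hit = True
            for rank, (term, _sim) in enumerate(nearest_neighbors(model, seed, k), 1):
                out.provenance.setdefault(term, set()).add((year, rank))
                out.origins.setdefault(term, set()).add(seed)
        if not hit:
            raise VocabularyError(f"seed {seed!r} absent from every yearly model")
    return out


def presence_filter(
    candidates: CandidateSet | Sequence[str],
    vocab_counts_by_year: Mapping[int, Mapping[str, int]],
    min_per_year: int = 5,
) -> list[str]:
    """Keep candidates present >= min_per_year times in every analysed year."""
    terms = candidates.terms if isinstance(candidates, CandidateSet) else list(candidates)
    return filter_terms(terms, vocab_counts_by_year, min_per_year=min_per_year)


def finalize_lexicon(
    base_survivors: Sequence[str],
    target_survivors: Sequence[str],
    exclude: Mapping[str, str] | None = None,
    *,
    assignment: Mapping[str, str] | None = None,
    seeds: Sequence[str] = (),
    expanded: Mapping[str, set[tuple[int, int]]] | None = None,
) -> Lexicon:
    """Apply the reviewed exclusion list and assemble the final lexicon.

    Every exclusion must carry a reason string; excluding a term that is not
    among the survivors is a warned no-op. ``assignment`` is the reviewed
    concept-family map (term -> "base" or "target"): when given, survivors
    absent from it are excluded as not retained by review — the declarative
    stand-in for the human refinement step — and family membership follows
    the map rather than which seed family surfaced the term. Without it,
    terms keep the family of the expansion they came from.
    """
    exclude = dict(exclude or {})
    survivors = list(base_survivors) + [
        t for t in target_survivors if t not in base_survivors
    ]
    applied: dict[str, str] = {}
    for term, reason in exclude.items():
        if term in survivors:
            applied[term] = reason
        else:
            logger.warning("exclusion of %r ignored: not among survivors", term)
    if assignment is not None:
        bad = {f for f in assignment.values() if f not in ("base", "target")}
        if bad:
            raise ValueError(f"assignment families must be 'base'/'target', got {sorted(bad)}")
        for term in survivors:
            if term not in applied and term not in assignment:
                applied[term] = "not retained by lexicon review"
        final_base = [t for t in survivors if t not in applied and assignment[t] == "base"]
        final_target = [t for t in survivors if t not in applied and assignment[t] == "target"]
    else:
        final_base = [t for t in base_survivors if t not in applied]
        final_target = [t for t in target_survivors if t not in applied]
    return Lexicon(
        seed_terms=list(seeds),
        expanded_candidates=dict(expanded or {}),
        surviving_terms=survivors,
        excluded_terms=applied,
        final_base_terms=final_base,
        final_target_terms=final_target,
    )


def reexpansion_report(
    models: Mapping[int, EmbeddingModel],
    terms: Sequence[str],
    k: int = 50,
) -> pd.DataFrame:
    """Neighbours of each surviving term, for human review of the lexicon."""
    rows = []
    for term in terms:
        for year in sorted(models):
            model = models[year]
            if term not in model:
                continue
            for rank, (nb, sim) in enumerate(nearest_neighbors(model, term, k), 1):
                rows.append(
                    {"term": term, "year": year, "rank": rank, "neighbor": nb, "cosine": sim}
                )
    return pd.DataFrame(rows, columns=["term", "year", "rank", "neighbor", "cosine"])


def audit_report(
    candidates: CandidateSet,
    lexicon: Lexicon,
    vocab_counts_by_year: Mapping[int, Mapping[str, int]],
) -> pd.DataFrame:
    """One row per candidate: origin seeds, years observed, min yearly count,
    decision and reason. Written as TSV by the CLI."""
    final = set(lexicon.final_base_terms) | set(lexicon.final_target_terms)
    rows = []
    for term in candidates.terms:
        counts = [vocab_counts_by_year[y].get(term, 0) for y in sorted(vocab_counts_by_year)]
        if term in final:
            decision, reason = "included", ""
        elif term in lexicon.excluded_terms:
            decision, reason = "excluded", lexicon.excluded_terms[term]
        else:
            decision, reason = "filtered", "below per-year presence floor"
        rows.append(
            {
                "term": term,
                "origin_seeds": ",".join(sorted(candidates.origins.get(term, set()))),
                "years_observed": sum(c > 0 for c in counts),
                "min_yearly_count": min(counts) if counts else 0,
                "decision": decision,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)
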