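"""Synthetic year-partitioned note corpora with planted lexical associations.

The generator emulates the statistical structure that the diachronic
association analysis assumes: a Zipfian background vocabulary, a planted
"base" term family (metastatic-like synonyms, including multi-word phrases),
planted "target" terms (palliative-like), and a per-year probability ``rho``
that a base-mentioning note also contains a target term. Trending ``rho``
schedules create corpora in which the base-target contextual association
genuinely strengthens or weakens across years, which is what the downstream
pipeline is asked to recover.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError

DEFAULT_BASE_TERMS = (
    "metastatic",
    "mets",
    "metastasis",
    "metastasized",
    "widely metastatic",
)
DEFAULT_TARGET_TERMS = ("palliative", "palliation")


@dataclass
class Note:
    """One clinical document: identifiers plus raw text."""

    note_id: str
    patient_id: str
    year: int
    text: str


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic corpus.

    Parameters
    ----------
    years
        Ordered calendar years; one corpus partition (and one embedding model)
        per year.
    notes_per_year
        Number of notes generated for each year.
    note_length_mean
        Poisson mean of the background token count per note, truncated at >= 5.
    vocab_size
        Background vocabulary size; token i is drawn with probability
        proportional to (i+1) ** -zipf_exponent.
    base_terms, target_terms
        Planted term families. Entries containing spaces are inserted as
        adjacent word sequences so the phrase learner must discover them.
    base_note_prob
        Probability that a note mentions a (uniformly chosen) base term.
        The default background_target_prob (0.15) keeps the target family's
        own-context occurrence mass comparable to its base-context mass over
        rho in [0, 0.6], so the association statistic responds through the
        whole range instead of saturating.
    assoc_schedule
        Year -> rho, the probability that a base-mentioning note also contains
        a target term.
    background_target_prob
        Probability that a non-base note contains a target term.
    n_patients, code_positive_frac, code_enrichment_odds
        Patient pool size, fraction carrying the flagged diagnosis code, and
        the odds multiplier by which base-term notes are preferentially
        assigned to flagged patients.
    pair_max_distance
        Optional cap (in background-token positions) on the distance between a
        co-occurring base/target pair; ``None`` places both uniformly.
    n_topics, topic_weight
        Topical structure of the background. Each note draws one topic;
        every background token comes from the topic's own (renormalized Zipf)
        word subset with probability ``topic_weight``, else from the global
        Zipf distribution. Word-embedding geometry degenerates on a
        structureless i.i.d. background (all cosines tend to a common value),
        so differential co-occurrence structure is a precondition for the
        analysis, not an optional extra.
    base_topics, target_topics
        Contextual anchoring of the planted families. Base-mentioning notes
        draw their topic from the first ``base_topics`` topics; non-base
        notes containing a target term draw from the next ``target_topics``
        topics; all other notes draw uniformly from every topic. With the
        families anchored to disjoint contexts, the co-occurrence probability
        rho is what moves target terms into base contexts, and the measured
        base-target cosine rises with it.
    """

    years: Sequence[int]
    notes_per_year: int = 2000
    note_length_mean: float = 40.0
    vocab_size: int = 500
    zipf_exponent: float = 1.1
    base_terms: Sequence[str] = DEFAULT_BASE_TERMS
    target_terms: Sequence[str] = DEFAULT_TARGET_TERMS
    base_note_prob: float = 0.3
    assoc_schedule: Mapping[int, float] = field(default_factory=dict)
    background_target_prob: float = 0.15
    n_patients: int = 500
    code_positive_frac: float = 0.3
    code_enrichment_odds: float = 5.0
    pair_max_distance: int | None = None
    n_topics: int = 20
    topic_weight: float = 0.5
    base_topics: int = 3
    target_topics: int = 3
    seed: int = 0
    flagged_code: str = "c799"

    def __post_init__(self) -> None:
        self.years = list(self.years)
        if self.notes_per_year < 0:
            raise ConfigurationError("notes_per_year must be non-negative")
        if self.vocab_size < 2:
            raise ConfigurationError("vocab_size must be at least 2")
        if self.note_length_mean <= 0:
            raise ConfigurationError("note_length_mean must be positive")
        if self.zipf_exponent <= 0:
            raise ConfigurationError("zipf_exponent must be positive")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if self.n_topics < 1:
            raise ConfigurationError("n_topics must be positive")
        if self.base_topics < 1 or self.target_topics < 1:
            raise ConfigurationError("base_topics and target_topics must be positive")
        if self.base_topics + self.target_topics > self.n_topics:
            raise ConfigurationError(
                "base_topics + target_topics cannot exceed n_topics"
            )
        for name in ("base_note_prob", "background_target_prob", "code_positive_frac",
                     "topic_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for year in self.years:
            if year not in self.assoc_schedule:
                raise ConfigurationError(f"assoc_schedule missing year {year}")
        for year, rho in self.assoc_schedule.items():
            if year not in self.years:
                raise ConfigurationError(f"assoc_schedule lists unknown year {year}")
            if not 0.0 <= rho <= 1.0:
                raise ConfigurationError(f"rho={rho} for year {year} outside [0, 1]")
        overlap = set(self.base_terms) & set(self.target_terms)
        if overlap:
            raise ConfigurationError(f"base/target families overlap: {sorted(overlap)}")
        planted_words = {
            w for t in list(self.base_terms) + list(self.target_terms) for w in t.split()
        }
        background = set(_background_vocab(self.vocab_size))
        clash = planted_words & background
        if clash:
            raise ConfigurationError(f"planted terms collide with background: {sorted(clash)}")


def _background_vocab(vocab_size: int) -> list[str]:
    width = max(4, len(str(vocab_size - 1)))
    return [f"w{i:0{width}d}" for i in range(vocab_size)]


def association_schedule_linear(
    years: Sequence[int], rho_start: float, rho_end: float
) -> dict[int, float]:
    """Linear-in-year interpolation of rho; endpoints exact."""
    years = list(years)
    if len(years) < 2:
        raise ConfigurationError("a linear schedule needs at least 2 years")
    for rho in (rho_start, rho_end):
        if not 0.0 <= rho <= 1.0:
            raise ConfigurationError(f"rho={rho} outside [0, 1]")
    y0, y1 = years[0], years[-1]
    if y0 == y1:
        raise ConfigurationError("first and last year coincide")
    span = y1 - y0
    return {y: rho_start + (rho_end - rho_start) * (y - y0) / span for y in years}


def generate_corpus(config: SyntheticConfig) -> tuple[list[Note], list[tuple[str, str]]]:
    """Generate notes plus a (patient_id, code) table; deterministic given seed.

    Each note is a bag of background Zipf tokens; with probability
    ``base_note_prob`` a base term is spliced in at a uniform position, and a
    base-mentioning note additionally receives a target term with probability
    ``assoc_schedule[year]``. Base-term notes are assigned to code-positive
    patients at ``code_enrichment_odds`` : 1 odds relative to their base rate.
    """
    rng = np.random.default_rng(config.seed)
    background = _background_vocab(config.vocab_size)
    probs = (np.arange(config.vocab_size) + 1.0) ** -config.zipf_exponent
    probs /= probs.sum()
    # round-robin topic assignment so each topic spans all frequency bands
    topic_probs = []
    for t in range(config.n_topics):
        members = np.arange(t, config.vocab_size, config.n_topics)
        p = np.zeros(config.vocab_size)
        p[members] = probs[members]
        topic_probs.append(p / p.sum())

    width = max(5, len(str(config.n_patients - 1)))
    patients = [f"p{i:0{width}d}" for i in range(config.n_patients)]
    n_flagged = int(round(config.code_positive_frac * config.n_patients))
    flagged = patients[:n_flagged]
    unflagged = patients[n_flagged:]
    # no notes -> no cohort: keep the code table empty too
    code_table = (
        [(p, config.flagged_code) for p in flagged]
        if config.notes_per_year > 0 and config.years
        else []
    )

    f = config.code_positive_frac
    odds = config.code_enrichment_odds
    p_flag_base = (odds * f) / (odds * f + (1.0 - f)) if 0.0 < f < 1.0 else f

    notes: list[Note] = []
    for year in config.years:
        rho = config.assoc_schedule[year]
        for i in range(config.notes_per_year):
            length = max(5, int(rng.poisson(config.note_length_mean)))
            has_base = rng.random() < config.base_note_prob
            has_target = rng.random() < (
                rho if has_base else config.background_target_prob
            )
            if has_base:
                topic = int(rng.integers(config.base_topics))
            elif has_target:
                topic = config.base_topics + int(rng.integers(config.target_topics))
            else:
                topic = int(rng.integers(config.n_topics))
            from_topic = rng.random(length) < config.topic_weight
            n_topical = int(from_topic.sum())
            idx = np.empty(length, dtype=np.int64)
            idx[from_topic] = rng.choice(
                config.vocab_size, size=n_topical, p=topic_probs[topic]
            )
            idx[~from_topic] = rng.choice(
                config.vocab_size, size=length - n_topical, p=probs
            )
            tokens = [background[j] for j in idx]

            base_pos = None
            if has_base:
                term = config.base_terms[rng.integers(len(config.base_terms))]
                base_pos = int(rng.integers(len(tokens) + 1))
                tokens[base_pos:base_pos] = term.split()
            if has_target and config.target_terms:
                term = config.target_terms[rng.integers(len(config.target_terms))]
                if has_base and config.pair_max_distance is not None:
                    lo = max(0, base_pos - config.pair_max_distance)
                    hi = min(len(tokens), base_pos + config.pair_max_distance) + 1
                    t_pos = int(rng.integers(lo, hi))
                else:
                    t_pos = int(rng.integers(len(tokens) + 1))
                tokens[t_pos:t_pos] = term.split()

            if has_base and flagged and unflagged:
                pool = flagged if rng.random() < p_flag_base else unflagged
            elif flagged and unflagged:
                pool = flagged if rng.random() < f else unflagged
            else:
                pool = patients
            patient = pool[rng.integers(len(pool))]

            notes.append(
                Note(
                    note_id=f"{year}-{i:05d}",
                    patient_id=patient,
                    year=year,
                    text=" ".join(tokens),
                )
            )
    return notes, code_table


def planted_assignment(config: SyntheticConfig) -> dict[str, str]:
    """Reviewed family map for the planted terms, in their phrase-merged form
    (multi-word plantings surface as underscore tokens after preprocessing)."""
    out = {t.replace(" ", "_"): "base" for t in config.base_terms}
    out.update({t.replace(" ", "_"): "target" for t in config.target_terms})
    return out


def write_notes_jsonl(notes: Iterable[Note], path: str | Path) -> None:
    with open(path, "w") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "year": n.year,
                        "text": n.text,
                    }
                )
                + "\n"
            )


def read_notes(path: str | Path) -> list[Note]:
    """Read notes from JSONL or CSV (note_id, patient_id, year, text)."""
    path = Path(path)
    notes: list[Note] = []
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                notes.append(
                    Note(row["note_id"], row["patient_id"], int(row["year"]), row["text"])
                )
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                obj = json.loads(line)
                notes.append(
                    Note(obj["note_id"], obj["patient_id"], int(obj["year"]), obj["text"])
                )
    return notes


def write_code_table(code_table: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "code"])
        writer.writerows(code_table)


def read_code_table(path: str | Path) -> list[tuple[str, str]]:
    with open(path, newline="") as fh:
        return [(row["patient_id"], row["code"]) for row in csv.DictReader(fh)]
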