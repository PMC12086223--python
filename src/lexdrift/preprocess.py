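"""Tokenization, phrase merging, vocabulary counting and cohort subsetting.

Tokenization is deliberately minimal: lowercase, punctuation stripped except
intra-token hyphens, whitespace split. No stemming or lemmatization is
applied — the analysis distinguishes morphological variants of the same stem
(e.g. "palliate" vs "palliation" vs "palliative"), so collapsing them would
destroy the quantity of interest.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .simulate import Note

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase, strip punctuation (keeping internal hyphens), split."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class PhraseTable:
    """Bigrams promoted to single underscore-joined tokens.

    A bigram (a, b) enters the table when it was seen at least ``min_count``
    times and its collocation score
    ``(count(ab) - min_count) * N / (count(a) * count(b))`` — with N the total
    token count — reaches ``threshold``.
    """

    scores: dict[tuple[str, str], float] = field(default_factory=dict)
    min_count: int = 5
    threshold: float = 10.0

    def __contains__(self, bigram: tuple[str, str]) -> bool:
        return bigram in self.scores

    def __len__(self) -> int:
        return len(self.scores)


def learn_phrases(
    docs: Iterable[Sequence[str]], min_count: int = 5, threshold: float = 10.0
) -> PhraseTable:
    """Score adjacent bigrams and keep those passing count and score floors."""
    if min_count < 1:
        raise ConfigurationError("min_count must be >= 1")
    unigrams: Counter[str] = Counter()
    bigrams: Counter[tuple[str, str]] = Counter()
    for doc in docs:
        unigrams.update(doc)
        bigrams.update(zip(doc, doc[1:]))
    total = sum(unigrams.values())
    table = PhraseTable(min_count=min_count, threshold=threshold)
    for (a, b), cab in bigrams.items():
        if cab < min_count:
            continue
        score = (cab - min_count) * total / (unigrams[a] * unigrams[b])
        if score >= threshold:
            table.scores[(a, b)] = score
    return table


def apply_phrases(tokens: Sequence[str], table: PhraseTable) -> list[str]:
    """Single left-to-right greedy pass; merged tokens are not re-merged."""
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        if i + 1 < n and (tokens[i], tokens[i + 1]) in table:
            out.append(tokens[i] + "_" + tokens[i + 1])
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def merge_phrases(
    docs: list[list[str]],
    min_count: int = 5,
    threshold: float = 10.0,
    passes: int = 2,
) -> tuple[list[list[str]], list[PhraseTable]]:
    """Repeatedly learn and apply a phrase table.

    Two passes (the default) let three-word units form: the first pass merges
    a bigram, the second can merge the result with a neighbour.
    """
    tables: list[PhraseTable] = []
    for _ in range(passes):
        table = learn_phrases(docs, min_count=min_count, threshold=threshold)
        tables.append(table)
        if not table.scores:
            break
        docs = [apply_phrases(d, table) for d in docs]
    return docs, tables


@dataclass
class YearCorpus:
    """Tokenized, phrase-merged documents for one calendar year."""

    year: int
    docs: list[list[str]]
    vocab_counts: Counter[str] = field(default_factory=Counter)

    @classmethod
    def from_docs(cls, year: int, docs: list[list[str]]) -> "YearCorpus":
        return cls(year=year, docs=docs, vocab_counts=count_vocab(docs))

    @property
    def n_docs(self) -> int:
        return len(self.docs)


def count_vocab(docs: Iterable[Sequence[str]]) -> Counter[str]:
    counts: Counter[str] = Counter()
    for doc in docs:
        counts.update(doc)
    return counts


def filter_terms(
    terms: Iterable[str],
    vocab_counts_by_year: Mapping[int, Mapping[str, int]],
    min_per_year: int = 5,
    years: Sequence[int] | None = None,
) -> list[str]:
    """Keep terms occurring at least ``min_per_year`` times in EVERY year."""
    if min_per_year < 1:
        raise ConfigurationError("min_per_year must be >= 1")
    if years is None:
        years = sorted(vocab_counts_by_year)
    else:
        unknown = [y for y in years if y not in vocab_counts_by_year]
        if unknown:
            raise ConfigurationError(f"no vocabulary counts for years {unknown}")
    return [
        t
        for t in terms
        if all(vocab_counts_by_year[y].get(t, 0) >= min_per_year for y in years)
    ]


def subset_by_codes(
    notes: Sequence[Note],
    code_table: Iterable[tuple[str, str]],
    code_list: Iterable[str],
) -> list[Note]:
    """Patient-level cohort selection: keep every note of any patient carrying
    at least one code from ``code_list``."""
    codes = set(code_list)
    if not codes:
        raise ConfigurationError("code_list must be non-empty")
    selected = {patient for patient, code in code_table if code in codes}
    kept = [n for n in notes if n.patient_id in selected]
    if notes and not kept:
        logger.warning(
            "code list %s matches no patient in the corpus; returning an empty subset",
            sorted(codes),
        )
    return kept


def build_year_corpora(
    notes: Sequence[Note],
    phrase_min_count: int = 5,
    phrase_threshold: float = 10.0,
    phrase_passes: int = 2,
) -> dict[int, YearCorpus]:
    """Tokenize notes, learn phrases on the pooled corpus, split by year.

    The phrase table is learned once over all years so a multi-word unit maps
    to the same underscore token in every yearly model.
    """
    tokenized = [tokenize(n.text) for n in notes]
    merged, _ = merge_phrases(
        tokenized,
        min_count=phrase_min_count,
        threshold=phrase_threshold,
        passes=phrase_passes,
    )
    by_year: dict[int, list[list[str]]] = {}
    for note, doc in zip(notes, merged):
        by_year.setdefault(note.year, []).append(doc)
    return {y: YearCorpus.from_docs(y, docs) for y, docs in sorted(by_year.items())}
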