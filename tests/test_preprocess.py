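"""Tokenizer, phrase learner/merger, presence filter and cohort subsetting."""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexdrift.errors import ConfigurationError
from lexdrift.preprocess import (
    PhraseTable,
    apply_phrases,
    build_year_corpora,
    filter_terms,
    learn_phrases,
    subset_by_codes,
    tokenize,
)
from lexdrift.simulate import Note


class TestTokenize:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("", []),
            ("Palliative Care consult.", ["palliative", "care", "consult"]),
            ("widely metastatic NSCLC", ["widely", "metastatic", "nsclc"]),
            ("stage-IV ca, s/p chemo!", ["stage-iv", "ca", "s", "p", "chemo"]),
            ("COVID-19 (+) pt", ["covid-19", "pt"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(max_size=80))
    def test_tokens_are_clean(self, text):
        tokens = tokenize(text)
        for t in tokens:
            assert t and t == t.lower()
            assert not t.startswith("-") and not t.endswith("-")
        # re-tokenizing the join is stable
        assert tokenize(" ".join(tokens)) == tokens


class TestLearnPhrases:
    def test_hand_scored_toy_corpus(self):
        # "palliative care" always adjacent; filler keeps other bigrams diluted
        docs = [["palliative", "care", "consult", "note"] for _ in range(10)]
        docs += [["note", "for", "chart", "review"] for _ in range(50)]
        table = learn_phrases(docs, min_count=5, threshold=10.0)

        # independent oracle: exhaustive counting plus the score formula
        uni, bi = Counter(), Counter()
        for d in docs:
            uni.update(d)
            bi.update(zip(d, d[1:]))
        total = sum(uni.values())
        expected = {
            pair: (c - 5) * total / (uni[pair[0]] * uni[pair[1]])
            for pair, c in bi.items()
            if c >= 5 and (c - 5) * total / (uni[pair[0]] * uni[pair[1]]) >= 10.0
        }
        assert ("palliative", "care") in table
        assert set(table.scores) == set(expected)
        for pair, score in expected.items():
            assert table.scores[pair] == pytest.approx(score)

    def test_rare_bigram_below_count_floor(self):
        docs = [["a", "b"]] + [["c"]] * 30
        table = learn_phrases(docs, min_count=5, threshold=0.1)
        assert ("a", "b") not in table

    def test_single_token_docs_yield_empty_table(self):
        assert len(learn_phrases([["x"]] * 50, min_count=1, threshold=0.0).scores) == 0

    def test_empty_corpus(self):
        assert len(learn_phrases([], min_count=5).scores) == 0


class TestApplyPhrases:
    def table(self, *pairs):
        return PhraseTable(scores={p: 99.0 for p in pairs})

    def test_merges_known_pair(self):
        out = apply_phrases(["palliative", "care", "consult"], self.table(("palliative", "care")))
        assert out == ["palliative_care", "consult"]

    def test_empty_table_is_identity(self):
        tokens = ["a", "b", "c"]
        assert apply_phrases(tokens, PhraseTable()) == tokens

    def test_left_to_right_single_pass(self):
        out = apply_phrases(["a", "b", "c"], self.table(("a", "b"), ("b", "c")))
        assert out == ["a_b", "c"]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["a", "b", "c", "d", "e"]), max_size=12))
    def test_non_merged_tokens_preserved_in_order(self, tokens):
        table = self.table(("a", "b"))
        out = apply_phrases(tokens, table)
        # flattening the output reproduces the input exactly
        flat = [p for t in out for p in t.split("_")]
        assert flat == tokens


class TestFilterTerms:
    counts = {
        2013: {"mets": 5, "rare": 4, "once": 1},
        2014: {"mets": 7, "rare": 9, "once": 1},
    }

    def test_boundary_inclusive(self):
        assert filter_terms(["mets"], self.counts, min_per_year=5) == ["mets"]

    def test_one_bad_year_excludes(self):
        assert filter_terms(["rare"], self.counts, min_per_year=5) == []

    def test_floor_of_one(self):
        assert filter_terms(["once"], self.counts, min_per_year=1) == ["once"]

    def test_unknown_year_errors(self):
        with pytest.raises(ConfigurationError):
            filter_terms(["mets"], self.counts, min_per_year=5, years=[2013, 2020])

    def test_monotone_in_floor(self):
        terms = ["mets", "rare", "once"]
        survivors = [
            set(filter_terms(terms, self.counts, min_per_year=m)) for m in range(1, 10)
        ]
        for lo, hi in zip(survivors, survivors[1:]):
            assert hi <= lo


class TestSubsetByCodes:
    def notes(self):
        return [
            Note(f"{p}-{i}", p, 2013, "text")
            for p in ("p1", "p2", "p3", "p4")
            for i in range(3)
        ]

    codes = [("p1", "c799"), ("p2", "c799"), ("p3", "z999")]

    def test_manual_enumeration(self):
        kept = subset_by_codes(self.notes(), self.codes, ["c799"])
        assert len(kept) == 6
        assert {n.patient_id for n in kept} == {"p1", "p2"}

    def test_no_match_is_empty_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert subset_by_codes(self.notes(), self.codes, ["nope"]) == []
        assert "matches no patient" in caplog.text

    def test_all_flagged_is_identity(self):
        notes = self.notes()
        codes = [(p, "c799") for p in ("p1", "p2", "p3", "p4")]
        assert subset_by_codes(notes, codes, ["c799"]) == notes

    def test_idempotent_and_subset(self):
        notes = self.notes()
        once = subset_by_codes(notes, self.codes, ["c799"])
        twice = subset_by_codes(once, self.codes, ["c799"])
        assert twice == once
        assert set(n.note_id for n in once) <= set(n.note_id for n in notes)

    def test_empty_code_list_errors(self):
        with pytest.raises(ConfigurationError):
            subset_by_codes(self.notes(), self.codes, [])


def test_planted_phrase_is_discovered_by_merging():
    """A multi-word planted term must surface as one underscore token."""
    notes = [
        Note(f"n{i}", "p0", 2013, "widely metastatic disease noted on scan")
        for i in range(30)
    ]
    notes += [Note(f"m{i}", "p0", 2013, "routine visit note for follow up") for i in range(30)]
    corpora = build_year_corpora(notes)
    assert "widely_metastatic" in corpora[2013].vocab_counts
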