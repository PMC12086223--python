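"""Association estimators and bootstrap uncertainty."""

import math

import pytest

from lexdrift.association import (
    bootstrap_ci,
    group_target_similarity,
    similarity_series,
)
from lexdrift.embedding import EmbedParams
from lexdrift.errors import VocabularyError

from conftest import make_model

SQRT2 = math.sqrt(2.0)


def geometry_model():
    return make_model(
        2013,
        {
            "base1": [1.0, 0.0],
            "base2": [0.0, 1.0],
            "tgt": [1 / SQRT2, 1 / SQRT2],
        },
    )


class TestPointEstimators:
    def test_singleton_base_group_degeneracy(self):
        model = make_model(2013, {"b": [1.0, 1.0], "t": [1.0, 0.0]})
        expected = 1 / SQRT2
        for method in ("centroid", "mean", "precision_weighted"):
            est = group_target_similarity(model, ["b"], "t", method)
            assert est.estimate == pytest.approx(expected)

    def test_centroid_and_mean_genuinely_differ(self):
        model = geometry_model()
        centroid = group_target_similarity(model, ["base1", "base2"], "tgt", "centroid")
        mean = group_target_similarity(model, ["base1", "base2"], "tgt", "mean")
        assert centroid.estimate == pytest.approx(1.0)
        assert mean.estimate == pytest.approx(1 / SQRT2)

    def test_inverse_variance_worked_example(self):
        # per-term cosines 0.1 and 0.3 with bootstrap variances 0.01 and 0.04
        model = make_model(
            2013,
            {
                "b1": [0.1, math.sqrt(1 - 0.01)],
                "b2": [0.3, math.sqrt(1 - 0.09)],
                "t": [1.0, 0.0],
            },
        )
        est = group_target_similarity(
            model, ["b1", "b2"], "t", "precision_weighted",
            term_variances={"b1": 0.01, "b2": 0.04},
        )
        assert est.estimate == pytest.approx(0.14, abs=1e-12)

    def test_equal_variances_reduce_to_mean(self):
        model = geometry_model()
        pw = group_target_similarity(
            model, ["base1", "base2"], "tgt", "precision_weighted",
            term_variances={"base1": 0.02, "base2": 0.02},
        )
        assert pw.estimate == pytest.approx(1 / SQRT2)

    def test_precision_weighted_within_per_term_range(self):
        model = geometry_model()
        est = group_target_similarity(
            model, ["base1", "base2"], "tgt", "precision_weighted",
            term_variances={"base1": 0.01, "base2": 0.5},
        )
        lo, hi = min(est.per_term.values()), max(est.per_term.values())
        assert lo <= est.estimate <= hi

    def test_fallback_to_mean_without_variances(self, caplog):
        model = geometry_model()
        with caplog.at_level("WARNING"):
            est = group_target_similarity(model, ["base1", "base2"], "tgt", "precision_weighted")
        assert est.estimate == pytest.approx(1 / SQRT2)
        assert "falling back" in caplog.text

    def test_oov_target_errors(self):
        with pytest.raises(VocabularyError, match="missing"):
            group_target_similarity(geometry_model(), ["base1"], "missing")

    def test_all_base_oov_errors(self):
        with pytest.raises(VocabularyError):
            group_target_similarity(geometry_model(), ["nope1", "nope2"], "tgt")

    def test_partial_base_oov_drops_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            est = group_target_similarity(geometry_model(), ["base1", "nope"], "tgt", "mean")
        assert est.n_base_terms_used == 1
        assert "absent" in caplog.text


class TestTermBootstrap:
    def test_singleton_base_has_zero_width_ci(self):
        model = make_model(2013, {"b": [1.0, 1.0], "t": [1.0, 0.0]})
        est = bootstrap_ci(
            None, None, ["b"], "t", method="mean", n_boot=25,
            boot_seed=1, mode="terms", model=model,
        )
        assert est.ci_low == est.ci_high == pytest.approx(est.estimate)

    def test_single_replicate_collapses_percentiles(self):
        model = geometry_model()
        est = bootstrap_ci(
            None, None, ["base1", "base2"], "tgt", method="mean",
            n_boot=1, boot_seed=2, mode="terms", model=model,
        )
        assert est.ci_low == est.ci_high
        assert est.n_boot == 1

    def test_replicates_stay_in_cosine_range(self):
        model = geometry_model()
        est = bootstrap_ci(
            None, None, ["base1", "base2"], "tgt", method="centroid",
            n_boot=40, boot_seed=3, mode="terms", model=model,
        )
        assert -1.0 <= est.ci_low <= est.ci_high <= 1.0


class TestDocumentBootstrap:
    def test_point_inside_percentile_ci(self, small_corpus):
        params = EmbedParams(dim=40, epochs=3, seed=5)
        est = bootstrap_ci(
            small_corpus, params,
            ["metastatic", "mets", "metastasis", "metastasized"],
            "palliative", method="centroid", n_boot=6, boot_seed=11,
        )
        assert est.n_boot >= 5  # at most one discard on this corpus
        assert est.ci_low <= est.estimate <= est.ci_high

    def test_reproducible_given_boot_seed(self, small_corpus, small_model):
        kw = dict(
            base_terms=["metastatic", "mets"], target="palliative",
            method="mean", n_boot=3, boot_seed=21, model=small_model,
        )
        e1 = bootstrap_ci(small_corpus, small_model.params, **kw)
        e2 = bootstrap_ci(small_corpus, small_model.params, **kw)
        assert (e1.estimate, e1.ci_low, e1.ci_high) == (e2.estimate, e2.ci_low, e2.ci_high)


class TestSeries:
    def models(self, missing_year=None):
        out = {}
        for i, year in enumerate(range(2013, 2021)):
            vecs = {
                "b": [1.0, 0.2 * i + 0.1],
                "t": [1.0, 0.0],
                "x": [0.0, 1.0],
            }
            if year == missing_year:
                vecs.pop("t")
            out[year] = make_model(year, vecs)
        return out

    def test_one_estimate_per_year_in_order(self):
        s = similarity_series({}, self.models(), ["b"], "t", method="mean")
        assert s.years == list(range(2013, 2021))
        assert s.gaps == []

    def test_missing_target_year_becomes_gap(self, caplog):
        with caplog.at_level("WARNING"):
            s = similarity_series({}, self.models(missing_year=2016), ["b"], "t", method="mean")
        assert len(s.estimates) == 7
        assert s.gaps == [2016]
        assert 2016 not in s.years

    def test_estimates_bounded(self):
        s = similarity_series({}, self.models(), ["b"], "t", method="centroid")
        for e in s.estimates:
            assert -1.0 <= e.estimate <= 1.0
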