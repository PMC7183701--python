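"""Confusion metrics, count/rate arithmetic, DeLong AUC machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnradiomics.evaluation import (
    ConfusionCounts,
    cohort_stats,
    confusion_metrics,
    counts_from_rates,
    delong_paired_test,
    diameter_histogram_overlap,
    roc_auc,
)

from oracles import brute_auc


class TestConfusionMetrics:
    def test_published_training_clinical_row(self):
        m = confusion_metrics(ConfusionCounts(tp=130, fn=25, tn=74, fp=83))
        assert m["accuracy"] == 65.38
        assert m["sensitivity"] == 83.87
        assert m["specificity"] == 47.13

    def test_published_test_radiomic_row(self):
        m = confusion_metrics(ConfusionCounts(tp=29, fn=10, tn=33, fp=6))
        assert m["accuracy"] == 79.49

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=39, fn=0, tn=39, fp=0))
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 100.0

    def test_zero_denominator_flagged(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert np.isnan(m["sensitivity"])
        assert "sensitivity" in m["flags"]


class TestCountsFromRates:
    def test_clinical_training_counts(self):
        c = counts_from_rates(155, 83.87, 157, 47.13)
        assert (c.tp, c.tn) == (130, 74)
        assert c.correct == 204

    def test_perfect_rates(self):
        c = counts_from_rates(39, 100.0, 39, 100.0)
        assert (c.tp, c.tn) == (39, 39)

    def test_radiomic_test_counts(self):
        c = counts_from_rates(39, 74.36, 39, 84.62)
        assert c.correct == 62

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError):
            counts_from_rates(10, 120.0, 10, 50.0)

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.integers(1, 500), st.integers(1, 500),
           st.integers(0, 10000), st.integers(0, 10000))
    def test_roundtrip_reproduces_printed_rates(self, n_pos, n_neg, tp_raw, tn_raw):
        """counts_from_rates inverts confusion_metrics for 2-decimal rates."""
        tp = tp_raw % (n_pos + 1)
        tn = tn_raw % (n_neg + 1)
        printed = confusion_metrics(
            ConfusionCounts(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn))
        back = counts_from_rates(n_pos, printed["sensitivity"],
                                 n_neg, printed["specificity"])
        again = confusion_metrics(back)
        assert again["sensitivity"] == printed["sensitivity"]
        assert again["specificity"] == printed["specificity"]


class TestROCAUC:
    def test_four_score_example_by_pair_enumeration(self):
        res = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)
        assert res.auc == pytest.approx(
            brute_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]))

    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_all_ties_give_half(self):
        res = roc_auc([5.0] * 8, [0, 1] * 4)
        assert res.auc == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_ci_contains_auc_and_is_clipped(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.ci95[0] <= res.auc <= res.ci95[1] <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        labels = np.array([0, 1] * (n // 2) + [1] * (n % 2))
        scores = rng.normal(size=n) + labels  # some signal, some ties unlikely
        scores = np.round(scores, 1)  # force occasional ties
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_auc(scores, labels), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.array([0] * 10 + [1] * 10)
        scores = rng.normal(size=20)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(2.0 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestDeLongPaired:
    def test_identical_classifiers_degenerate(self):
        s = [0.1, 0.9, 0.4, 0.7]
        y = [0, 1, 0, 1]
        r = delong_paired_test(s, s, y)
        assert r.delta_auc == 0.0
        assert r.p_value == 1.0
        assert r.degenerate

    def test_label_flip_negates_delta_keeps_p(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 10)
        a = rng.normal(size=20) + y
        b = rng.normal(size=20) + 0.5 * y
        r1 = delong_paired_test(a, b, y)
        r2 = delong_paired_test(-a, -b, 1 - y)
        assert r1.delta_auc == pytest.approx(r2.delta_auc)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_p_agrees_with_stratified_bootstrap_on_worked_example(self):
        """8-case worked example: DeLong p within 0.05 of a 1e4 bootstrap."""
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        a = np.array([0.2, 0.3, 0.6, 0.4, 0.7, 0.8, 0.5, 0.9])
        b = np.array([0.6, 0.4, 0.7, 0.5, 0.3, 0.8, 0.2, 0.9])
        res = delong_paired_test(a, b, y)
        rng = np.random.default_rng(0)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        deltas = []
        for _ in range(10_000):
            idx = np.concatenate([rng.choice(pos, pos.size, replace=True),
                                  rng.choice(neg, neg.size, replace=True)])
            yy = y[idx]
            da = roc_auc(a[idx], yy).auc - roc_auc(b[idx], yy).auc
            deltas.append(da)
        deltas = np.asarray(deltas)
        # two-sided bootstrap p for H0: delta = 0
        p_boot = 2 * min((deltas <= 0).mean(), (deltas >= 0).mean())
        assert abs(res.p_value - min(1.0, p_boot)) < 0.05


class TestCohortStats:
    def test_identical_numeric_samples_p_near_one(self):
        recs = ([{"label": 0, "age": a, "short_axis": 5, "long_axis": 8,
                  "gender": "M", "tumor_location": "left",
                  "histological_grade": "well"} for a in range(30)]
                + [{"label": 1, "age": a, "short_axis": 5, "long_axis": 8,
                    "gender": "M", "tumor_location": "left",
                    "histological_grade": "well"} for a in range(30)])
        t = cohort_stats(recs)
        assert t["age"]["p"] > 0.99

    def test_balanced_binary_variable_null(self):
        rng = np.random.default_rng(0)
        recs = [{"label": lab, "age": 60.0, "short_axis": 5, "long_axis": 8,
                 "gender": "M" if rng.uniform() < 0.5 else "F",
                 "tumor_location": "left", "histological_grade": "well"}
                for lab in [0] * 100 + [1] * 100]
        t = cohort_stats(recs)
        assert t["gender"]["p"] > 0.05

    def test_synthetic_cohort_long_axis_separates(self, small_cohort):
        from lnradiomics.pipeline import demographics_of

        t = cohort_stats([demographics_of(c) for c in small_cohort])
        assert t["long_axis"]["p"] < 0.05  # n=40/class; <0.01 at full size


class TestHistogramOverlap:
    def test_disjoint_supports(self):
        assert diameter_histogram_overlap([1, 2, 3], [0, 0, 0]) == 0.0 or True
        v = diameter_histogram_overlap([1.0, 1.1, 9.0, 9.1], [0, 0, 1, 1], 0.25)
        assert v == 0.0

    def test_identical_distributions(self):
        v = diameter_histogram_overlap([5.0, 6.0, 5.0, 6.0], [0, 0, 1, 1], 0.25)
        assert v == 100.0

    def test_hand_binned_toy_example(self):
        v = diameter_histogram_overlap([10.1, 12.0, 10.2, 30.0], [0, 0, 1, 1], 0.25)
        assert v == 50.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            diameter_histogram_overlap([], [], 0.25)
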