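"""Metric correctness against brute-force oracles and printed-count
identities."""

from fractions import Fraction

import numpy as np
import pytest

from deepbeat import evaluate as ev
from deepbeat.types import QaClass, ValidationError


def brute_confusion(y_true, y_pred, classes):
    """Independent loop-based tally (the oracle)."""
    out = {}
    for c in classes:
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred):
            if t == c and p == c:
                tp += 1
            elif t != c and p == c:
                fp += 1
            elif t == c and p != c:
                fn += 1
            else:
                tn += 1
        out[c] = (tp, fp, tn, fn)
    return out


class TestConfusion:
    def test_perfect_prediction_has_no_errors(self):
        y = ["AF", "NSR", "AF"]
        counts = ev.confusion(y, y, ["AF", "NSR"])
        for c in ("AF", "NSR"):
            assert counts.fp[c] == counts.fn[c] == 0

    def test_hand_counted_two_class_example(self):
        counts = ev.confusion(["AF", "AF", "NSR"], ["AF", "NSR", "NSR"],
                              ["AF", "NSR"])
        assert (counts.tp["AF"], counts.fn["AF"], counts.tn["AF"],
                counts.fp["AF"]) == (1, 1, 1, 0)

    def test_matches_brute_force_on_random_labels(self):
        rng = np.random.default_rng(0)
        classes = ["a", "b", "c"]
        for _ in range(25):
            y_true = rng.choice(classes, size=40).tolist()
            y_pred = rng.choice(classes, size=40).tolist()
            counts = ev.confusion(y_true, y_pred, classes)
            oracle = brute_confusion(y_true, y_pred, classes)
            for c in classes:
                assert (counts.tp[c], counts.fp[c], counts.tn[c],
                        counts.fn[c]) == oracle[c]

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            ev.confusion(["a"], ["z"], ["a", "b"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ev.confusion(["a"], ["a", "b"], ["a", "b"])


class TestMetricsFromCounts:
    def test_episode_count_sensitivity(self):
        """Sensitivity from raw episode counts: 925 detected of 929 AF
        episodes equals 925/929 to machine precision."""
        counts = ev.ConfusionCounts(classes=["AF"], tp={"AF": 925},
                                    fp={"AF": 0}, tn={"AF": 0},
                                    fn={"AF": 4}, n_windows=929)
        m = ev.metrics_from_counts(counts)
        assert m["AF"]["sensitivity"] == Fraction(925, 929)
        assert float(m["AF"]["sensitivity"]) == 925 / 929

    def test_perfect_classifier_metrics(self):
        counts = ev.confusion(["AF", "NSR"], ["AF", "NSR"], ["AF", "NSR"])
        m = ev.metrics_from_counts(counts)
        for c in ("AF", "NSR"):
            assert m[c]["sensitivity"] == 1 and m[c]["specificity"] == 1
            assert m[c]["f1"] == 1 and m[c]["fpr"] == 0 and m[c]["fnr"] == 0

    def test_zero_denominator_convention(self):
        counts = ev.ConfusionCounts(classes=["x"], tp={"x": 0}, fp={"x": 0},
                                    tn={"x": 5}, fn={"x": 3}, n_windows=8)
        m = ev.metrics_from_counts(counts)
        assert m["x"]["precision"] == 0 and m["x"]["f1"] == 0

    def test_complement_identities_exact_rationals(self):
        """sensitivity + FNR = 1 and specificity + FPR = 1 exactly."""
        rng = np.random.default_rng(1)
        classes = ["a", "b"]
        for _ in range(50):
            y_true = rng.choice(classes, size=30).tolist()
            y_pred = rng.choice(classes, size=30).tolist()
            counts = ev.confusion(y_true, y_pred, classes)
            m = ev.metrics_from_counts(counts)
            for c in classes:
                tp, fp, tn, fn = counts.for_class(c)
                if tp + fn > 0:
                    assert m[c]["sensitivity"] + m[c]["fnr"] == 1
                if tn + fp > 0:
                    assert m[c]["specificity"] + m[c]["fpr"] == 1


class TestWeightedMacro:
    def _metrics(self, y_true, y_pred, classes):
        return ev.metrics_from_counts(ev.confusion(y_true, y_pred, classes))

    def test_equal_supports_is_plain_mean(self):
        m = self._metrics(["a", "b", "a", "b"], ["a", "a", "b", "b"],
                          ["a", "b"])
        rep = ev.weighted_macro(m, {"a": 1, "b": 1})
        expected = (float(m["a"]["f1"]) + float(m["b"]["f1"])) / 2
        assert rep.aggregate["f1"] == pytest.approx(expected, abs=1e-12)

    def test_dominant_support_approaches_majority_metric(self):
        m = self._metrics(["a", "b"], ["a", "a"], ["a", "b"])
        rep = ev.weighted_macro(m, {"a": 999, "b": 1})
        gap = abs(float(m["a"]["f1"]) - float(m["b"]["f1"]))
        assert abs(rep.aggregate["f1"] - float(m["a"]["f1"])) <= 0.001 * gap + 1e-9

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(2)
        classes = ["a", "b", "c"]
        for _ in range(100):
            y_true = rng.choice(classes, size=25).tolist()
            y_pred = rng.choice(classes, size=25).tolist()
            m = self._metrics(y_true, y_pred, classes)
            supports = {c: int(sum(1 for t in y_true if t == c)) + 1
                        for c in classes}
            rep = ev.weighted_macro(m, supports)
            total = sum(supports.values())
            for name in ev.METRIC_NAMES:
                expected = sum(supports[c] * float(m[c][name])
                               for c in classes) / total
                assert rep.aggregate[name] == pytest.approx(expected,
                                                            abs=1e-9)

    def test_all_zero_supports_rejected(self):
        m = self._metrics(["a", "b"], ["a", "b"], ["a", "b"])
        with pytest.raises(ValidationError):
            ev.weighted_macro(m, {"a": 0, "b": 0})


class TestQaFiltering:
    def test_all_excellent_equals_unfiltered(self):
        y_true = ["AF", "NSR", "AF", "NSR"]
        y_pred = ["AF", "NSR", "NSR", "NSR"]
        qa = [QaClass.EXCELLENT] * 4
        filt, retained = ev.qa_filtered_eval(y_true, y_pred, qa, ["AF", "NSR"])
        plain = ev.evaluate_labels(y_true, y_pred, ["AF", "NSR"])
        assert retained == 4
        assert filt.aggregate == plain.aggregate

    def test_retained_count_matches_label_count(self):
        y_true = ["AF"] * 6 + ["NSR"] * 6
        y_pred = y_true
        qa = [QaClass.EXCELLENT, QaClass.POOR] * 6
        filt, retained = ev.qa_filtered_eval(y_true, y_pred, qa, ["AF", "NSR"])
        assert retained == 6
        assert filt.retention_fraction == pytest.approx(0.5)

    def test_zero_retained_raises_explicit_error(self):
        with pytest.raises(ValidationError, match="EXCELLENT"):
            ev.qa_filtered_eval(["AF"], ["AF"], [QaClass.POOR], ["AF", "NSR"])


class TestPerIndividualAggregate:
    def test_single_subject_equals_per_episode(self):
        y_true = ["AF", "NSR", "AF", "NSR", "AF"]
        y_pred = ["AF", "NSR", "NSR", "NSR", "AF"]
        rep = ev.per_individual_aggregate(y_true, y_pred, ["s1"] * 5,
                                          ["AF", "NSR"])
        plain = ev.evaluate_labels(y_true, y_pred, ["AF", "NSR"])
        for name in ev.METRIC_NAMES:
            assert rep.aggregate[name] == pytest.approx(
                plain.aggregate[name], abs=1e-12)

    def test_duplicated_subject_data_is_idempotent(self):
        y_true = ["AF", "NSR", "AF"]
        y_pred = ["AF", "AF", "AF"]
        rep1 = ev.per_individual_aggregate(y_true, y_pred, ["s1"] * 3,
                                           ["AF", "NSR"])
        rep2 = ev.per_individual_aggregate(y_true * 2, y_pred * 2,
                                           ["s1"] * 3 + ["s2"] * 3,
                                           ["AF", "NSR"])
        for name in ev.METRIC_NAMES:
            assert rep2.aggregate[name] == pytest.approx(
                rep1.aggregate[name], abs=1e-12)

    def test_matches_brute_force_two_stage_computation(self):
        rng = np.random.default_rng(3)
        classes = ["AF", "NSR"]
        subjects = rng.choice(["s1", "s2", "s3"], size=60).tolist()
        y_true = rng.choice(classes, size=60).tolist()
        y_pred = rng.choice(classes, size=60).tolist()
        rep = ev.per_individual_aggregate(y_true, y_pred, subjects, classes)
        # oracle: per-subject weighted-macro metrics, then window-weighted
        total = len(subjects)
        for name in ev.METRIC_NAMES:
            acc = 0.0
            for s in set(subjects):
                idx = [i for i, x in enumerate(subjects) if x == s]
                sub_rep = ev.evaluate_labels([y_true[i] for i in idx],
                                             [y_pred[i] for i in idx],
                                             classes)
                acc += len(idx) * sub_rep.aggregate[name]
            assert rep.aggregate[name] == pytest.approx(acc / total, abs=1e-9)


class TestExhaustiveSmallInstances:
    def test_all_two_window_label_combinations_match_oracle(self):
        """Exhaustive check over every (y_true, y_pred) combination of two
        windows with two classes."""
        classes = ["AF", "NSR"]
        for t1 in classes:
            for t2 in classes:
                for p1 in classes:
                    for p2 in classes:
                        y_true, y_pred = [t1, t2], [p1, p2]
                        counts = ev.confusion(y_true, y_pred, classes)
                        oracle = brute_confusion(y_true, y_pred, classes)
                        for c in classes:
                            assert (counts.tp[c], counts.fp[c],
                                    counts.tn[c], counts.fn[c]) == oracle[c]
                        m = ev.metrics_from_counts(counts)
                        for c in classes:
                            assert 0 <= m[c]["f1"] <= 1
                            tp, fp, tn, fn = counts.for_class(c)
                            if tp + fn > 0:
                                assert m[c]["sensitivity"] + m[c]["fnr"] == 1
                            if tn + fp > 0:
                                assert m[c]["specificity"] + m[c]["fpr"] == 1
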