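"""Metrics against scalar oracles; curves against exhaustive sweeps."""

import math

import numpy as np
import pytest

from ppigray.evaluation import (ConfusionCounts, confusion_metrics,
                                member_dispersion, network_predict, pr_aupr,
                                roc_auc, top_u_precision)
from ppigray.io_formats import Pair


def metrics_oracle(tp, tn, fp, fn):
    """Direct scalar recomputation of the six formulas."""
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    den = math.sqrt((tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    acc = (tp + tn) / (tp + tn + fp + fn)
    return sens, spec, prec, f1, mcc, acc


def auc_oracle(probs, labels):
    """O(n^2) pairwise comparison with half-credit for ties."""
    pos = [p for p, l in zip(probs, labels) if l == 1]
    neg = [p for p, l in zip(probs, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def aupr_oracle(probs, labels):
    """Exhaustive sweep over all score thresholds, step-wise area."""
    order = np.argsort(-np.asarray(probs), kind="stable")
    labels = np.asarray(labels)[order]
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    sorted_probs = np.asarray(probs)[order]
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and sorted_probs[j] == sorted_probs[i]:
            tp += labels[j]
            fp += 1 - labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        report = confusion_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert all(v == 1.0 for v in report.as_dict().values())

    def test_hand_example(self):
        report = confusion_metrics(ConfusionCounts(tp=40, tn=45, fp=5, fn=10))
        assert report.sensitivity == pytest.approx(0.8)
        assert report.specificity == pytest.approx(0.9)
        assert report.accuracy == pytest.approx(0.85)
        sens, spec, prec, f1, mcc, acc = metrics_oracle(40, 45, 5, 10)
        assert report.f1 == pytest.approx(f1)
        assert report.mcc == pytest.approx(mcc)

    def test_against_oracle_on_random_matrices(self):
        rng = np.random.default_rng(77)
        for _ in range(1000):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 50, 4))
            if tp + tn + fp + fn == 0:
                continue
            report = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            expected = metrics_oracle(tp, tn, fp, fn)
            got = (report.sensitivity, report.specificity, report.precision,
                   report.f1, report.mcc, report.accuracy)
            np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 40, 4))
            a = confusion_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            b = confusion_metrics(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
            assert a.sensitivity == pytest.approx(b.specificity)
            assert a.specificity == pytest.approx(b.sensitivity)
            assert a.accuracy == pytest.approx(b.accuracy)
            assert abs(a.mcc) == pytest.approx(abs(b.mcc))

    def test_accuracy_complement_identity(self):
        counts = ConfusionCounts(tp=13, tn=17, fp=3, fn=7)
        report = confusion_metrics(counts)
        assert report.accuracy == 1 - (counts.fp + counts.fn) / counts.total

    def test_zero_denominator_flags_not_crash(self):
        report = confusion_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert report.sensitivity == 0.0
        assert "sensitivity" in report.degenerate

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, tn=0, fp=0, fn=0)


class TestRocAuc:
    def test_perfect_separation(self):
        area, _, _ = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert area == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        probs = rng.random(n)
        labels = rng.integers(0, 2, n)
        area, _, _ = roc_auc(probs, labels)
        # permutation expectation 0.5, tolerance 3 standard errors
        se = math.sqrt((n + 1) / (12 * labels.sum() * (n - labels.sum())))
        assert abs(area - 0.5) < 3 * se

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            labels = np.concatenate([[0, 1], rng.integers(0, 2, n - 2)])
            probs = np.round(rng.random(n), 1)  # coarse grid to force ties
            area, _, _ = roc_auc(probs, labels)
            assert area == pytest.approx(auc_oracle(probs, labels), rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        probs = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a1, _, _ = roc_auc(probs, labels)
        a2, _, _ = roc_auc(np.exp(3 * probs), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.5, 0.6]), np.array([1, 1]))


class TestPrAupr:
    def test_perfect_separation(self):
        area, _, _ = pr_aupr(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert area == pytest.approx(1.0)

    def test_all_positive_labels(self):
        area, recall, precision = pr_aupr(np.array([0.9, 0.4, 0.1]),
                                          np.array([1, 1, 1]))
        assert np.all(precision == 1.0)

    def test_matches_exhaustive_sweep_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(5, 25))
            labels = np.concatenate([[1], rng.integers(0, 2, n - 1)])
            probs = rng.random(n)
            area, _, _ = pr_aupr(probs, labels)
            assert area == pytest.approx(aupr_oracle(probs, labels), rel=1e-10)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_aupr(np.array([0.5]), np.array([0]))


class TestTopU:
    def test_all_top_positive(self):
        probs = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        assert top_u_precision(probs, labels, 3) == 1.0

    def test_u_equals_n(self):
        labels = np.array([1, 0, 1, 0])
        assert top_u_precision(np.arange(4) / 4, labels, 4) == 0.5

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(10, 60))
            probs = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            u = int(rng.integers(1, n + 1))
            order = sorted(range(n), key=lambda i: (-probs[i], i))
            expected = sum(labels[i] for i in order[:u]) / u
            assert top_u_precision(probs, labels, u) == pytest.approx(expected)

    def test_n_below_u_rejected(self):
        with pytest.raises(ValueError):
            top_u_precision(np.array([0.5]), np.array([1]), 2)


class TestNetworkPredict:
    def _pairs(self, n):
        return [Pair(f"a{i}", f"b{i}", "unknown") for i in range(n)]

    def test_interaction_mode_matches_default_classification(self):
        probs = np.array([0.9, 0.4, 0.6])
        edges = network_predict(probs, self._pairs(3), 0.5, "interaction")
        assert [e[0] for e in edges] == ["a0", "a2"]

    def test_non_interaction_mode(self):
        probs = np.array([0.005, 0.5, 0.002])
        edges = network_predict(probs, self._pairs(3), 0.01, "non_interaction")
        assert [e[0] for e in edges] == ["a0", "a2"]

    def test_threshold_sweep_produces_nested_sets(self):
        rng = np.random.default_rng(9)
        probs = rng.random(200)
        pairs = self._pairs(200)
        previous = None
        for threshold in (0.5, 0.8, 0.9, 0.95, 0.98):
            edges = {(a, b) for a, b, _ in
                     network_predict(probs, pairs, threshold, "interaction")}
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_misaligned_scores_rejected(self):
        with pytest.raises(ValueError):
            network_predict(np.array([0.5]), self._pairs(2), 0.5)


class TestMemberDispersion:
    def test_mean_sd_variance_consistency(self):
        rng = np.random.default_rng(11)
        member_probs = rng.random((5, 40))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        out = member_dispersion(member_probs, y)
        for stats in out.values():
            assert stats["variance"] == pytest.approx(stats["sd"] ** 2)
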