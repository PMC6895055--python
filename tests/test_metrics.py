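"""Evaluation-metric semantics: direct substitutions, conventions and
equivalence with brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from aimtk import metrics

from .oracles import auc_pairs, bf_bruteforce, iou_bruteforce, recall_bruteforce


def square_mask(size, r0, c0, h, w):
    m = np.zeros((size, size), dtype=int)
    m[r0 : r0 + h, c0 : c0 + w] = 1
    return m


class TestPixelScores:
    def test_recall_direct_substitution(self):
        # TP=9, FN=1 -> 0.9
        truth = np.zeros((5, 5), dtype=int)
        truth[:2, :5] = 1  # 10 truth pixels
        pred = truth.copy()
        pred[0, 0] = 0  # one miss
        assert metrics.pixel_recall(pred, truth)[1] == pytest.approx(0.9)

    def test_recall_identity_and_empty_pred(self):
        truth = square_mask(8, 2, 2, 3, 3)
        assert metrics.pixel_recall(truth, truth)[1] == 1.0
        assert metrics.pixel_recall(np.zeros_like(truth), truth)[1] == 0.0

    def test_iou_overlapping_rectangles(self):
        # two 2x4 rectangles overlapping in 2x2: TP=4, FP=4, FN=4 -> 1/3
        truth = square_mask(8, 0, 0, 2, 4)
        pred = square_mask(8, 0, 2, 2, 4)
        assert metrics.iou_score(pred, truth)[1] == pytest.approx(1 / 3)

    def test_iou_identity_and_disjoint(self):
        a = square_mask(8, 0, 0, 2, 2)
        b = square_mask(8, 4, 4, 2, 2)
        assert metrics.iou_score(a, a)[1] == 1.0
        assert metrics.iou_score(a, b)[1] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            metrics.pixel_recall(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_iou_bounded_by_precision_and_recall(self, rng):
        # IoU <= min(precision, recall), provable from the count formulas
        for _ in range(50):
            pred = rng.integers(0, 2, (16, 16))
            truth = rng.integers(0, 2, (16, 16))
            pc = metrics.pixel_counts(pred, truth, 1)
            if pc.tp + pc.fp == 0 or pc.tp + pc.fn == 0:
                continue
            iou = metrics.iou_score(pred, truth)[1]
            prec = pc.tp / (pc.tp + pc.fp)
            rec = pc.tp / (pc.tp + pc.fn)
            assert iou <= min(prec, rec) + 1e-12


class TestBFScore:
    def test_identity_is_one(self):
        m = square_mask(16, 4, 4, 6, 6)
        assert metrics.bf_score(m, m, 2.0) == 1.0

    def test_one_empty_is_zero(self):
        m = square_mask(16, 4, 4, 6, 6)
        z = np.zeros_like(m)
        assert metrics.bf_score(z, m, 2.0) == 0.0
        assert metrics.bf_score(m, z, 2.0) == 0.0
        assert metrics.bf_score(z, z, 2.0) == 1.0

    def test_shifted_square_tolerance(self):
        # 6x6 square shifted by 1 px: every boundary pixel within sqrt(2)
        truth = square_mask(16, 4, 4, 6, 6)
        pred = square_mask(16, 5, 5, 6, 6)
        assert metrics.bf_score(pred, truth, 2.0) == 1.0
        # at theta=1 the diagonal-corner pixels (distance sqrt 2) fail
        bf1 = metrics.bf_score(pred, truth, 1.0)
        assert bf1 == pytest.approx(bf_bruteforce(pred, truth, 1.0), abs=1e-12)
        assert bf1 < 1.0

    def test_theta_fraction_of_diagonal(self):
        m = square_mask(100, 10, 10, 30, 30)
        # 0.0075 * sqrt(2) * 100 ~ 1.06 px
        assert metrics.bf_score(m, m, 0.0075) == 1.0
        with pytest.raises(ValueError):
            metrics.bf_score(m, m, -1.0)

    def test_symmetry_and_theta_monotonicity(self, rng):
        for _ in range(20):
            a = rng.integers(0, 2, (20, 20))
            b = rng.integers(0, 2, (20, 20))
            assert metrics.bf_score(a, b, 2.0) == pytest.approx(
                metrics.bf_score(b, a, 2.0), abs=1e-12
            )
            scores = [metrics.bf_score(a, b, th) for th in (1.0, 1.5, 2.0, 3.0, 5.0)]
            assert all(s1 >= s0 - 1e-12 for s0, s1 in zip(scores, scores[1:]))

    def test_oracle_equivalence_random_masks(self, rng):
        for _ in range(60):
            h, w = rng.integers(5, 33, 2)
            pred = (rng.random((h, w)) < 0.4).astype(int)
            truth = (rng.random((h, w)) < 0.4).astype(int)
            theta = float(rng.uniform(1.0, 6.0))
            got = metrics.bf_score(pred, truth, theta)
            want = bf_bruteforce(pred, truth, theta)
            assert got == pytest.approx(want, abs=1e-12)


class TestConfusionAndAccuracy:
    def test_perfect_predictions(self, rng):
        truth = list(rng.integers(0, 3, 50))
        cm, acc = metrics.confusion_and_accuracy(truth, truth)
        assert acc == 1.0
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_binary_substitution(self):
        # TP=40, TN=50, FP=5, FN=5 -> 0.9
        truth = ["pos"] * 45 + ["neg"] * 55
        pred = ["pos"] * 40 + ["neg"] * 5 + ["pos"] * 5 + ["neg"] * 50
        cm, acc = metrics.confusion_and_accuracy(pred, truth)
        assert acc == pytest.approx(0.9)

    def test_constant_prediction_balanced_four_class(self):
        truth = [c for c in "abcd" for _ in range(10)]
        pred = ["a"] * 40
        _, acc = metrics.confusion_and_accuracy(pred, truth)
        assert acc == pytest.approx(0.25)

    def test_unseen_label_warns(self):
        with pytest.warns(UserWarning, match="not in truth"):
            cm, _ = metrics.confusion_and_accuracy(["a", "z"], ["a", "a"])
        assert "z" in cm.classes


class TestROC:
    def test_perfect_separation(self):
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        curves = metrics.roc_one_vs_rest(probs, [0, 0, 1, 1])
        assert all(c.auc == 1.0 for c in curves)

    def test_all_tied_scores(self):
        probs = np.full((6, 2), 0.5)
        curves = metrics.roc_one_vs_rest(probs, [0, 0, 0, 1, 1, 1])
        assert all(c.auc == pytest.approx(0.5) for c in curves)

    def test_three_item_example(self):
        # positives scored [0.9, 0.4], negative 0.6 -> 1 of 2 pairs ordered
        probs = np.array([[0.9, 0.1], [0.4, 0.6], [0.6, 0.4]])
        curves = metrics.roc_one_vs_rest(probs, [0, 0, 1], class_names=[0, 1])
        auc0 = next(c.auc for c in curves if c.class_name == 0)
        assert auc0 == pytest.approx(0.5)

    def test_absent_class_omitted(self):
        probs = np.array([[0.7, 0.3], [0.6, 0.4]])
        curves = metrics.roc_one_vs_rest(probs, [0, 0], class_names=[0, 1])
        assert [c.class_name for c in curves] == [0]

    def test_curve_monotone_and_endpoints(self, rng):
        probs = rng.dirichlet(np.ones(3), size=40)
        truth = rng.integers(0, 3, 40)
        for c in metrics.roc_one_vs_rest(probs, truth):
            assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)
            assert c.fpr[0] == 0 and c.tpr[0] == 0
            assert c.fpr[-1] == pytest.approx(1.0) and c.tpr[-1] == pytest.approx(1.0)

    def test_auc_equals_pair_statistic_and_sklearn(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 30))
            scores = np.round(rng.random(n), 2)  # coarse grid to force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            probs = np.column_stack([1 - scores, scores])
            curves = metrics.roc_one_vs_rest(probs, labels, class_names=[0, 1])
            auc1 = next(c.auc for c in curves if c.class_name == 1)
            assert auc1 == pytest.approx(auc_pairs(scores, labels == 1), abs=1e-12)
            assert auc1 == pytest.approx(roc_auc_score(labels, scores), abs=1e-10)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="simplic"):
            metrics.roc_one_vs_rest(np.array([[0.9, 0.3]]), [0])


def test_recall_iou_match_bruteforce_oracles(rng):
    for _ in range(60):
        h, w = rng.integers(4, 33, 2)
        pred = rng.integers(0, 3, (h, w))
        truth = rng.integers(0, 3, (h, w))
        got_r = metrics.pixel_recall(pred, truth)
        got_i = metrics.iou_score(pred, truth)
        for cls in (1, 2):
            if cls in got_r:
                assert got_r[cls] == pytest.approx(
                    recall_bruteforce(pred, truth, cls), abs=1e-12
                )
                assert got_i[cls] == pytest.approx(
                    iou_bruteforce(pred, truth, cls), abs=1e-12
                )
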