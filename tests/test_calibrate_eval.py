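"""Threshold calibration and the multi-label evaluation metrics.

Calibration is checked against an independent exhaustive grid search,
dice against scikit-learn's F1, and the multi-label confusion matrix
against a from-scratch enumeration of the attribution rule.
"""

import itertools

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.metrics import f1_score

from protloc.calibrate_eval import (
    ConfusionMatrix,
    ThresholdSet,
    accuracy_by_multiloc,
    apply_thresholds,
    calibrate_thresholds,
    cooccurrence_matrix,
    dice_for_class,
    evaluate,
    groupwise_dice,
    mean_diag_accuracy,
    multilabel_confusion,
    per_class_dice,
)
from protloc.classes import CLASS_INDEX, N_CLASSES


class TestDice:
    def test_closed_form(self):
        pred = np.array([1, 1, 1, 0, 0])
        true = np.array([1, 1, 0, 1, 0])        # TP=2 FP=1 FN=1
        assert dice_for_class(pred, true) == pytest.approx(4 / 6)

    def test_perfect_prediction(self):
        v = np.array([1, 0, 1])
        assert dice_for_class(v, v) == 1.0

    def test_zero_denominator_convention(self):
        z = np.zeros(5)
        assert dice_for_class(z, z) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dice_for_class(np.zeros(3), np.zeros(4))

    def test_equals_f1_score(self, rng):
        for _ in range(100):
            pred = rng.random(30) > 0.5
            true = rng.random(30) > 0.5
            assert dice_for_class(pred, true) == pytest.approx(
                f1_score(true, pred, zero_division=0.0), abs=1e-12
            )


def brute_force_thresholds(conf, truth):
    """Independent exhaustive search over the 0.01 grid."""
    out = np.zeros(conf.shape[1])
    for c in range(conf.shape[1]):
        best_d, best_t = -1.0, None
        for k in range(101):
            t = k / 100.0
            d = dice_for_class(conf[:, c] >= t, truth[:, c])
            if d > best_d:                       # strict: keep smallest maximizer
                best_d, best_t = d, t
        out[c] = best_t
    return out


class TestCalibration:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        conf = rng.random((50, N_CLASSES))
        truth = rng.random((50, N_CLASSES)) > 0.6
        ts = calibrate_thresholds(conf, truth)
        np.testing.assert_allclose(ts.thresholds, brute_force_thresholds(conf, truth))

    def test_tie_breaks_to_smallest_grid_value(self):
        conf = np.tile(np.array([0.2, 0.4, 0.6, 0.8])[:, None], (1, N_CLASSES))
        truth = np.tile(np.array([0, 0, 1, 1])[:, None], (1, N_CLASSES))
        ts = calibrate_thresholds(conf, truth)
        assert (ts.thresholds == 0.41).all()     # any t in (0.40, 0.60] is perfect

    def test_already_perfect_at_zero(self):
        conf = np.full((4, N_CLASSES), 0.9)
        truth = np.ones((4, N_CLASSES))
        ts = calibrate_thresholds(conf, truth)
        assert (ts.thresholds == 0.0).all()

    def test_invariant_to_sample_order(self, rng):
        conf = rng.random((30, N_CLASSES))
        truth = rng.random((30, N_CLASSES)) > 0.5
        perm = rng.permutation(30)
        a = calibrate_thresholds(conf, truth).thresholds
        b = calibrate_thresholds(conf[perm], truth[perm]).thresholds
        np.testing.assert_array_equal(a, b)

    def test_grid_membership(self, rng):
        conf = rng.random((20, N_CLASSES))
        truth = rng.random((20, N_CLASSES)) > 0.5
        ts = calibrate_thresholds(conf, truth)
        ts.validate()


def test_apply_thresholds_inclusive_boundary():
    ts = ThresholdSet(np.full(N_CLASSES, 0.5))
    conf = np.full((1, N_CLASSES), 0.5)
    assert apply_thresholds(conf, ts).all()      # >= rule: equality predicts present
    assert not apply_thresholds(conf - 1e-9, ts).any()
    assert apply_thresholds(np.zeros((2, N_CLASSES)), ThresholdSet(np.zeros(N_CLASSES))).all()


def enumerate_rule(true_sets, pred_sets, n_classes=N_CLASSES):
    """From-scratch restatement of the attribution rule."""
    counts = np.zeros((n_classes, n_classes), dtype=int)
    totals = np.zeros(n_classes, dtype=int)
    for T, P in zip(true_sets, pred_sets):
        for c in T:
            totals[c] += 1
            if c in P:
                counts[c][c] += 1
            else:
                for fp in P:
                    if fp not in T:
                        counts[c][fp] += 1
    return counts, totals


class TestMultilabelConfusion:
    def test_caption_example(self):
        NU, NI, CY = CLASS_INDEX["NU"], CLASS_INDEX["NI"], CLASS_INDEX["CY"]
        cm = multilabel_confusion([{NU, NI}], [{NU, CY}])
        assert cm.counts[NU, NU] == 1
        assert cm.counts[NI, CY] == 1
        assert cm.counts.sum() == 2

    def test_exact_match_only_diagonal(self):
        NU = CLASS_INDEX["NU"]
        cm = multilabel_confusion([{NU}], [{NU}])
        assert cm.counts[NU, NU] == 1 and cm.counts.sum() == 1

    def test_missed_label_without_false_positive(self):
        AF = CLASS_INDEX["AF"]
        cm = multilabel_confusion([{AF}], [set()])
        assert cm.row_totals[AF] == 1 and cm.counts.sum() == 0
        assert cm.normalized[AF, AF] == 0.0

    def test_enumeration_over_small_alphabet(self):
        """All (T, P) pairs with |T| <= 2, |P| <= 2 over 4 classes."""
        classes = [0, 1, 2, 3]
        subsets = [set(c) for r in (1, 2) for c in itertools.combinations(classes, r)]
        psets = [set()] + subsets
        T, P = [], []
        for t in subsets:
            for p in psets:
                T.append(t)
                P.append(p)
        cm = multilabel_confusion(T, P)
        counts, totals = enumerate_rule(T, P)
        np.testing.assert_array_equal(cm.counts, counts)
        np.testing.assert_array_equal(cm.row_totals, totals)

    def test_reduces_to_classical_confusion_for_single_labels(self, rng):
        """Single-label truth + single-label predictions = classical matrix."""
        y_true = rng.integers(0, 3, size=60)
        y_pred = rng.integers(0, 3, size=60)
        cm = multilabel_confusion([{t} for t in y_true], [{p} for p in y_pred])
        classical = sk_confusion(y_true, y_pred, labels=range(N_CLASSES))
        np.testing.assert_array_equal(cm.counts, classical)

    def test_diagonal_counts_equal_total_hits(self, rng):
        T = [set(rng.choice(13, size=rng.integers(1, 4), replace=False)) for _ in range(50)]
        P = [set(rng.choice(13, size=rng.integers(0, 4), replace=False)) for _ in range(50)]
        cm = multilabel_confusion(T, P)
        hits = sum(len(t & p) for t, p in zip(T, P))
        assert np.diag(cm.counts).sum() == hits

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError):
            multilabel_confusion([], [])


class TestMeanDiagAccuracy:
    def test_arithmetic_mean(self):
        counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
        totals = np.zeros(N_CLASSES, dtype=int)
        counts[0, 0], totals[0] = 4, 4           # 1.0
        counts[1, 1], totals[1] = 1, 2           # 0.5
        assert mean_diag_accuracy(ConfusionMatrix(counts, totals)) == pytest.approx(0.75)

    def test_absent_class_excluded_with_warning(self, caplog):
        counts = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
        totals = np.zeros(N_CLASSES, dtype=int)
        counts[0, 0], totals[0] = 2, 2
        with caplog.at_level("WARNING"):
            acc = mean_diag_accuracy(ConfusionMatrix(counts, totals))
        assert acc == 1.0
        assert "excluded" in caplog.text

    def test_all_rows_empty_rejected(self):
        z = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
        with pytest.raises(ValueError):
            mean_diag_accuracy(ConfusionMatrix(z, np.zeros(N_CLASSES, dtype=int)))


class TestAccuracyByMultiloc:
    def test_exact_match_counts(self):
        T = [{0}, {0, 1}, {0, 1, 2}]
        out = accuracy_by_multiloc(T, T)
        assert all(out[k]["correct_fraction"] == 1.0 for k in (1, 2, 3))
        assert np.isnan(out[4]["correct_fraction"])

    def test_partial_retrieval_is_incorrect_under_exact_match(self):
        T, P = [{0, 1, 2}], [{0, 1}]
        assert accuracy_by_multiloc(T, P)[3]["correct_fraction"] == 0.0
        assert accuracy_by_multiloc(T, P, rule="all_found")[3]["correct_fraction"] == 0.0
        assert accuracy_by_multiloc([{0, 1}], [{0, 1, 2}], rule="all_found")[2][
            "correct_fraction"
        ] == 1.0


class TestCooccurrence:
    def test_direct_counting(self):
        NU, NI, CY = CLASS_INDEX["NU"], CLASS_INDEX["NI"], CLASS_INDEX["CY"]
        m = cooccurrence_matrix([{NU}, {NU, NI}, {NI, CY}])
        assert m[NU, NI] == pytest.approx(0.5)
        assert m[NI, NU] == pytest.approx(0.5)
        assert m[NI, CY] == pytest.approx(0.5)

    def test_single_label_dataset_is_diagonal(self):
        m = cooccurrence_matrix([{i} for i in range(5)])
        np.testing.assert_array_equal(m, np.diag([1.0] * 5 + [0.0] * 8))

    def test_diagonal_one_for_represented_classes(self, rng):
        sets = [set(rng.choice(13, size=rng.integers(1, 4), replace=False)) for _ in range(30)]
        m = cooccurrence_matrix(sets)
        rep = sorted(set().union(*sets))
        assert all(m[r, r] == 1.0 for r in rep)


class TestGroupwiseDice:
    def test_single_group_equals_global_mean_dice(self, rng):
        conf = rng.random((40, N_CLASSES))
        truth = rng.random((40, N_CLASSES)) > 0.5
        ts = calibrate_thresholds(conf, truth)
        out = groupwise_dice(conf, truth, ts, ["only"] * 40)
        d = per_class_dice(apply_thresholds(conf, ts), truth)
        present = truth.sum(axis=0) > 0
        assert out == {"only": pytest.approx(d[present].mean())}

    def test_perfect_and_failing_groups(self):
        truth = np.zeros((4, N_CLASSES))
        truth[:, 0] = 1
        conf = np.zeros((4, N_CLASSES))
        conf[:2, 0] = 0.9                        # group a: perfect, group b: missed
        ts = ThresholdSet(np.full(N_CLASSES, 0.5))
        out = groupwise_dice(conf, truth, ts, ["a", "a", "b", "b"], major_groups=["a", "b"])
        assert out["a"] == 1.0 and out["b"] == 0.0

    def test_misaligned_tags_rejected(self, rng):
        conf = rng.random((4, N_CLASSES))
        with pytest.raises(ValueError):
            groupwise_dice(conf, conf > 0.5, ThresholdSet(np.zeros(N_CLASSES)), ["a"])


def test_perfect_classifier_stub_end_to_end(rng):
    """Well-separated single-label truth + near-oracle confidences -> ~1.0."""
    n = 120
    truth = np.zeros((n, N_CLASSES))
    truth[np.arange(n), rng.integers(0, N_CLASSES, n)] = 1
    conf = truth * rng.uniform(0.8, 1.0, truth.shape) + (1 - truth) * rng.uniform(
        0.0, 0.2, truth.shape
    )
    ts = calibrate_thresholds(conf, truth)
    report = evaluate(conf, truth, ts, group_tags=["g"] * n)
    assert report.mean_diag_accuracy >= 0.99
    assert report.mean_dice >= 0.99
    assert report.by_multiloc[1]["correct_fraction"] >= 0.99
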