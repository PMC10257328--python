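"""The five classifiers, confusion counting and the evaluation formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fpbow.classify import ClassifierSpec, confusion, evaluate, fit_predict, metrics


class TestFitPredict:
    def test_knn_majority_rule(self):
        # three nearest training points of the query are all active
        xtr = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        ytr = np.array([1, 1, 1, 0, 0, 0])
        pred = fit_predict("knn", xtr, ytr, np.array([[0.05]]))
        assert pred.tolist() == [1]

    def test_seeded_rf_memorizes_separable_data(self, rng):
        x = rng.normal(size=(100, 5))
        y = (x[:, 0] > 0).astype(int)
        pred = fit_predict(ClassifierSpec(name="rf"), x, y, x)
        assert (pred == y).mean() >= 0.99

    def test_constant_features_predict_majority(self):
        x = np.ones((30, 3))
        y = np.array([1] * 20 + [0] * 10)
        pred = fit_predict("lr", x, y, np.ones((5, 3)))
        assert (pred == 1).all()

    def test_single_class_training_warns_and_is_constant(self):
        x = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.warns(UserWarning, match="single-class"):
            pred = fit_predict("svm", x, np.zeros(10, dtype=int), x)
        assert (pred == 0).all()

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_predict("lr", np.zeros((3, 2)), np.array([0, 1, 2]), np.zeros((1, 2)))

    @pytest.mark.parametrize("name", ["lr", "knn", "rf", "dt", "svm"])
    def test_all_five_run_and_label_every_row(self, name, rng):
        x = rng.normal(size=(60, 4))
        y = (x[:, 1] > 0).astype(int)
        pred = fit_predict(name, x, y, rng.normal(size=(9, 4)))
        assert pred.shape == (9,) and set(pred) <= {0, 1}


class TestConfusion:
    def test_hand_example(self):
        assert confusion([1, 1, 0, 0], [1, 0, 0, 1]) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        tp, fp, fn, tn = confusion([1, 0, 1], [1, 0, 1])
        assert fp == 0 and fn == 0

    def test_matches_brute_force_on_random_pairs(self, rng):
        y_true = rng.integers(0, 2, size=1000)
        y_pred = rng.integers(0, 2, size=1000)
        tp, fp, fn, tn = confusion(y_true, y_pred)
        btp = bfp = bfn = btn = 0
        for t, p in zip(y_true, y_pred):
            if t == 1 and p == 1:
                btp += 1
            elif t == 0 and p == 1:
                bfp += 1
            elif t == 1 and p == 0:
                bfn += 1
            else:
                btn += 1
        assert (tp, fp, fn, tn) == (btp, bfp, bfn, btn)
        assert tp + fp + fn + tn == 1000

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1, 0], [1])

    def test_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_balanced_example(self):
        rep = metrics(1, 1, 1, 1)
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (0.5, 0.5, 0.5, 0.5)

    def test_direct_formula_evaluation(self):
        rep = metrics(tp=2, fp=1, fn=2, tn=5)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(0.5)
        assert rep.f1 == pytest.approx(4 / 7)

    def test_no_positive_predictions_convention(self):
        rep = metrics(tp=0, fp=0, fn=3, tn=7)
        assert math.isnan(rep.precision)
        # the 2TP form stays defined as long as 2TP+FP+FN > 0
        assert rep.f1 == 0.0

    def test_all_zero_counts(self):
        with pytest.raises(ValueError, match="zero"):
            metrics(0, 0, 0, 0)

    def test_negative_count(self):
        with pytest.raises(ValueError):
            metrics(-1, 0, 0, 1)

    def test_self_evaluation_is_perfect(self, rng):
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1  # both classes present
        rep = evaluate(y, y)
        assert rep.accuracy == 1.0 and rep.recall == 1.0

    @given(
        tp=st.integers(0, 200), fp=st.integers(0, 200),
        fn=st.integers(0, 200), tn=st.integers(0, 200),
    )
    def test_both_f1_forms_agree(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        rep = metrics(tp, fp, fn, tn)
        if not (math.isnan(rep.precision) or math.isnan(rep.recall)) and rep.precision + rep.recall > 0:
            harmonic = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            assert rep.f1 == pytest.approx(harmonic)

    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_accuracy_label_symmetry(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        assert metrics(tp, fp, fn, tn).accuracy == metrics(tn, fn, fp, tp).accuracy
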