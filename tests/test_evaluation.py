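"""Confusion-matrix metrics, generalized MCC and the K-fold driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

from fogsense.evaluation import (
    ConfusionMatrix,
    confusion,
    gorodkin_mcc,
    multiclass_metrics,
    run_cv,
    stratified_kfold,
)


class TestConfusion:
    def test_diagonal_pattern(self):
        cm = confusion([0, 1, 2], [0, 1, 2], K=3)
        np.testing.assert_array_equal(cm.C, np.eye(3, dtype=int))

    def test_off_diagonal_counts(self):
        cm = confusion([0, 0], [1, 1], K=3)
        assert cm.C[0, 1] == 2 and cm.C.sum() == 2

    def test_empty_inputs(self):
        cm = confusion([], [], K=3)
        assert cm.s == 0

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion([0, 3], [0, 0], K=3)

    def test_marginals(self):
        cm = ConfusionMatrix(np.array([[5, 1], [2, 4]]))
        assert cm.t.tolist() == [6, 6]
        assert cm.p.tolist() == [7, 5]
        assert cm.c == 9 and cm.s == 12


class TestMulticlassMetrics:
    def test_perfect_prediction_all_ones(self):
        rep = multiclass_metrics(ConfusionMatrix(np.diag([40, 30, 30])))
        assert rep.accuracy == 1.0
        for arr in (rep.precision, rep.recall, rep.specificity, rep.fbeta):
            np.testing.assert_allclose(arr, 1.0)
        assert rep.weighted_fbeta == 1.0

    def test_binary_collapse_case(self):
        rep = multiclass_metrics(ConfusionMatrix(np.array([[2, 0], [2, 0]])))
        assert rep.recall[0] == 1.0 and rep.recall[1] == 0.0
        assert rep.accuracy == 0.5
        assert rep.flags  # never-predicted class 1 flagged

    def test_weighted_recall_equals_accuracy(self, rng):
        for _ in range(50):
            C = rng.integers(0, 20, size=(3, 3))
            if C.sum() == 0:
                continue
            rep = multiclass_metrics(ConfusionMatrix(C))
            assert rep.weighted_recall == pytest.approx(rep.accuracy)

    def test_rates_within_unit_interval(self, rng):
        for _ in range(50):
            C = rng.integers(0, 30, size=(4, 4))
            if C.sum() == 0:
                continue
            rep = multiclass_metrics(ConfusionMatrix(C), beta=2.0)
            for arr in (rep.precision, rep.recall, rep.specificity, rep.fbeta):
                assert np.all((arr >= 0) & (arr <= 1))

    def test_relabeling_invariance(self, rng):
        y_true = rng.integers(0, 3, 60)
        y_pred = rng.integers(0, 3, 60)
        perm = np.array([2, 0, 1])
        a = multiclass_metrics(confusion(y_true, y_pred, 3))
        b = multiclass_metrics(confusion(perm[y_true], perm[y_pred], 3))
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.weighted_fbeta == pytest.approx(b.weighted_fbeta)
        assert a.mcc == pytest.approx(b.mcc)


class TestGorodkinMCC:
    def test_perfect_prediction_is_one(self):
        assert gorodkin_mcc(ConfusionMatrix(np.diag([40, 30, 30]))) == pytest.approx(1.0)

    def test_uniform_matrix_is_zero(self):
        assert gorodkin_mcc(ConfusionMatrix(np.full((3, 3), 10))) == pytest.approx(0.0)

    def test_cyclic_permutation_is_minus_half(self):
        C = 25 * np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        assert gorodkin_mcc(ConfusionMatrix(C)) == pytest.approx(-0.5)

    def test_degenerate_marginals_return_zero(self):
        C = np.zeros((3, 3), dtype=int)
        C[1, :] = [3, 4, 5]  # single true class
        assert gorodkin_mcc(ConfusionMatrix(C)) == 0.0

    @given(st.lists(st.integers(0, 50), min_size=4, max_size=4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_binary_case_matches_classical_mcc(self, cells):
        C = np.array(cells).reshape(2, 2)
        if C.sum() == 0:
            return
        y_true = np.repeat([0, 0, 1, 1], C.ravel())
        y_pred = np.repeat([0, 1, 0, 1], C.ravel())
        expected = matthews_corrcoef(y_true, y_pred) if len(np.unique(y_true)) > 1 else 0.0
        got = gorodkin_mcc(ConfusionMatrix(C))
        if len(np.unique(y_true)) > 1 and len(np.unique(y_pred)) > 1:
            assert got == pytest.approx(expected, abs=1e-12)
        else:
            assert got == 0.0

    def test_bounded_on_random_matrices(self, rng):
        for _ in range(10_000):
            C = rng.integers(0, 100, size=(3, 3))
            if C.sum() == 0:
                continue
            v = gorodkin_mcc(ConfusionMatrix(C))
            assert -1.0 - 1e-12 <= v <= 1.0 + 1e-12


class TestStratifiedKFold:
    def test_partition_property(self, rng):
        y = rng.integers(0, 3, 90)
        folds = stratified_kfold(y, K=5, seed=0)
        test_sets = [set(te) for _, te in folds]
        assert set().union(*test_sets) == set(range(90))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not test_sets[i] & test_sets[j]

    def test_per_fold_class_proportions(self):
        y = np.repeat([0, 1, 2], [50, 25, 25])
        for _, te in stratified_kfold(y, K=5, seed=1):
            counts = np.bincount(y[te], minlength=3)
            np.testing.assert_allclose(counts, [10, 5, 5], atol=1)

    def test_fold_sizes(self, rng):
        y = rng.integers(0, 3, 100)
        sizes = [len(te) for _, te in stratified_kfold(y, K=5, seed=2)]
        assert all(abs(s - 20) <= 2 for s in sizes)

    def test_class_smaller_than_k_rejected(self):
        y = np.array([0] * 20 + [1] * 3)
        with pytest.raises(ValueError, match="needs"):
            stratified_kfold(y, K=5)


class TestRunCV:
    def test_nearest_centroid_beats_chance_and_is_deterministic(self, rng):
        X = np.vstack([rng.normal(c * 4, 0.5, size=(30, 3)) for c in range(3)])
        y = np.repeat([0, 1, 2], 30)

        def fit_predict(Xtr, ytr, Xte, seed):
            centroids = np.stack([Xtr[ytr == c].mean(axis=0) for c in range(3)])
            d = np.linalg.norm(Xte[:, None] - centroids[None], axis=2)
            return d.argmin(axis=1)

        res1 = run_cv(X, y, fit_predict, K=5, seed=0)
        res2 = run_cv(X, y, fit_predict, K=5, seed=0)
        assert len(res1.folds) == 5
        agg = res1.aggregate()
        assert agg["accuracy"][0] > 1 / 3
        assert agg == res2.aggregate()
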