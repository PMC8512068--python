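"""Ensemble combination: voting, averaging and the stacked head."""

import itertools

import numpy as np
import pytest

from fogsense.ensembles import (
    EnsembleSpec,
    average_predict,
    majority_predict,
    majority_vote,
    stacked_predict,
    train_stacked_head,
)
from fogsense.models import TrainConfig, build_bilstm, predict_proba, reduced_lstm_spec, train


def _mode_with_lowest_tie(row):
    counts = np.bincount(row, minlength=3)
    return int(np.flatnonzero(counts == counts.max())[0])


@pytest.fixture(scope="module")
def trained_pair():
    """Two tiny constituents trained on the same separable data."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(loc, 0.3, size=(30, 4)) for loc in (-3, 0, 3)])
    y = np.repeat([0, 1, 2], 30)
    out = []
    for seed in (0, 1):
        net = build_bilstm(4, reduced_lstm_spec(hidden=4, n_layers=1), seed=seed)
        out.append(train(net, X, y, TrainConfig(max_epochs=80, patience=79, seed=seed)))
    return out, X, y


class TestMajorityVote:
    def test_simple_mode(self):
        assert majority_vote(np.array([[0, 0, 1, 2, 0, 1]]))[0] == 0

    def test_unanimous(self):
        assert majority_vote(np.array([[2, 2, 2]]))[0] == 2

    def test_exhaustive_against_mode_counting(self):
        """All vote matrices with m <= 4 voters over 3 classes match a
        per-row mode count (lowest-index tie rule without probabilities)."""
        for m in range(1, 5):
            votes = np.array(list(itertools.product([0, 1, 2], repeat=m)))
            got = majority_vote(votes)
            expected = [_mode_with_lowest_tie(row) for row in votes]
            assert got.tolist() == expected

    def test_six_voter_spot_checks(self, rng):
        votes = rng.integers(0, 3, size=(200, 6))
        got = majority_vote(votes)
        expected = [_mode_with_lowest_tie(row) for row in votes]
        assert got.tolist() == expected

    def test_tie_broken_by_summed_probability(self):
        votes = np.array([[0, 0, 0, 1, 1, 1]])
        probas = np.zeros((1, 6, 3))
        probas[0, :3, 0] = [0.6, 0.6, 0.6]   # class-0 voters, lukewarm
        probas[0, 3:, 1] = [0.99, 0.99, 0.99]  # class-1 voters, confident
        assert majority_vote(votes, probas)[0] == 1

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(np.empty((2, 0), dtype=int))


class TestAveragePredict:
    def test_mean_of_one_hot_outputs(self, trained_pair):
        models, X, y = trained_pair
        spec = EnsembleSpec(models, ["a", "b"], mode="average")
        inputs = {"a": X[:5], "b": X[:5]}
        expected = (predict_proba(models[0], X[:5]) + predict_proba(models[1], X[:5])) / 2
        np.testing.assert_allclose(average_predict(spec, inputs), expected)

    def test_rows_sum_to_one(self, trained_pair):
        models, X, _ = trained_pair
        spec = EnsembleSpec(models, ["a", "b"], mode="average")
        P = average_predict(spec, {"a": X, "b": X})
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_permutation_invariance(self, trained_pair):
        models, X, _ = trained_pair
        fwd = EnsembleSpec(models, ["a", "b"], mode="average")
        rev = EnsembleSpec(models[::-1], ["b", "a"], mode="average")
        np.testing.assert_allclose(
            average_predict(fwd, {"a": X, "b": X}),
            average_predict(rev, {"a": X, "b": X}),
        )


class TestStacked:
    def test_untrained_head_rejected(self, trained_pair):
        models, X, _ = trained_pair
        spec = EnsembleSpec(models, ["a", "b"], mode="stacked")
        with pytest.raises(RuntimeError, match="untrained"):
            stacked_predict(spec, {"a": X, "b": X})

    def test_head_input_width_is_constituents_times_classes(self, trained_pair):
        models, X, y = trained_pair
        spec = EnsembleSpec(models, ["a", "b"], mode="stacked")
        train_stacked_head(spec, {"a": X, "b": X}, y,
                           TrainConfig(max_epochs=10, patience=9, seed=0))
        assert spec.head.layers[0].W.value.shape == (2 * 3, 10)
        P = stacked_predict(spec, {"a": X, "b": X})
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_consistent_constituents_carry_through(self, trained_pair):
        """When both constituents agree, all three schemes agree with them."""
        models, X, y = trained_pair
        spec = EnsembleSpec(models, ["a", "b"], mode="stacked")
        train_stacked_head(spec, {"a": X, "b": X}, y,
                           TrainConfig(max_epochs=100, patience=99, seed=0))
        inputs = {"a": X, "b": X}
        p0 = predict_proba(models[0], X).argmax(1)
        p1 = predict_proba(models[1], X).argmax(1)
        agree = p0 == p1
        assert agree.mean() > 0.8
        maj = majority_predict(EnsembleSpec(models, ["a", "b"], mode="majority"), inputs)
        avg = average_predict(EnsembleSpec(models, ["a", "b"], mode="average"), inputs).argmax(1)
        stk = stacked_predict(spec, inputs).argmax(1)
        assert np.array_equal(maj[agree], p0[agree])
        assert np.array_equal(avg[agree], p0[agree])
        assert (stk[agree] == p0[agree]).mean() > 0.9  # statistical, head-dependent

    def test_misaligned_batches_rejected(self, trained_pair):
        models, X, _ = trained_pair
        spec = EnsembleSpec(models, ["a", "b"], mode="average")
        with pytest.raises(ValueError, match="misaligned"):
            average_predict(spec, {"a": X[:5], "b": X[:4]})


class TestEnsembleSpec:
    def test_single_constituent_rejected(self, trained_pair):
        models, _, _ = trained_pair
        with pytest.raises(ValueError, match="at least 2"):
            EnsembleSpec(models[:1], ["a"], mode="majority")

    def test_unknown_mode_rejected(self, trained_pair):
        models, _, _ = trained_pair
        with pytest.raises(ValueError, match="mode"):
            EnsembleSpec(models, ["a", "b"], mode="blend")
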