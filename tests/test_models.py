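"""Model builders, training loop and prediction contracts."""

import numpy as np
import pytest

from fogsense import _nn
from fogsense.models import (
    CNNSpec,
    LSTMSpec,
    TrainConfig,
    build_bilstm,
    build_cnn,
    predict_proba,
    reduced_lstm_spec,
    train,
)


def _separable_blobs(rng, n_per_class=60, d=10):
    """Three linearly separable point clouds."""
    X = np.vstack([
        rng.normal(loc, 0.3, size=(n_per_class, d))
        for loc in (-3.0, 0.0, 3.0)
    ])
    y = np.repeat([0, 1, 2], n_per_class)
    return X, y


class TestBuildCNN:
    def test_full_topology_layer_sequence(self):
        net = build_cnn((3, 128, 128))
        kinds = [type(l).__name__ for l in net.layers]
        assert kinds == (
            ["Conv2D", "LeakyReLU", "MaxPool2", "Dropout"] * 4
            + ["Flatten"]
            + ["Dense", "LeakyReLU", "Dropout"] * 2
            + ["Dense"]
        )
        # four poolings: 128 -> 8 spatial, 8 channels -> flatten 512 -> 100 -> 50 -> 3
        dense = [l for l in net.layers if isinstance(l, _nn.Dense)]
        assert dense[0].W.value.shape == (8 * 8 * 8, 100)
        assert dense[1].W.value.shape == (100, 50)
        assert dense[2].W.value.shape == (50, 3)

    def test_too_small_input_names_failing_stage(self):
        with pytest.raises(ValueError, match="conv block 4"):
            build_cnn((3, 8, 8))

    def test_parameter_count_deterministic_golden(self):
        """Parameter count is a pure function of input shape and spec."""
        full = build_cnn((3, 128, 128))
        reduced = build_cnn((3, 32, 32), CNNSpec(conv_filters=(16, 8, 4, 2)))

        def conv_params(cin, cout, k=4):
            return cin * k * k * cout + cout

        expected_full = (
            conv_params(3, 64) + conv_params(64, 32) + conv_params(32, 16)
            + conv_params(16, 8)
            + (8 * 8 * 8) * 100 + 100 + 100 * 50 + 50 + 50 * 3 + 3
        )
        expected_reduced = (
            conv_params(3, 16) + conv_params(16, 8) + conv_params(8, 4)
            + conv_params(4, 2)
            + (2 * 2 * 2) * 100 + 100 + 100 * 50 + 50 + 50 * 3 + 3
        )
        assert full.param_count() == expected_full
        assert reduced.param_count() == expected_reduced

    def test_same_seed_same_init(self):
        a = build_cnn((3, 32, 32), CNNSpec(conv_filters=(4, 2, 2, 2)), seed=5)
        b = build_cnn((3, 32, 32), CNNSpec(conv_filters=(4, 2, 2, 2)), seed=5)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)


class TestBuildBiLSTM:
    @pytest.mark.parametrize("linput,hidden", [(128, 384), (27, 81), (1, 3)])
    def test_width_rule_hidden_equals_three_linput(self, linput, hidden):
        net = build_bilstm(linput)
        lstm_layers = [l for l in net.layers if isinstance(l, _nn.BiLSTM)]
        assert len(lstm_layers) == 4
        assert all(l.hidden == hidden for l in lstm_layers)

    def test_sequence_returns_between_stacked_layers(self):
        net = build_bilstm(8, LSTMSpec(n_layers=3, hidden_units=4))
        lstm_layers = [l for l in net.layers if isinstance(l, _nn.BiLSTM)]
        assert [l.return_sequences for l in lstm_layers] == [True, True, False]

    def test_softmax_head_width_three(self):
        net = build_bilstm(8, reduced_lstm_spec(hidden=4))
        assert net.layers[-1].W.value.shape[1] == 3

    def test_bad_linput_rejected(self):
        with pytest.raises(ValueError):
            build_bilstm(0)


class TestTrain:
    def test_learns_separable_data_above_chance(self, rng):
        X, y = _separable_blobs(rng)
        net = build_bilstm(10, reduced_lstm_spec(hidden=6, n_layers=1), seed=0)
        model = train(net, X, y, TrainConfig(max_epochs=15, patience=14, seed=0))
        assert model.history["train_acc"][-1] > 1 / 3
        assert model.history["train_loss"][0] > model.history["train_loss"][-1]

    def test_early_stopping_on_flat_validation(self, rng):
        """With constant validation accuracy, training stops after patience."""
        X, y = _separable_blobs(rng, n_per_class=20, d=4)
        spec = LSTMSpec(n_layers=1, hidden_units=2, learning_rate=0.0)  # frozen
        net = build_bilstm(4, spec, seed=0)
        model = train(net, X, y, TrainConfig(max_epochs=100, patience=5, seed=0))
        assert len(model.history["val_acc"]) == 6  # epoch 0 improves, then 5 stalls

    def test_returns_best_validation_epoch_weights(self, rng):
        X, y = _separable_blobs(rng, n_per_class=30, d=6)
        net = build_bilstm(6, reduced_lstm_spec(hidden=4, n_layers=1), seed=1)
        model = train(net, X, y, TrainConfig(max_epochs=10, patience=9, seed=1))
        best = model.history["best_val_acc"]
        assert best == max(model.history["val_acc"])

    def test_seeded_determinism(self, rng):
        X, y = _separable_blobs(rng, n_per_class=20, d=4)
        hists = []
        for _ in range(2):
            net = build_bilstm(4, reduced_lstm_spec(hidden=3, n_layers=1), seed=3)
            m = train(net, X, y, TrainConfig(max_epochs=5, patience=4, seed=3))
            hists.append(m.history["train_loss"])
        assert hists[0] == hists[1]

    def test_missing_class_rejected(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.repeat([0, 1], 20)  # class 2 absent
        net = build_bilstm(4, reduced_lstm_spec(hidden=2, n_layers=1), seed=0)
        with pytest.raises(ValueError, match="missing"):
            train(net, X, y, TrainConfig(max_epochs=5, patience=4, seed=0))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    X, y = _separable_blobs(rng, n_per_class=20, d=4)
    net = build_bilstm(4, reduced_lstm_spec(hidden=3, n_layers=1), seed=0)
    return train(net, X, y, TrainConfig(max_epochs=5, patience=4, seed=0))


class TestPredictProba:
    def test_rows_sum_to_one(self, fitted, rng):
        P = predict_proba(fitted, rng.normal(size=(7, 4)))
        assert P.shape == (7, 3)
        assert np.all(P >= 0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_batch(self, fitted):
        assert predict_proba(fitted, np.empty((0, 4))).shape == (0, 3)

    def test_shape_mismatch_rejected(self, fitted, rng):
        with pytest.raises(ValueError, match="shape"):
            predict_proba(fitted, rng.normal(size=(3, 7)))
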