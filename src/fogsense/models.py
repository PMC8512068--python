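"""CNN and bidirectional-LSTM classifiers for FOG window classification.

Two architectures cover the six data modalities:

* A convolutional network for the four time-frequency image encodings
  (recurrence plot, STFT spectrogram, Haar DWT rendering, pseudo
  Wigner-Ville): four conv blocks with filter counts 64/32/16/8, 4×4
  kernels, leaky-rectifier activations (slope 0.3), 2×2 max pooling and
  dropout 0.25, then dense layers of 100 and 50 units (dropout 0.2) and a
  3-way softmax.  Optimized with RMSProp at learning rate 1e-4.
* A stack of four bidirectional LSTM layers with tanh cell activations for
  the raw magnitude window and for the 27-feature vector read as a
  sequence.  The hidden width per direction is ``linput * sigma`` with
  sigma = 3; the last recurrent layer emits its two final states into a
  3-way softmax.  Optimized with Adam at learning rate 1e-4.

Training runs up to 500 epochs with early stopping after 50 epochs without
a strict validation-accuracy improvement (20% of the training partition is
held out for validation) and returns the best-validation-epoch weights.

A reduced-scale profile — 32×32 images, filter counts [16, 8, 4, 2], two
recurrent layers of hidden width 24, at most 30 epochs and learning rate
1e-3 — supports CPU-scale experiments; it is always selected explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from . import _nn

__all__ = [
    "CNNSpec",
    "LSTMSpec",
    "TrainConfig",
    "TrainedModel",
    "REDUCED_CNN",
    "reduced_lstm_spec",
    "build_cnn",
    "build_bilstm",
    "train",
    "predict_proba",
]


@dataclass(frozen=True)
class CNNSpec:
    """Topology and optimizer of the convolutional classifier."""

    conv_filters: tuple[int, ...] = (64, 32, 16, 8)
    kernel: int = 4
    leaky_alpha: float = 0.3
    pool: int = 2
    conv_dropout: float = 0.25
    dense_units: tuple[int, ...] = (100, 50)
    dense_dropout: float = 0.2
    n_classes: int = 3
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-4


@dataclass(frozen=True)
class LSTMSpec:
    """Topology and optimizer of the bidirectional LSTM classifier.

    ``hidden_units`` of None means the width rule hidden = linput * sigma.
    """

    n_layers: int = 4
    sigma: int = 3
    hidden_units: int | None = None
    n_classes: int = 3
    optimizer: str = "adam"
    learning_rate: float = 1e-4


#: Reduced-scale CNN profile for CPU experiments (pair with 32×32 images and
#: small batches: the short epoch budget is offset by more, larger steps).
REDUCED_CNN = CNNSpec(conv_filters=(16, 8, 4, 2), learning_rate=3e-3)


def reduced_lstm_spec(hidden: int = 24, n_layers: int = 2) -> LSTMSpec:
    """Reduced-scale BiLSTM profile for CPU experiments."""
    return LSTMSpec(n_layers=n_layers, hidden_units=hidden, learning_rate=1e-3)


@dataclass
class TrainConfig:
    """Training protocol: epoch budget, early stopping and batching."""

    max_epochs: int = 500
    patience: int = 50
    val_fraction: float = 0.2
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class TrainedModel:
    """A fitted network plus its spec, class order and training history."""

    spec: CNNSpec | LSTMSpec
    network: _nn.Sequential
    class_order: tuple[int, ...] = (0, 1, 2)
    history: dict = field(default_factory=dict)
    input_kind: str = "image"  # "image" or "sequence"


def build_cnn(input_shape: tuple[int, int, int], spec: CNNSpec = CNNSpec(),
              seed: int = 0) -> _nn.Sequential:
    """Build the untrained convolutional network for (C, H, W) inputs.

    Four conv/pool blocks halve the spatial extent each time, so H and W
    must survive four 2×2 poolings; inputs smaller than 16×16 are rejected
    with the failing stage named.
    """
    c, h, w = input_shape
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    ch = c
    hh, ww = h, w
    for i, f in enumerate(spec.conv_filters):
        if hh < spec.pool or ww < spec.pool or hh % spec.pool or ww % spec.pool:
            raise ValueError(
                f"conv block {i + 1}: spatial extent {hh}x{ww} cannot be "
                f"{spec.pool}x{spec.pool}-pooled (input {h}x{w} too small or not "
                f"divisible)"
            )
        layers += [
            _nn.Conv2D(ch, f, spec.kernel, rng),
            _nn.LeakyReLU(spec.leaky_alpha),
            _nn.MaxPool2(),
            _nn.Dropout(spec.conv_dropout),
        ]
        ch = f
        hh //= spec.pool
        ww //= spec.pool
    layers.append(_nn.Flatten())
    n_in = ch * hh * ww
    for units in spec.dense_units:
        layers += [
            _nn.Dense(n_in, units, rng),
            _nn.LeakyReLU(spec.leaky_alpha),
            _nn.Dropout(spec.dense_dropout),
        ]
        n_in = units
    layers.append(_nn.Dense(n_in, spec.n_classes, rng))
    net = _nn.Sequential(layers)
    net.meta = {"spec": spec, "input_kind": "image", "input_shape": input_shape}
    return net


def build_bilstm(linput: int, spec: LSTMSpec = LSTMSpec(), n_features: int = 1,
                 seed: int = 0) -> _nn.Sequential:
    """Build the untrained stacked bidirectional LSTM for length-``linput``
    sequences of ``n_features`` values per step.

    Hidden width per direction is ``spec.hidden_units`` or, by the width
    rule, ``linput * spec.sigma``.  All recurrent layers but the last return
    full sequences; the last returns its concatenated final states.
    """
    if linput < 1:
        raise ValueError("linput must be >= 1")
    hidden = spec.hidden_units if spec.hidden_units is not None else linput * spec.sigma
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    n_in = n_features
    for i in range(spec.n_layers):
        last = i == spec.n_layers - 1
        layers.append(_nn.BiLSTM(n_in, hidden, rng, return_sequences=not last))
        n_in = 2 * hidden
    layers.append(_nn.Dense(n_in, spec.n_classes, rng))
    net = _nn.Sequential(layers)
    net.meta = {"spec": spec, "input_kind": "sequence", "hidden": hidden,
                "input_shape": (linput, n_features)}
    return net


def _as_network_input(X: np.ndarray, kind: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if kind == "sequence" and X.ndim == 2:
        X = X[:, :, None]
    return X


def _accuracy(net: _nn.Sequential, X: np.ndarray, y: np.ndarray) -> float:
    pred = net.forward(X, train=False).argmax(axis=1)
    return float(np.mean(pred == y))


def train(network: _nn.Sequential, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig = TrainConfig()) -> TrainedModel:
    """Fit a network with minibatch gradient descent and early stopping.

    The data are split into train/validation partitions (stratified,
    ``cfg.val_fraction`` held out).  Training stops at ``cfg.max_epochs`` or
    after ``cfg.patience`` consecutive epochs without strict improvement of
    validation accuracy; the returned model carries the weights of the best
    validation epoch and the full per-epoch history.

    Raises
    ------
    ValueError
        If any class is absent from the training partition.
    """
    meta = getattr(network, "meta", {"spec": None, "input_kind": "image"})
    kind = meta["input_kind"]
    spec = meta["spec"]
    X = _as_network_input(X, kind)
    y = np.asarray(y, dtype=np.int64)
    n_classes = spec.n_classes if spec is not None else int(y.max()) + 1

    idx_train, idx_val = train_test_split(
        np.arange(len(y)), test_size=cfg.val_fraction, stratify=y,
        random_state=cfg.seed % (2 ** 32),
    )
    Xtr, ytr = X[idx_train], y[idx_train]
    Xva, yva = X[idx_val], y[idx_val]
    present = set(np.unique(ytr))
    if set(range(n_classes)) - present:
        raise ValueError(f"classes missing from training partition: "
                         f"{sorted(set(range(n_classes)) - present)}")

    rng = np.random.default_rng(cfg.seed)
    opt = _nn.make_optimizer(
        spec.optimizer if spec is not None else "adam",
        network.params(),
        spec.learning_rate if spec is not None else 1e-3,
    )
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_acc = -np.inf
    best_weights = network.get_weights()
    best_epoch = -1
    stall = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(ytr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            network.zero_grad()
            logits = network.forward(Xtr[batch], train=True, rng=rng)
            loss, grad = _nn.softmax_cross_entropy(logits, ytr[batch])
            network.backward(grad)
            opt.step()
            losses.append(loss)
        val_logits = network.forward(Xva, train=False)
        val_loss, _ = _nn.softmax_cross_entropy(val_logits, yva)
        val_acc = float(np.mean(val_logits.argmax(axis=1) == yva))
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(_accuracy(network, Xtr, ytr))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = network.get_weights()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    network.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_acc"] = best_acc
    return TrainedModel(spec=spec, network=network,
                        class_order=tuple(range(n_classes)),
                        history=history, input_kind=kind)


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Class-probability matrix (n, n_classes); rows sum to 1.

    An empty batch yields an empty (0, n_classes) matrix.
    """
    X = _as_network_input(X, model.input_kind)
    n_classes = len(model.class_order)
    if len(X) == 0:
        return np.empty((0, n_classes))
    expected = getattr(model.network, "meta", {}).get("input_shape")
    if expected is not None and tuple(X.shape[1:]) != tuple(expected):
        raise ValueError(f"input shape {X.shape[1:]} != expected {tuple(expected)}")
    return _nn.softmax(model.network.forward(X, train=False))
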