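"""Combination of the six constituent classifiers into ensemble predictors.

Three schemes combine the per-modality models (four image CNNs plus the
raw-signal and feature BiLSTMs):

* **stacked** — the constituents' softmax outputs are concatenated
  (6 × 3 = 18 values) and fed to a small trainable head (dense 10 with a
  rectifier, dense 3 with softmax); constituent weights stay frozen.
* **average** — the elementwise arithmetic mean of the constituent
  probability rows; nothing to train.
* **majority** — hard voting on the constituents' argmax labels; ties break
  to the tied class with the largest summed constituent probability,
  falling back to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from .models import TrainConfig, TrainedModel, predict_proba

__all__ = [
    "EnsembleSpec",
    "constituent_probas",
    "train_stacked_head",
    "stacked_predict",
    "average_predict",
    "majority_vote",
    "majority_predict",
]


@dataclass
class EnsembleSpec:
    """Constituents, their input modalities, and the combination mode."""

    constituents: list[TrainedModel]
    modalities: list[str]
    mode: str = "majority"  # "stacked" | "average" | "majority"
    head: _nn.Sequential | None = None
    head_units: int = 10
    learning_rate: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.constituents) < 2:
            raise ValueError("an ensemble needs at least 2 constituents")
        if len(self.constituents) != len(self.modalities):
            raise ValueError("one modality per constituent required")
        orders = {m.class_order for m in self.constituents}
        if len(orders) != 1:
            raise ValueError("constituents disagree on class order")
        if self.mode not in ("stacked", "average", "majority"):
            raise ValueError(f"unknown ensemble mode {self.mode!r}")

    @property
    def n_classes(self) -> int:
        return len(self.constituents[0].class_order)


def constituent_probas(spec: EnsembleSpec, inputs: dict[str, np.ndarray]) -> list[np.ndarray]:
    """Per-constituent probability matrices for aligned multimodal inputs."""
    probas = []
    n = None
    for model, modality in zip(spec.constituents, spec.modalities):
        if modality not in inputs:
            raise KeyError(f"missing input for modality {modality!r}")
        p = predict_proba(model, inputs[modality])
        if n is None:
            n = len(p)
        elif len(p) != n:
            raise ValueError("modality batches are misaligned")
        probas.append(p)
    return probas


def train_stacked_head(spec: EnsembleSpec, inputs: dict[str, np.ndarray],
                       y: np.ndarray, cfg: TrainConfig | None = None) -> EnsembleSpec:
    """Fit the stacked ensemble's dense head on frozen constituent outputs."""
    if spec.mode != "stacked":
        raise ValueError("head training applies to the stacked mode only")
    probas = constituent_probas(spec, inputs)
    Z = np.hstack(probas)
    y = np.asarray(y, dtype=np.int64)
    cfg = cfg or TrainConfig(max_epochs=200, patience=30)
    rng = np.random.default_rng(cfg.seed)
    k = spec.n_classes
    head = _nn.Sequential([
        _nn.Dense(Z.shape[1], spec.head_units, rng),
        _nn.ReLU(),
        _nn.Dense(spec.head_units, k, rng),
    ])
    opt = _nn.Adam(head.params(), lr=spec.learning_rate)
    for _ in range(cfg.max_epochs):
        order = rng.permutation(len(y))
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            head.zero_grad()
            loss, grad = _nn.softmax_cross_entropy(head.forward(Z[batch]), y[batch])
            head.backward(grad)
            opt.step()
    spec.head = head
    return spec


def stacked_predict(spec: EnsembleSpec, inputs: dict[str, np.ndarray]) -> np.ndarray:
    """Probabilities from the trained stacked head (concatenated 18-wide input).

    Raises
    ------
    RuntimeError
        If the head has not been trained.
    """
    if spec.head is None:
        raise RuntimeError("stacked head is untrained; call train_stacked_head first")
    Z = np.hstack(constituent_probas(spec, inputs))
    return _nn.softmax(spec.head.forward(Z))


def average_predict(spec: EnsembleSpec, inputs: dict[str, np.ndarray]) -> np.ndarray:
    """Elementwise mean of the constituent probability rows."""
    return np.mean(constituent_probas(spec, inputs), axis=0)


def majority_vote(votes: np.ndarray, probas: np.ndarray | None = None) -> np.ndarray:
    """Per-row modal label of an (n, m) vote matrix.

    Ties break to the tied class with the largest summed constituent
    probability when ``probas`` (n, m, K) is given, else to the lowest
    class index.
    """
    votes = np.asarray(votes, dtype=np.int64)
    if votes.ndim != 2 or votes.shape[1] < 1:
        raise ValueError("votes must be (n, m) with m >= 1 voters")
    n, m = votes.shape
    k = int(votes.max(initial=0)) + 1
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        counts = np.bincount(votes[i], minlength=k)
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if len(tied) == 1 or probas is None:
            out[i] = tied[0]
        else:
            sums = probas[i].sum(axis=0)  # summed probability per class
            out[i] = tied[np.argmax(sums[tied])]
    return out


def majority_predict(spec: EnsembleSpec, inputs: dict[str, np.ndarray]) -> np.ndarray:
    """Hard-voting labels over the constituents' argmax predictions."""
    probas = np.stack(constituent_probas(spec, inputs), axis=1)  # (n, m, K)
    votes = probas.argmax(axis=2)
    return majority_vote(votes, probas)
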