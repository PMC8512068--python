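"""SMOTE class balancing for windowed sensor data.

The window population is dominated by NonFOG: freezes are episodic and the
PreFOG transition contributes exactly one window per onset.  Rather than
duplicating minority rows or discarding majority rows, SMOTE (synthetic
minority oversampling) draws new minority samples uniformly along segments
joining a minority row to one of its k nearest same-class neighbors, so the
synthetic population fills the minority region of the representation space.

Balancing operates on flattened raw windows by default, so every downstream
modality (features, recurrence plot, spectrogram, wavelet, Wigner-Ville)
stays consistent per synthetic sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["LabeledMatrix", "smote_balance"]


@dataclass
class LabeledMatrix:
    """Rows of equal-width real vectors with integer class labels."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.X) != len(self.y):
            raise ValueError("X and y row counts differ")

    def __len__(self) -> int:
        return len(self.X)


def smote_balance(data: LabeledMatrix, k: int = 5, seed: int = 0) -> LabeledMatrix:
    """Oversample every minority class up to the majority-class count.

    Each synthetic row is x + u * (x' - x) with u ~ Uniform(0, 1), where x is
    a uniformly chosen minority row and x' one of its ``k`` nearest neighbors
    within the same class (k is clipped to class size - 1).  Original rows
    are preserved and come first in the output; synthesis is reproducible
    given ``seed``.

    Raises
    ------
    ValueError
        If a class that needs oversampling has fewer than 2 samples
        (no segment to interpolate on), or ``k < 1``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(data.y, return_counts=True)
    target = counts.max()
    new_X = [data.X]
    new_y = [data.y]
    for cls, count in zip(classes, counts):
        need = int(target - count)
        if need == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {cls} has {count} sample(s); SMOTE needs at least 2"
            )
        rows = data.X[data.y == cls]
        kk = min(k, count - 1)
        # +1 because each row's nearest neighbor is itself
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(rows)
        neigh = nn.kneighbors(rows, return_distance=False)[:, 1:]
        base = rng.integers(0, count, size=need)
        pick = rng.integers(0, kk, size=need)
        u = rng.random(need)
        x = rows[base]
        xp = rows[neigh[base, pick]]
        new_X.append(x + u[:, None] * (xp - x))
        new_y.append(np.full(need, cls, dtype=np.int64))
    return LabeledMatrix(np.vstack(new_X), np.concatenate(new_y))
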