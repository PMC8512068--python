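"""Multiclass evaluation metrics and the cross-validation driver.

Metrics are derived from the K×K confusion matrix C (rows true class,
columns predicted class): accuracy, one-vs-rest precision / recall /
specificity / Fβ per class with support-weighted averages, and the
generalized (multiclass) Matthews correlation coefficient

    R_K = (c·s − Σ_k p_k t_k) / sqrt((s² − Σ_k p_k²)(s² − Σ_k t_k²))

with t_k the occurrences of class k, p_k the predictions for class k, c the
trace and s the total count.  R_K is +1 for perfect prediction, 0 for
prediction independent of the truth, and negative for systematically wrong
prediction.

Model comparison uses stratified K-fold cross validation (K = 5 by
default): the data are shuffled, split into K class-proportion-preserving
folds, a fresh model is trained per fold and scored on its held-out fold,
and per-metric mean ± standard deviation across folds is reported.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "multiclass_metrics",
    "gorodkin_mcc",
    "stratified_kfold",
    "run_cv",
    "CVResult",
]


@dataclass
class ConfusionMatrix:
    """K×K confusion counts with the marginal totals of the R_K statistic."""

    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.int64)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.C < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def K(self) -> int:
        return self.C.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Occurrences of each class (row sums)."""
        return self.C.sum(axis=1)

    @property
    def p(self) -> np.ndarray:
        """Predictions for each class (column sums)."""
        return self.C.sum(axis=0)

    @property
    def c(self) -> int:
        """Correct predictions (trace)."""
        return int(np.trace(self.C))

    @property
    def s(self) -> int:
        """Total number of samples."""
        return int(self.C.sum())


@dataclass
class MetricsReport:
    """Accuracy, per-class and weighted rates, Fβ and generalized MCC."""

    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    fbeta: np.ndarray
    weighted_precision: float
    weighted_recall: float
    weighted_specificity: float
    weighted_fbeta: float
    mcc: float
    beta: float = 1.0
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.weighted_precision,
            "sensitivity": self.weighted_recall,
            "specificity": self.weighted_specificity,
            "fbeta": self.weighted_fbeta,
            "mcc": self.mcc,
        }


def confusion(y_true, y_pred, K: int) -> ConfusionMatrix:
    """Confusion matrix with C[i, j] = #(true i, predicted j)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= K):
            raise ValueError(f"{name} contains labels outside [0, {K})")
    if y_true.size == 0:
        return ConfusionMatrix(np.zeros((K, K), dtype=np.int64))
    return ConfusionMatrix(_sk_confusion(y_true, y_pred, labels=np.arange(K)))


def multiclass_metrics(cm: ConfusionMatrix, beta: float = 1.0) -> MetricsReport:
    """One-vs-rest rates per class with support-weighted averages.

    Per class k: precision = C_kk / p_k, recall = C_kk / t_k, specificity =
    TN_k / (s - t_k), Fβ the weighted harmonic precision/recall mean.
    Zero-denominator conventions (flagged in the report): a never-predicted
    class has precision 0; an absent class has recall 0.
    Weighted averages weight by class support t_k; accuracy is trace / total
    and equals the support-weighted recall.
    """
    if cm.s == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(cm.C).astype(float)
    t = cm.t.astype(float)
    p = cm.p.astype(float)
    s = float(cm.s)
    flags: list[str] = []

    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(p > 0, diag / np.where(p > 0, p, 1), 0.0)
        recall = np.where(t > 0, diag / np.where(t > 0, t, 1), 0.0)
        tn = s - t - p + diag
        specificity = np.where(s - t > 0, tn / np.where(s - t > 0, s - t, 1), 0.0)
        pr = precision * recall
        denom = beta ** 2 * precision + recall
        fbeta = np.where(denom > 0, (1 + beta ** 2) * pr / np.where(denom > 0, denom, 1), 0.0)
    if np.any(p == 0):
        flags.append(f"never-predicted classes {np.flatnonzero(p == 0).tolist()}: precision set to 0")
    if np.any(t == 0):
        flags.append(f"absent classes {np.flatnonzero(t == 0).tolist()}: recall set to 0")

    weights = t / s
    return MetricsReport(
        accuracy=cm.c / cm.s,
        precision=precision,
        recall=recall,
        specificity=specificity,
        fbeta=fbeta,
        weighted_precision=float(weights @ precision),
        weighted_recall=float(weights @ recall),
        weighted_specificity=float(weights @ specificity),
        weighted_fbeta=float(weights @ fbeta),
        mcc=gorodkin_mcc(cm),
        beta=beta,
        flags=flags,
    )


def gorodkin_mcc(cm: ConfusionMatrix) -> float:
    """Generalized multiclass Matthews correlation coefficient R_K.

    Returns 0 when either radicand vanishes (degenerate marginals: all mass
    in one true class or one predicted class).
    """
    t = cm.t.astype(float)
    p = cm.p.astype(float)
    s = float(cm.s)
    c = float(cm.c)
    cov = c * s - p @ t
    r1 = s * s - p @ p
    r2 = s * s - t @ t
    if r1 <= 0 or r2 <= 0:
        return 0.0
    return float(cov / np.sqrt(r1 * r2))


def stratified_kfold(y, K: int = 5, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified K-fold split of the index set.

    Test folds are disjoint, cover every index, and preserve the global
    class proportions within ±1 sample per class.

    Raises
    ------
    ValueError
        If any class has fewer than K samples.
    """
    y = np.asarray(y, dtype=np.int64)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < K:
        raise ValueError(f"smallest class has {counts.min()} samples; needs >= K={K}")
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed % (2 ** 32))
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


@dataclass
class CVResult:
    """Per-fold metric reports and their mean ± sd aggregation."""

    folds: list[MetricsReport]
    runtime_s: float

    def aggregate(self) -> dict[str, tuple[float, float]]:
        keys = self.folds[0].as_dict().keys()
        table = {k: np.array([f.as_dict()[k] for f in self.folds]) for k in keys}
        return {k: (float(v.mean()), float(v.std())) for k, v in table.items()}


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray],
    K: int = 5,
    seed: int = 0,
    beta: float = 1.0,
    n_classes: int = 3,
) -> CVResult:
    """Stratified K-fold evaluation of a model-building procedure.

    ``fit_predict(X_train, y_train, X_test, fold_seed)`` must train a fresh
    model on the training partition (applying any balancing there, never on
    the test partition) and return predicted labels for ``X_test``.  Models
    are discarded after scoring; only the metric reports are kept.
    """
    y = np.asarray(y, dtype=np.int64)
    reports = []
    t0 = time.perf_counter()
    for fold, (tr, te) in enumerate(stratified_kfold(y, K=K, seed=seed)):
        pred = fit_predict(X[tr], y[tr], X[te], seed + 1000 * (fold + 1))
        cm = confusion(y[te], pred, K=n_classes)
        reports.append(multiclass_metrics(cm, beta=beta))
    return CVResult(folds=reports, runtime_s=time.perf_counter() - t0)
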