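"""End-to-end experiment orchestration.

Composes the pipeline stages — recording (simulated or loaded), magnitude
fusion, windowing and PreFOG relabeling, per-fold SMOTE balancing, modality
extraction (raw window, 27-feature vector, four time-frequency images),
constituent training and the three ensembles — under stratified K-fold
cross validation, and aggregates per-model metric tables.

SMOTE operates on flattened raw windows inside each training partition, so
every modality derived afterwards stays consistent per synthetic sample and
no synthetic information leaks into the test fold.  A ``replication`` policy
that balances the full set before splitting is available for parity with
protocols that order balancing before the split.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import ensembles as _ens
from . import models as _models
from .augmentation import LabeledMatrix, smote_balance
from .evaluation import confusion, multiclass_metrics, stratified_kfold
from .features import feature_matrix
from .io import combine_magnitude, read_daphnet
from .segmentation import WindowSet, relabel_prefog, segment_recording
from .synthetic import SimulationConfig, make_balanced_windowset
from .tfr import RPConfig, encode_window

__all__ = ["RunConfig", "ModalityData", "build_modalities", "run_experiment"]

IMAGE_MODALITIES = ("RP", "STFT", "DWT", "PWVD")
SEQUENCE_MODALITIES = ("raw", "features")
ALL_MODALITIES = SEQUENCE_MODALITIES + IMAGE_MODALITIES


@dataclass
class RunConfig:
    """One experiment: input, window length, modalities, models, folds."""

    source: str = "simulate"               # "simulate" or a Daphnet file path
    sensor: str = "A"
    w: float = 2.0
    modalities: tuple[str, ...] = ("RP", "DWT", "features", "raw")
    ensemble_modes: tuple[str, ...] = ("majority",)
    K: int = 5
    profile: str = "reduced"               # "reduced" or "full"
    smote_policy: str = "per_fold"         # "per_fold" or "replication"
    smote_k: int = 5
    beta: float = 1.0
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("modality set must be non-empty")
        unknown = set(self.modalities) - set(ALL_MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        if self.w not in (1.0, 2.0, 3.0, 4.0) and not 1 <= self.w <= 4:
            raise ValueError("window length must lie in 1-4 s")
        if self.ensemble_modes and len(self.modalities) < 2:
            raise ValueError("ensembles need at least 2 constituent modalities")
        if self.profile not in ("reduced", "full"):
            raise ValueError("profile must be 'reduced' or 'full'")

    @property
    def image_size(self) -> tuple[int, int]:
        return (32, 32) if self.profile == "reduced" else (128, 128)


@dataclass
class ModalityData:
    """Aligned per-modality arrays for one set of windows."""

    arrays: dict[str, np.ndarray]

    def subset(self, idx: np.ndarray) -> "ModalityData":
        return ModalityData({k: v[idx] for k, v in self.arrays.items()})


def load_windows(cfg: RunConfig) -> WindowSet:
    """Produce the labeled window set from the configured source."""
    if cfg.source == "simulate":
        ws, _ = make_balanced_windowset(cfg.simulation, w=cfg.w, sensor=cfg.sensor)
        return ws
    rec = read_daphnet(cfg.source)
    mag = combine_magnitude(rec)
    return relabel_prefog(segment_recording(mag, w=cfg.w, sensor=cfg.sensor,
                                            recording_id=str(cfg.source)))


def build_modalities(
    windows: np.ndarray,
    fs: float,
    modalities: tuple[str, ...],
    image_size: tuple[int, int] = (128, 128),
    rp_config: RPConfig | None = None,
) -> ModalityData:
    """Derive every requested representation from a raw window matrix."""
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    arrays: dict[str, np.ndarray] = {}
    for name in modalities:
        if name == "raw":
            arrays[name] = windows
        elif name == "features":
            # the freeze index of a flat window is infinite by convention;
            # clamp for the network input
            f = feature_matrix(windows, fs)
            arrays[name] = np.nan_to_num(f, posinf=1e6, neginf=-1e6)
        elif name in IMAGE_MODALITIES:
            arrays[name] = np.stack([
                encode_window(row, fs, name, size=image_size, rp_config=rp_config).pixels
                for row in windows
            ])
        else:
            raise ValueError(f"unknown modality {name!r}")
    return ModalityData(arrays)


@dataclass
class _Constituent:
    name: str
    model: _models.TrainedModel
    center: np.ndarray
    scale: np.ndarray
    train_time_s: float


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    flat = X.reshape(len(X), -1)
    center = flat.mean(axis=0)
    scale = flat.std(axis=0)
    scale[scale == 0] = 1.0
    return center, scale


def _apply_scaler(X: np.ndarray, center, scale) -> np.ndarray:
    flat = X.reshape(len(X), -1)
    return ((flat - center) / scale).reshape(X.shape)


def _train_config(cfg: RunConfig, seed: int, image: bool) -> _models.TrainConfig:
    if cfg.profile == "reduced":
        # the short budget is the stopper; patience only guards degenerate
        # runs.  CNNs get small batches so 30 epochs provide enough steps.
        return _models.TrainConfig(max_epochs=30, patience=29, seed=seed,
                                   batch_size=8 if image else 32)
    return _models.TrainConfig(max_epochs=500, patience=50, seed=seed)


def fit_constituent(
    name: str, X: np.ndarray, y: np.ndarray, cfg: RunConfig, seed: int
) -> _Constituent:
    """Train one per-modality model (CNN for images, BiLSTM for sequences)."""
    t0 = time.perf_counter()
    center, scale = _fit_scaler(X)
    Xs = _apply_scaler(X, center, scale)
    image = name in IMAGE_MODALITIES
    if image:
        spec = _models.REDUCED_CNN if cfg.profile == "reduced" else _models.CNNSpec()
        net = _models.build_cnn(Xs.shape[1:], spec, seed=seed)
    else:
        spec = (_models.reduced_lstm_spec() if cfg.profile == "reduced"
                else _models.LSTMSpec())
        net = _models.build_bilstm(Xs.shape[1], spec, seed=seed)
    model = _models.train(net, Xs, y, _train_config(cfg, seed, image))
    return _Constituent(name, model, center, scale, time.perf_counter() - t0)


def _scaled_inputs(constituents: list[_Constituent], data: ModalityData) -> dict[str, np.ndarray]:
    return {
        c.name: _apply_scaler(data.arrays[c.name], c.center, c.scale)
        for c in constituents
    }


def run_experiment(cfg: RunConfig) -> dict:
    """Run the full cross-validated comparison and return the report.

    The report maps each model name (constituent modalities, then
    ``ensemble_<mode>``) to mean ± sd of accuracy, weighted precision /
    sensitivity / specificity / Fβ and generalized MCC across folds, plus
    the mean per-fold train+test runtime in seconds (modality extraction
    excluded).  Deterministic given ``cfg.seed``.
    """
    ws = load_windows(cfg)
    X_raw = ws.matrix()
    y = ws.labels
    fs = ws.fs

    if cfg.smote_policy == "replication":
        balanced = smote_balance(LabeledMatrix(X_raw, y), k=cfg.smote_k, seed=cfg.seed)
        X_raw, y = balanced.X, balanced.y

    folds = stratified_kfold(y, K=cfg.K, seed=cfg.seed)
    names = list(cfg.modalities) + [f"ensemble_{m}" for m in cfg.ensemble_modes]
    scores: dict[str, list] = {n: [] for n in names}
    runtimes: dict[str, list] = {n: [] for n in names}

    for fold, (tr, te) in enumerate(folds):
        fold_seed = cfg.seed + 1000 * (fold + 1)
        Xtr_raw, ytr = X_raw[tr], y[tr]
        if cfg.smote_policy == "per_fold":
            balanced = smote_balance(LabeledMatrix(Xtr_raw, ytr), k=cfg.smote_k,
                                     seed=fold_seed)
            Xtr_raw, ytr = balanced.X, balanced.y
        train_data = build_modalities(Xtr_raw, fs, cfg.modalities, cfg.image_size)
        test_data = build_modalities(X_raw[te], fs, cfg.modalities, cfg.image_size)

        constituents = []
        for name in cfg.modalities:
            con = fit_constituent(name, train_data.arrays[name], ytr, cfg, fold_seed)
            constituents.append(con)
            t0 = time.perf_counter()
            Xte = _apply_scaler(test_data.arrays[name], con.center, con.scale)
            pred = _models.predict_proba(con.model, Xte).argmax(axis=1)
            test_time = time.perf_counter() - t0
            scores[name].append(
                multiclass_metrics(confusion(y[te], pred, 3), beta=cfg.beta))
            runtimes[name].append(con.train_time_s + test_time)

        test_inputs = _scaled_inputs(constituents, test_data)
        train_inputs = _scaled_inputs(constituents, train_data)
        for mode in cfg.ensemble_modes:
            t0 = time.perf_counter()
            spec = _ens.EnsembleSpec(
                constituents=[c.model for c in constituents],
                modalities=[c.name for c in constituents],
                mode=mode,
            )
            if mode == "stacked":
                _ens.train_stacked_head(spec, train_inputs, ytr,
                                        _models.TrainConfig(max_epochs=100, patience=20,
                                                            seed=fold_seed))
                pred = _ens.stacked_predict(spec, test_inputs).argmax(axis=1)
            elif mode == "average":
                pred = _ens.average_predict(spec, test_inputs).argmax(axis=1)
            else:
                pred = _ens.majority_predict(spec, test_inputs)
            key = f"ensemble_{mode}"
            scores[key].append(
                multiclass_metrics(confusion(y[te], pred, 3), beta=cfg.beta))
            runtimes[key].append(time.perf_counter() - t0)

    report: dict = {"config": _config_dict(cfg), "models": {}}
    for name in names:
        table: dict = {}
        for metric in ("accuracy", "precision", "sensitivity", "specificity",
                       "fbeta", "mcc"):
            vals = np.array([r.as_dict()[metric] for r in scores[name]])
            table[metric] = [round(float(vals.mean()), 6), round(float(vals.std()), 6)]
        table["runtime_s"] = round(float(np.mean(runtimes[name])), 3)
        report["models"][name] = table
    return report


def _config_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["image_size"] = list(cfg.image_size)
    return d


def format_table(report: dict) -> str:
    """Human-readable table: one row per model, mean±sd per metric."""
    metrics = ("accuracy", "precision", "sensitivity", "specificity", "fbeta", "mcc")
    header = f"{'model':<18}" + "".join(f"{m:>16}" for m in metrics) + f"{'runtime(s)':>12}"
    lines = [header, "-" * len(header)]
    for name, row in report["models"].items():
        cells = "".join(f"{row[m][0]:.3f}±{row[m][1]:.3f}".rjust(16) for m in metrics)
        lines.append(f"{name:<18}" + cells + f"{row['runtime_s']:>12.1f}")
    return "\n".join(lines)


def save_report(report: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
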