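"""Reading, cleaning and conditioning of wearable accelerometer recordings.

The Daphnet dialect is a whitespace-delimited text file with 11 columns per
row: a millisecond timestamp, nine acceleration channels (ankle, leg and
trunk sensors x three axes each) and an integer annotation — 0 for samples
recorded outside the experimental protocol, 1 for experiment without freezing
and 2 for a freezing-of-gait (FOG) episode.  Sampling rate is 64 Hz.

This module turns such files into :class:`SensorRecording` objects, removes
out-of-experiment samples, fuses each sensor's three axes into a magnitude
stream (:class:`MagnitudeRecording`), and offers integer-factor decimation
and min-max normalization for recordings captured at other rates or scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "CHANNEL_NAMES",
    "SENSOR_LOCATIONS",
    "SensorRecording",
    "MagnitudeRecording",
    "DaphnetParseError",
    "read_daphnet",
    "write_daphnet",
    "read_csv",
    "write_csv",
    "drop_out_of_experiment",
    "split_segments",
    "combine_magnitude",
    "resample",
    "minmax_normalize",
]

#: Sensor locations: Ankle, Leg (above knee), Trunk.
SENSOR_LOCATIONS = ("A", "L", "T")

#: The nine acceleration channels, in file column order.
CHANNEL_NAMES = tuple(f"{loc}{ax}" for loc in SENSOR_LOCATIONS for ax in "XYZ")


class DaphnetParseError(ValueError):
    """Raised when a sensor file does not follow the expected layout."""


@dataclass
class SensorRecording:
    """A multichannel acceleration time series with per-sample annotations.

    Attributes
    ----------
    timestamps : ndarray
        Millisecond timestamps, monotone non-decreasing.
    channels : dict
        Ordered mapping of channel name (``AX`` … ``TZ``) to acceleration
        array.  All arrays share one length.
    annotations : ndarray
        Integer per-sample labels in {0, 1, 2}.
    fs : float
        Sampling frequency in Hz (64 for Daphnet).
    """

    timestamps: np.ndarray
    channels: dict[str, np.ndarray]
    annotations: np.ndarray
    fs: float = 64.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps)
        self.annotations = np.asarray(self.annotations, dtype=np.int64)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        n = len(self.annotations)
        if len(self.timestamps) != n:
            raise ValueError("timestamps and annotations length mismatch")
        for name, arr in self.channels.items():
            if len(arr) != n:
                raise ValueError(f"channel {name!r} length {len(arr)} != {n}")
        bad = set(np.unique(self.annotations)) - {0, 1, 2}
        if bad:
            raise ValueError(f"annotations outside {{0,1,2}}: {sorted(bad)}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return len(self.annotations)

    def take(self, idx: np.ndarray) -> "SensorRecording":
        """Return a new recording restricted to the given sample indices."""
        return SensorRecording(
            timestamps=self.timestamps[idx],
            channels={k: v[idx] for k, v in self.channels.items()},
            annotations=self.annotations[idx],
            fs=self.fs,
        )


@dataclass
class MagnitudeRecording:
    """Per-sensor acceleration magnitude streams after axis fusion.

    ``signals`` maps sensor location (``A``, ``L``, ``T``) to the euclidean
    magnitude sqrt(x² + y² + z²) of that sensor's three axes.  Annotations are
    restricted to {1, 2}: out-of-experiment samples must have been removed
    upstream.  ``segment_bounds`` records the [start, stop) sample ranges of
    contiguous source segments so that downstream windowing never straddles a
    gap left by removed data.
    """

    signals: dict[str, np.ndarray]
    annotations: np.ndarray
    fs: float
    segment_bounds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.annotations = np.asarray(self.annotations, dtype=np.int64)
        self.signals = {k: np.asarray(v, dtype=float) for k, v in self.signals.items()}
        n = len(self.annotations)
        for name, arr in self.signals.items():
            if len(arr) != n:
                raise ValueError(f"signal {name!r} length mismatch")
            if np.any(arr < 0):
                raise ValueError("magnitude values must be non-negative")
        if np.any(self.annotations == 0):
            raise ValueError("annotation 0 present; drop out-of-experiment samples first")
        if not self.segment_bounds:
            self.segment_bounds = [(0, n)] if n else []

    def __len__(self) -> int:
        return len(self.annotations)


def _parse_table(text: str, origin: str) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 11:
            raise DaphnetParseError(
                f"{origin}: line {lineno}: expected 11 columns, found {len(parts)}"
            )
        try:
            values = [float(p) for p in parts]
        except ValueError as exc:
            raise DaphnetParseError(f"{origin}: line {lineno}: {exc}") from None
        if values[10] != int(values[10]):
            raise DaphnetParseError(
                f"{origin}: line {lineno}: annotation {parts[10]!r} is not an integer"
            )
        rows.append(values)
    if not rows:
        raise DaphnetParseError(f"{origin}: file contains no samples")
    return np.asarray(rows, dtype=float)


def read_daphnet(path: str | Path, fs: float = 64.0) -> SensorRecording:
    """Read a Daphnet-dialect whitespace-delimited sensor file.

    Columns are: time in ms, ankle X/Y/Z, leg X/Y/Z, trunk X/Y/Z, annotation.

    Raises
    ------
    DaphnetParseError
        If a row has the wrong column count, a non-numeric field, or a
        non-integer annotation, or if the file is empty.
    """
    path = Path(path)
    table = _parse_table(path.read_text(), str(path))
    ann = table[:, 10].astype(np.int64)
    if set(np.unique(ann)) - {0, 1, 2}:
        raise DaphnetParseError(f"{path}: annotations outside {{0,1,2}}")
    return SensorRecording(
        timestamps=table[:, 0],
        channels={name: table[:, i + 1] for i, name in enumerate(CHANNEL_NAMES)},
        annotations=ann,
        fs=fs,
    )


def write_daphnet(rec: SensorRecording, path: str | Path) -> None:
    """Write a recording in the Daphnet whitespace-delimited dialect.

    Floats are rendered with :func:`repr`-grade precision so that a
    read → write → read cycle is bit-exact.
    """
    path = Path(path)
    cols = [rec.timestamps] + [rec.channels[c] for c in CHANNEL_NAMES]
    with path.open("w") as fh:
        for i in range(len(rec)):
            fields = [np.format_float_positional(c[i], trim="-") for c in cols]
            fields.append(str(int(rec.annotations[i])))
            fh.write(" ".join(fields) + "\n")


def read_csv(path: str | Path, fs: float) -> SensorRecording:
    """Read a generic CSV accelerometer export with a header row.

    The file must contain a ``time_ms`` column, the nine channel columns
    named as in :data:`CHANNEL_NAMES`, and an ``annotation`` column.
    """
    df = pd.read_csv(path)
    missing = {"time_ms", "annotation", *CHANNEL_NAMES} - set(df.columns)
    if missing:
        raise DaphnetParseError(f"{path}: missing columns {sorted(missing)}")
    return SensorRecording(
        timestamps=df["time_ms"].to_numpy(float),
        channels={c: df[c].to_numpy(float) for c in CHANNEL_NAMES},
        annotations=df["annotation"].to_numpy(np.int64),
        fs=fs,
    )


def write_csv(rec: SensorRecording, path: str | Path) -> None:
    """Serialize a recording to CSV (columns time_ms, channels…, annotation)."""
    df = pd.DataFrame({"time_ms": rec.timestamps})
    for c in CHANNEL_NAMES:
        df[c] = rec.channels[c]
    df["annotation"] = rec.annotations
    df.to_csv(path, index=False)


def drop_out_of_experiment(rec: SensorRecording) -> SensorRecording:
    """Remove every sample annotated 0 (not part of the experiment).

    Relative order of the surviving samples is preserved.  The result may be
    empty.  Idempotent.
    """
    keep = np.flatnonzero(rec.annotations != 0)
    return rec.take(keep)


def split_segments(rec: SensorRecording) -> list[tuple[int, int]]:
    """[start, stop) ranges of contiguous non-zero-annotated runs.

    Removing out-of-experiment blocks leaves temporal gaps; windows built
    across such gaps would span physically discontinuous signal, so the
    magnitude recording keeps these boundaries.
    """
    mask = rec.annotations != 0
    bounds: list[tuple[int, int]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            bounds.append((start, i))
            start = None
    if start is not None:
        bounds.append((start, len(mask)))
    return bounds


def combine_magnitude(rec: SensorRecording, split_at_gaps: bool = True) -> MagnitudeRecording:
    """Fuse each sensor's three axes into a magnitude stream.

    For each location C in {A, L, T} the output is
    sqrt(X² + Y² + Z²) per sample.  Samples annotated 0 are dropped first;
    with ``split_at_gaps`` (default) the boundaries of the contiguous
    surviving runs are recorded so that segmentation never builds a window
    across a removed block.

    Raises
    ------
    KeyError
        If any of the nine channels is missing.
    """
    missing = set(CHANNEL_NAMES) - set(rec.channels)
    if missing:
        raise KeyError(f"missing channels: {sorted(missing)}")
    raw_bounds = split_segments(rec) if split_at_gaps else None
    kept = drop_out_of_experiment(rec)
    signals = {}
    for loc in SENSOR_LOCATIONS:
        x, y, z = (kept.channels[f"{loc}{ax}"] for ax in "XYZ")
        signals[loc] = np.sqrt(x * x + y * y + z * z)
    if raw_bounds is None:
        bounds = [(0, len(kept))] if len(kept) else []
    else:
        # re-index the per-run bounds into the compacted coordinate system
        bounds = []
        offset = 0
        for s, e in raw_bounds:
            bounds.append((offset, offset + (e - s)))
            offset += e - s
    return MagnitudeRecording(signals=signals, annotations=kept.annotations,
                              fs=kept.fs, segment_bounds=bounds)


def resample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Decimate a signal from ``fs`` to ``target_fs`` with anti-alias filtering.

    Only integer-factor downsampling is supported (the practical case being
    128 Hz exports decimated to the 64 Hz the models are built around).

    Raises
    ------
    ValueError
        If upsampling is requested or the ratio is not an integer.
    """
    if fs <= 0 or target_fs <= 0:
        raise ValueError("sampling rates must be positive")
    if target_fs > fs:
        raise ValueError(f"upsampling {fs} -> {target_fs} Hz is not supported")
    ratio = fs / target_fs
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(f"{fs} Hz is not an integer multiple of {target_fs} Hz")
    x = np.asarray(x, dtype=float)
    if q == 1:
        return x.copy()
    # polyphase FIR anti-alias filter; linear boundary extension avoids
    # edge ringing (constants stay fixed points)
    out = _sig.resample_poly(x, 1, q, padtype="line")
    return out[: int(len(x) * target_fs // fs)]


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map a signal linearly onto [0, 1] via (x - min) / (max - min).

    A constant signal maps to all zeros (division guard).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty signal")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)
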