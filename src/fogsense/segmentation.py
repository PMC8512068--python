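"""Windowing of magnitude signals and PreFOG relabeling.

A magnitude stream is cut into non-overlapping windows of ``w`` seconds
(``w*fs`` samples).  A window containing any FOG-annotated sample is labeled
FOG; the window immediately preceding each FOG run is relabeled PreFOG — the
transition state through which gait deteriorates before a freeze, and the
class whose prediction enables pre-emptive cueing.

Window classes: 0 = NonFOG, 1 = FOG, 2 = PreFOG.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import MagnitudeRecording

__all__ = [
    "NON_FOG",
    "FOG",
    "PRE_FOG",
    "SignalWindow",
    "WindowSet",
    "segment",
    "segment_recording",
    "relabel_prefog",
    "class_counts",
]

NON_FOG, FOG, PRE_FOG = 0, 1, 2


@dataclass
class SignalWindow:
    """One fixed-length window: samples, class label and provenance."""

    samples: np.ndarray
    label: int
    origin: tuple = ("", "", 0)  # (recording id, sensor location, start sample)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.label not in (NON_FOG, FOG, PRE_FOG):
            raise ValueError(f"label must be 0/1/2, got {self.label}")


@dataclass
class WindowSet:
    """An ordered collection of equal-length non-overlapping windows."""

    windows: list[SignalWindow]
    w: float
    fs: float

    def __post_init__(self) -> None:
        n = self.window_length
        for win in self.windows:
            if len(win.samples) != n:
                raise ValueError(f"window length {len(win.samples)} != w*fs = {n}")

    @property
    def window_length(self) -> int:
        return int(round(self.w * self.fs))

    @property
    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=np.int64)

    def matrix(self) -> np.ndarray:
        """Windows stacked as an (n_windows, w*fs) array."""
        if not self.windows:
            return np.empty((0, self.window_length))
        return np.stack([w.samples for w in self.windows])

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def save(self, directory: str | Path, stem: str = "windows") -> None:
        """Write a manifest CSV (origin, start, label) and a sample-matrix CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = pd.DataFrame(
            {
                "recording": [w.origin[0] for w in self.windows],
                "sensor": [w.origin[1] for w in self.windows],
                "start": [w.origin[2] for w in self.windows],
                "label": self.labels,
            }
        )
        manifest.to_csv(directory / f"{stem}_manifest.csv", index=False)
        pd.DataFrame(self.matrix()).to_csv(directory / f"{stem}_samples.csv", index=False)


def segment(
    signal: np.ndarray,
    annotations: np.ndarray,
    w: float,
    fs: float,
    *,
    recording_id: str = "",
    sensor: str = "",
    start_offset: int = 0,
) -> WindowSet:
    """Cut a signal into non-overlapping windows of ``w*fs`` samples.

    Windows live on the half-open grid [k*w*fs, (k+1)*w*fs); the trailing
    remainder is discarded.  A window is labeled FOG (1) if any of its samples
    carries annotation 2, else NonFOG (0).  A signal shorter than one window
    yields an empty :class:`WindowSet`.
    """
    n = int(round(w * fs))
    if n < 2:
        raise ValueError("w*fs must be at least 2 samples")
    signal = np.asarray(signal, dtype=float)
    annotations = np.asarray(annotations)
    if len(signal) != len(annotations):
        raise ValueError("signal and annotations must be aligned")
    k = len(signal) // n
    windows = []
    for i in range(k):
        sl = slice(i * n, (i + 1) * n)
        label = FOG if np.any(annotations[sl] == 2) else NON_FOG
        windows.append(
            SignalWindow(signal[sl], label, (recording_id, sensor, start_offset + i * n))
        )
    return WindowSet(windows, w=w, fs=fs)


def segment_recording(
    rec: MagnitudeRecording, w: float, sensor: str = "A", recording_id: str = ""
) -> WindowSet:
    """Segment one sensor stream of a magnitude recording.

    Each contiguous source segment (between removed out-of-experiment blocks)
    is windowed independently, so no window straddles a discontinuity.
    """
    if sensor not in rec.signals:
        raise KeyError(f"sensor {sensor!r} not in recording")
    sig = rec.signals[sensor]
    windows: list[SignalWindow] = []
    for s, e in rec.segment_bounds:
        ws = segment(
            sig[s:e], rec.annotations[s:e], w, rec.fs,
            recording_id=recording_id, sensor=sensor, start_offset=s,
        )
        windows.extend(ws.windows)
    return WindowSet(windows, w=w, fs=rec.fs)


def relabel_prefog(ws: WindowSet) -> WindowSet:
    """Mark the window immediately before each FOG onset as PreFOG.

    For every maximal run of FOG windows, the grid-adjacent preceding window
    from the same recording/sensor is relabeled 2 provided it is currently
    NonFOG.  FOG labels are never touched, so back-to-back freezes keep their
    observed labels.  Idempotent.
    """
    n = ws.window_length
    out = [SignalWindow(w.samples, w.label, w.origin) for w in ws.windows]
    for i in range(1, len(out)):
        cur, prev = out[i], out[i - 1]
        same_stream = cur.origin[:2] == prev.origin[:2]
        adjacent = cur.origin[2] == prev.origin[2] + n
        if (
            cur.label == FOG
            and prev.label == NON_FOG
            and same_stream
            and adjacent
        ):
            out[i - 1] = SignalWindow(prev.samples, PRE_FOG, prev.origin)
    return WindowSet(out, w=ws.w, fs=ws.fs)


def class_counts(labels: "WindowSet | Iterable[int]") -> dict[int, int]:
    """Count windows per class; always reports all three classes."""
    if isinstance(labels, WindowSet):
        labels = labels.labels
    arr = np.asarray(list(labels), dtype=np.int64)
    return {c: int(np.sum(arr == c)) for c in (NON_FOG, FOG, PRE_FOG)}
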