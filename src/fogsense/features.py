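"""Handcrafted time- and frequency-domain descriptors of a signal window.

Each window of the fused acceleration magnitude is summarized by 27
statistics: order statistics and moments of the amplitude distribution,
signal-magnitude and crossing-rate measures, and spectral measures built on
the window's periodogram — notably the freeze index, the ratio of spectral
power in the freeze band (3–8 Hz, where freezing-of-gait trembling
concentrates) to power in the locomotion band (0.5–3 Hz, normal stepping
rates).

The catalogue of descriptors contains two measures — normalized signal
magnitude area and signal vector magnitude — that coincide on a magnitude
stream (both reduce to mean |x| once the three axes have been fused), so the
default 27-name vector keeps ``norm_sma`` and drops the redundant ``svm``
alias; pass ``keep_svm=True`` to report the same value under the other name.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

__all__ = [
    "FREEZE_BAND",
    "LOCOMOTION_BAND",
    "FEATURE_NAMES",
    "FeatureVector",
    "band_power",
    "freeze_index",
    "mean_crossing_rate",
    "extract_features",
    "feature_matrix",
    "feature_names",
]

#: Freeze-band and locomotion-band edges in Hz.
FREEZE_BAND = (3.0, 8.0)
LOCOMOTION_BAND = (0.5, 3.0)

_BASE_NAMES = (
    "min", "max", "range", "mean", "median", "mode", "trimmed_mean",
    "std", "variance", "rms", "mean_abs", "median_abs_dev",
    "p25", "p75", "iqr", "norm_sma", "skewness", "kurtosis",
    "mean_crossing_rate", "fft_peak",
    "entropy", "energy", "peak_frequency",
    "freeze_band_power", "locomotion_band_power", "freeze_index", "band_power",
)


def feature_names(keep_svm: bool = False) -> tuple[str, ...]:
    """The fixed 27-name feature order (``svm`` aliases ``norm_sma``)."""
    if keep_svm:
        return tuple(n if n != "norm_sma" else "svm" for n in _BASE_NAMES)
    return _BASE_NAMES


FEATURE_NAMES = feature_names()


@dataclass
class FeatureVector:
    """The 27 descriptors of one window, in :data:`FEATURE_NAMES` order."""

    values: np.ndarray
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != 27:
            raise ValueError(f"expected 27 features, got {len(self.values)}")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __len__(self) -> int:
        return len(self.values)


def _periodogram(window: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided rectangular-window periodogram, P[k] = |X_k|^2 / n."""
    window = np.asarray(window, dtype=float)
    n = len(window)
    spec = np.abs(np.fft.rfft(window)) ** 2 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def band_power(window: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Sum of periodogram power over bins with lo <= f <= hi, divided by fs."""
    if not 0 <= lo < hi <= fs / 2:
        raise ValueError(f"band [{lo}, {hi}] outside [0, fs/2]")
    freqs, spec = _periodogram(window, fs)
    mask = (freqs >= lo) & (freqs <= hi)
    return float(spec[mask].sum() / fs)


def freeze_index(window: np.ndarray, fs: float) -> float:
    """Freeze-band power (3–8 Hz) over locomotion-band power (0.5–3 Hz).

    Returns +inf with a warning when the locomotion band carries no power
    (e.g. a constant window).
    """
    fp = band_power(window, fs, *FREEZE_BAND)
    lp = band_power(window, fs, *LOCOMOTION_BAND)
    if lp == 0.0:
        warnings.warn("zero locomotion-band power; freeze index is infinite",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    return fp / lp


def mean_crossing_rate(window: np.ndarray) -> float:
    """Crossings of the window mean, normalized by window length.

    Counts every sign change of (x - mean); samples exactly at the mean do
    not interrupt a crossing.  Result lies in [0, 1).
    """
    x = np.asarray(window, dtype=float)
    if len(x) < 2:
        raise ValueError("window must have at least 2 samples")
    d = np.sign(x - x.mean())
    d = d[d != 0]
    if len(d) < 2:
        return 0.0
    return float(np.sum(d[1:] != d[:-1]) / len(x))


def extract_features(
    window: np.ndarray, fs: float, trim: float = 0.1, keep_svm: bool = False
) -> FeatureVector:
    """Compute the 27-descriptor vector for one window.

    Parameters
    ----------
    window : array
        Signal samples (one windowed magnitude stream).
    fs : float
        Sampling frequency in Hz.
    trim : float
        Fraction cut from each tail for the trimmed mean (default 10%).
    keep_svm : bool
        Report the magnitude-area value under the name ``svm`` instead of
        ``norm_sma`` (the two coincide on a magnitude stream).

    Notes
    -----
    Mode is taken over values rounded to 3 decimals (ties break to the
    smallest value).  Skewness and kurtosis are moment estimators, kurtosis
    non-excess.  Spectral entropy is the Shannon entropy (natural log) of the
    periodogram normalized over non-DC bins.  Variance is the square of the
    population standard deviation.
    """
    x = np.asarray(window, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite values")
    n = len(x)
    freqs, spec = _periodogram(x, fs)

    mn, mx = float(x.min()), float(x.max())
    std = float(x.std())
    mean_abs = float(np.abs(x).mean())
    p25, p75 = (float(q) for q in np.percentile(x, [25, 75]))

    # spectral measures on non-DC bins
    ac = spec[1:]
    total_ac = ac.sum()
    if total_ac > 0:
        p = ac / total_ac
        entropy = float(-np.sum(p[p > 0] * np.log(p[p > 0])))
        peak_freq = float(freqs[1:][np.argmax(ac)])
    else:
        entropy = 0.0
        peak_freq = 0.0

    fbp = band_power(x, fs, *FREEZE_BAND)
    lbp = band_power(x, fs, *LOCOMOTION_BAND)
    fi = freeze_index(x, fs)

    values = [
        mn,
        mx,
        mx - mn,
        float(x.mean()),
        float(np.median(x)),
        float(_stats.mode(np.round(x, 3)).mode),
        float(_stats.trim_mean(x, trim)),
        std,
        std ** 2,
        float(np.sqrt(np.mean(x ** 2))),
        mean_abs,
        float(np.median(np.abs(x - np.median(x)))),
        p25,
        p75,
        p75 - p25,
        mean_abs,                       # normalized signal magnitude area
        float(_stats.skew(x)) if std > 0 else 0.0,
        float(_stats.kurtosis(x, fisher=False)) if std > 0 else 0.0,
        mean_crossing_rate(x),
        float(np.max(np.abs(np.fft.rfft(x))) / n),
        entropy,
        float(np.sum(np.abs(np.fft.fft(x)) ** 2) / n),
        peak_freq,
        fbp,
        lbp,
        fi,
        fbp + lbp,
    ]
    return FeatureVector(np.asarray(values), names=feature_names(keep_svm))


def feature_matrix(windows: np.ndarray, fs: float, **kw) -> np.ndarray:
    """Stack :func:`extract_features` over the rows of a window matrix."""
    return np.stack([extract_features(row, fs, **kw).values for row in np.atleast_2d(windows)])
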