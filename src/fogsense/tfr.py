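"""Time-frequency image encodings of signal windows.

Each window is rendered as a fixed-size 3-channel image under one of four
encodings, so a 2-D convolutional network can read the window's temporal and
spectral structure:

``RP``
    Recurrence plot — binary matrix marking time pairs (i, j) whose
    amplitudes differ by at most a similarity threshold ε.
``STFT``
    Short-time Fourier transform magnitude spectrogram.
``DWT``
    Haar discrete wavelet decomposition, approximation and detail coefficient
    tracks stacked as horizontal heatmap bands.
``PWVD``
    Pseudo Wigner-Ville distribution — the bilinear Wigner-Ville
    time-frequency distribution with a frequency-smoothing taper on the
    instantaneous autocorrelation, computed on the analytic signal.

Rendering maps matrix values through a fixed perceptually uniform colormap to
3×H×W arrays in [0, 255]; network-side normalization divides each channel by
255 and then by its mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from matplotlib import colormaps
from scipy import signal as _sig
from skimage.transform import resize as _resize

__all__ = [
    "ENCODINGS",
    "RPConfig",
    "TFRImage",
    "recurrence_matrix",
    "stft_spectrogram",
    "haar_dwt",
    "haar_idwt",
    "pwvd",
    "render_image",
    "normalize_image",
    "encode_window",
]

ENCODINGS = ("RP", "STFT", "DWT", "PWVD")

#: Colormap used for every encoding; fixed so images are bit-reproducible.
_COLORMAP = "viridis"


@dataclass
class RPConfig:
    """Recurrence-plot threshold policy.

    ``epsilon_policy`` is one of ``"fixed"`` (ε = ``epsilon_param``),
    ``"range_fraction"`` (ε = param × signal range) or
    ``"distance_percentile"`` (ε = the param-th percentile of all pairwise
    distances; the scale-free default used in recurrence analysis practice).
    """

    epsilon_policy: str = "distance_percentile"
    epsilon_param: float = 10.0

    def resolve(self, window: np.ndarray) -> float:
        x = np.asarray(window, dtype=float)
        if self.epsilon_policy == "fixed":
            eps = float(self.epsilon_param)
        elif self.epsilon_policy == "range_fraction":
            eps = float(self.epsilon_param) * float(x.max() - x.min())
        elif self.epsilon_policy == "distance_percentile":
            d = np.abs(x[:, None] - x[None, :])
            eps = float(np.percentile(d[np.triu_indices(len(x), k=1)], self.epsilon_param))
        else:
            raise ValueError(f"unknown epsilon policy {self.epsilon_policy!r}")
        if eps < 0:
            raise ValueError("resolved epsilon must be >= 0")
        return eps


@dataclass
class TFRImage:
    """A 3×H×W image rendering of one window under one encoding."""

    pixels: np.ndarray
    encoding: str
    source: tuple = ("", "", 0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 3:
            raise ValueError(f"pixels must be (3, H, W), got {self.pixels.shape}")
        if self.encoding not in ENCODINGS:
            raise ValueError(f"encoding must be one of {ENCODINGS}")


def recurrence_matrix(window: np.ndarray, cfg: RPConfig | None = None) -> np.ndarray:
    """Binary recurrence matrix R[i, j] = 1 iff |x(i) - x(j)| <= ε.

    Symmetric with unit diagonal.
    """
    x = np.asarray(window, dtype=float)
    if len(x) < 2:
        raise ValueError("window must have at least 2 samples")
    cfg = cfg or RPConfig()
    eps = cfg.resolve(x)
    return (np.abs(x[:, None] - x[None, :]) <= eps).astype(np.uint8)


def stft_spectrogram(
    window: np.ndarray,
    fs: float,
    seg_len: int | None = None,
    overlap: int | None = None,
    taper: str = "hann",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude spectrogram of one window.

    Defaults: Hann taper, segment length fs/4 and 50% overlap, which yields
    at least 8 frames on a 2 s window at 64 Hz.

    Returns ``(freqs, times, S)`` with S of shape (n_freqs, n_frames),
    non-negative, frequency axis spanning [0, fs/2].
    """
    x = np.asarray(window, dtype=float)
    if seg_len is None:
        seg_len = max(2, int(fs) // 4)
    if seg_len > len(x):
        raise ValueError(f"seg_len {seg_len} exceeds window length {len(x)}")
    if overlap is None:
        overlap = seg_len // 2
    if overlap >= seg_len:
        raise ValueError("overlap must be smaller than seg_len")
    # boundary=None/padded=False keeps only frames fully inside the window,
    # so no slice mixes signal with zero padding
    freqs, times, Z = _sig.stft(
        x, fs=fs, window=taper, nperseg=seg_len, noverlap=overlap,
        boundary=None, padded=False,
    )
    return freqs, times, np.abs(Z)


def haar_dwt(window: np.ndarray, levels: int = 1) -> tuple[np.ndarray, list[np.ndarray]]:
    """Orthonormal Haar analysis of a window.

    Level 1: a[k] = (x[2k] + x[2k+1]) / sqrt(2), d[k] = (x[2k] - x[2k+1]) /
    sqrt(2); deeper levels recurse on the approximation.  Returns
    ``(approximation, [detail_level1, ..., detail_levelL])`` with details
    ordered from finest to coarsest.

    Raises
    ------
    ValueError
        If the window length is not divisible by 2**levels.
    """
    x = np.asarray(window, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(x) % (2 ** levels):
        raise ValueError(f"length {len(x)} not divisible by 2^{levels}")
    coeffs = pywt.wavedec(x, "haar", mode="periodization", level=levels)
    approx = coeffs[0]
    details = list(reversed(coeffs[1:]))  # finest first
    return approx, details


def haar_idwt(approx: np.ndarray, details: list[np.ndarray]) -> np.ndarray:
    """Inverse of :func:`haar_dwt` (exact reconstruction)."""
    coeffs = [np.asarray(approx, dtype=float)] + [np.asarray(d, float) for d in reversed(details)]
    return pywt.waverec(coeffs, "haar", mode="periodization")


def pwvd(
    window: np.ndarray, fs: float, smoothing_len: int | None = None, n_freq: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pseudo Wigner-Ville distribution of one window.

    The Wigner-Ville kernel x(n+k)·conj(x(n-k)) is computed on the analytic
    signal (suppressing negative-frequency cross terms), multiplied by an odd-
    length Hann frequency-smoothing taper h(k) — the "pseudo" ingredient —
    and Fourier-transformed over the lag k.  The result is real-valued with
    one time slice per input sample; amplitude scaling of the window scales
    the distribution quadratically (bilinearity).

    Parameters
    ----------
    smoothing_len : odd int
        Length of the lag taper; defaults to the largest odd number
        <= len(window)/4.

    Returns ``(freqs, times, W)`` with W of shape (n_freq, len(window)).
    """
    x = np.asarray(window, dtype=float)
    n = len(x)
    if smoothing_len is None:
        smoothing_len = max(3, (n // 4) | 1)
    if smoothing_len % 2 == 0:
        raise ValueError("smoothing_len must be odd")
    if smoothing_len > n:
        raise ValueError("smoothing_len exceeds window length")
    if n_freq is None:
        n_freq = n
    z = _sig.hilbert(x)
    half = (smoothing_len - 1) // 2
    taper = _sig.get_window("hann", smoothing_len, fftbins=False)
    R = np.zeros((n_freq, n), dtype=complex)
    for t in range(n):
        kmax = min(t, n - 1 - t, half, (n_freq - 1) // 2)
        k = np.arange(1, kmax + 1)
        R[0, t] = taper[half] * z[t] * np.conj(z[t])
        vals = taper[half + k] * z[t + k] * np.conj(z[t - k])
        R[k, t] = vals
        R[-k, t] = np.conj(vals)
    W = np.real(np.fft.fft(R, axis=0))
    freqs = np.arange(n_freq) * fs / (2.0 * n_freq)
    times = np.arange(n) / fs
    return freqs, times, W


def render_image(
    matrix: np.ndarray | tuple,
    encoding: str,
    size: tuple[int, int] = (128, 128),
    source: tuple = ("", "", 0),
) -> TFRImage:
    """Render a matrix (or DWT coefficient pair) as a 3×H×W image in [0, 255].

    Values are min-max scaled to [0, 1] (a constant matrix maps to zeros),
    passed through a fixed perceptually uniform colormap and bilinearly
    resized.  For the DWT encoding pass ``(approx, details)``: the
    coefficient tracks are stacked as horizontal bands before mapping.
    """
    if encoding == "DWT" and isinstance(matrix, tuple):
        approx, details = matrix
        tracks = [np.asarray(approx, dtype=float)] + [np.asarray(d, float) for d in details]
        width = max(len(t) for t in tracks)
        matrix = np.stack([
            np.repeat(t, width // len(t)) if width % len(t) == 0
            else _resize(t, (width,), order=0, anti_aliasing=False)
            for t in tracks
        ])
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise ValueError("cannot render an empty matrix")
    if m.ndim == 1:
        m = m[None, :]
    lo, hi = m.min(), m.max()
    gray = np.zeros_like(m) if hi == lo else (m - lo) / (hi - lo)
    rgb = colormaps[_COLORMAP](gray)[..., :3]  # (H, W, 3) in [0, 1]
    # smooth before downscaling so fine texture (e.g. recurrence lines)
    # maps to local density instead of aliasing noise
    aa = rgb.shape[0] > size[0] or rgb.shape[1] > size[1]
    rgb = _resize(rgb, size, order=1, anti_aliasing=aa, preserve_range=True)
    pixels = np.transpose(rgb, (2, 0, 1)) * 255.0
    return TFRImage(pixels=pixels, encoding=encoding, source=source)


def normalize_image(img: TFRImage) -> TFRImage:
    """Scale channels to [0, 1] then center by dividing by the channel mean.

    Each channel is divided by 255 and then by its mean, so non-zero channels
    come out with mean exactly 1.  An all-zero channel stays zero (with a
    warning) rather than producing NaNs.
    """
    p = img.pixels / 255.0
    out = np.empty_like(p)
    for c in range(3):
        mean = p[c].mean()
        if mean == 0.0:
            warnings.warn(f"channel {c} is all zeros; left unnormalized",
                          RuntimeWarning, stacklevel=2)
            out[c] = p[c]
        else:
            out[c] = p[c] / mean
    return TFRImage(pixels=out, encoding=img.encoding, source=img.source)


def encode_window(
    window: np.ndarray,
    fs: float,
    encoding: str,
    size: tuple[int, int] = (128, 128),
    rp_config: RPConfig | None = None,
    normalized: bool = True,
    source: tuple = ("", "", 0),
) -> TFRImage:
    """One-stop encoding of a raw window into a (normalized) TFR image."""
    if encoding == "RP":
        mat: np.ndarray | tuple = recurrence_matrix(window, rp_config)
    elif encoding == "STFT":
        mat = stft_spectrogram(window, fs)[2]
    elif encoding == "DWT":
        mat = haar_dwt(window, levels=1)
    elif encoding == "PWVD":
        mat = pwvd(window, fs)[2]
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    img = render_image(mat, encoding, size=size, source=source)
    return normalize_image(img) if normalized else img
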