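"""Encode one window under the four time-frequency image encodings.

Each 2-second window becomes a 3x32x32 image: recurrence plot (RP), STFT
spectrogram, Haar wavelet coefficient bands (DWT) and pseudo Wigner-Ville
distribution (PWVD).  After normalization every non-zero channel has mean
exactly 1 — the form the convolutional classifier consumes.
"""

import numpy as np

from fogsense.segmentation import FOG
from fogsense.synthetic import SimulationConfig, make_balanced_windowset
from fogsense.tfr import ENCODINGS, encode_window, pwvd, stft_spectrogram

windows, _ = make_balanced_windowset(SimulationConfig(n_fog_events=6, seed=42), w=2.0)
fog_window = next(w for w in windows if w.label == FOG)

for encoding in ENCODINGS:
    img = encode_window(fog_window.samples, windows.fs, encoding, size=(32, 32))
    means = [img.pixels[c].mean() for c in range(3)]
    print(f"{encoding:>4}: shape {img.pixels.shape}, channel means "
          f"{np.round(means, 6)}")

# skip the DC bin: the magnitude stream carries the gravity offset there
freqs, _, S = stft_spectrogram(fog_window.samples, windows.fs)
print(f"STFT dominant frequency of this FOG window: "
      f"{freqs[1:][np.argmax(S[1:].sum(axis=1))]:.1f} Hz (freeze band is 3-8 Hz)")
demeaned = fog_window.samples - fog_window.samples.mean()
freqs, _, W = pwvd(demeaned, windows.fs)
print(f"PWVD dominant frequency: {freqs[1:][np.argmax(W[1:].sum(axis=1))]:.2f} Hz")
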