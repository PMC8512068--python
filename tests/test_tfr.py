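"""Time-frequency encodings against brute-force and closed-form oracles."""

import numpy as np
import pytest

from fogsense.tfr import (
    RPConfig,
    TFRImage,
    encode_window,
    haar_dwt,
    haar_idwt,
    normalize_image,
    pwvd,
    recurrence_matrix,
    render_image,
    stft_spectrogram,
)

FS = 64.0


def _tone(freq, n=128, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


def _brute_force_rp(x, eps):
    n = len(x)
    R = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for j in range(n):
            R[i, j] = 1 if abs(x[i] - x[j]) <= eps else 0
    return R


class TestRecurrenceMatrix:
    def test_constant_window_all_ones(self):
        assert recurrence_matrix(np.ones(8), RPConfig("fixed", 0.0)).all()

    def test_tiny_explicit_case(self):
        R = recurrence_matrix(np.array([0.0, 1.0, 0.0]), RPConfig("fixed", 0.5))
        np.testing.assert_array_equal(R, [[1, 0, 1], [0, 1, 0], [1, 0, 1]])

    def test_saturating_epsilon_gives_all_ones(self, rng):
        x = rng.normal(size=32)
        eps = np.abs(x[:, None] - x[None, :]).max()
        assert recurrence_matrix(x, RPConfig("fixed", eps)).all()

    @pytest.mark.parametrize("n", [2, 17, 64, 256])
    def test_matches_brute_force_double_loop(self, rng, n):
        x = rng.normal(size=n)
        cfg = RPConfig("distance_percentile", 10.0)
        eps = cfg.resolve(x)
        np.testing.assert_array_equal(recurrence_matrix(x, cfg), _brute_force_rp(x, eps))

    def test_symmetry_and_unit_diagonal(self, rng):
        R = recurrence_matrix(rng.normal(size=50))
        assert np.array_equal(R, R.T)
        assert np.all(np.diag(R) == 1)


class TestSTFT:
    def test_tone_peak_in_every_frame(self):
        freqs, _, S = stft_spectrogram(_tone(5.0), FS)
        peak_bins = freqs[np.argmax(S, axis=0)]
        target = freqs[np.argmin(np.abs(freqs - 5.0))]
        assert np.all(peak_bins == target)

    def test_zero_signal_all_zero(self):
        _, _, S = stft_spectrogram(np.zeros(128), FS)
        assert np.all(S == 0)

    def test_frequency_shift_moves_dominant_bin(self):
        x = np.concatenate([_tone(1.0, 64), _tone(5.0, 64)])
        freqs, _, S = stft_spectrogram(x, FS)
        assert freqs[np.argmax(S[:, 0])] < freqs[np.argmax(S[:, -1])]

    def test_nonnegative_and_band_limited(self, rng):
        freqs, _, S = stft_spectrogram(rng.normal(size=128), FS)
        assert np.all(S >= 0)
        assert freqs[0] == 0 and freqs[-1] == FS / 2

    def test_oversized_segment_rejected(self):
        with pytest.raises(ValueError, match="seg_len"):
            stft_spectrogram(np.zeros(8), FS, seg_len=16)


class TestHaarDWT:
    def test_explicit_matrix_case(self):
        a, (d,) = haar_dwt(np.array([1.0, 1.0, 1.0, 1.0]), 1)
        np.testing.assert_allclose(a, [np.sqrt(2), np.sqrt(2)])
        np.testing.assert_allclose(d, [0, 0])

    def test_matches_explicit_haar_matrix(self, rng):
        """One level equals multiplication by the orthonormal Haar matrix."""
        n = 16
        x = rng.normal(size=n)
        H = np.zeros((n, n))
        for k in range(n // 2):
            H[k, 2 * k] = H[k, 2 * k + 1] = 1 / np.sqrt(2)
            H[n // 2 + k, 2 * k] = 1 / np.sqrt(2)
            H[n // 2 + k, 2 * k + 1] = -1 / np.sqrt(2)
        expected = H @ x
        a, (d,) = haar_dwt(x, 1)
        np.testing.assert_allclose(a, expected[: n // 2], atol=1e-12)
        np.testing.assert_allclose(d, expected[n // 2:], atol=1e-12)

    def test_constants_annihilated_at_every_level(self):
        a, details = haar_dwt(np.full(64, 3.3), 3)
        for d in details:
            np.testing.assert_allclose(d, 0, atol=1e-12)

    def test_energy_conservation_and_reconstruction(self, rng):
        x = rng.normal(size=128)
        a, details = haar_dwt(x, 3)
        energy = np.sum(a ** 2) + sum(np.sum(d ** 2) for d in details)
        assert energy == pytest.approx(np.sum(x ** 2), abs=1e-9)
        np.testing.assert_allclose(haar_idwt(a, details), x, atol=1e-9)

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            haar_dwt(np.zeros(6), 2)


class TestPWVD:
    def test_tone_peak_at_interior_times(self):
        freqs, _, W = pwvd(_tone(5.0), FS)
        interior = W[:, 20:108]
        peaks = freqs[np.argmax(interior, axis=0)]
        assert np.all(np.abs(peaks - 5.0) <= freqs[1])

    def test_zero_signal(self):
        _, _, W = pwvd(np.zeros(64), FS)
        assert np.all(W == 0)

    def test_bilinearity_in_amplitude(self, rng):
        x = rng.normal(size=64)
        _, _, W1 = pwvd(x, FS)
        _, _, W2 = pwvd(2.0 * x, FS)
        np.testing.assert_allclose(W2, 4.0 * W1, atol=1e-9)

    def test_real_valued_with_time_axis_length(self, rng):
        x = rng.normal(size=64)
        _, times, W = pwvd(x, FS)
        assert W.shape[1] == 64 and len(times) == 64
        assert np.isrealobj(W)

    def test_even_smoothing_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            pwvd(np.zeros(64), FS, smoothing_len=8)


class TestRenderNormalize:
    def test_output_shape_contract(self, rng):
        img = render_image(rng.normal(size=(17, 23)), "STFT", size=(32, 32))
        assert img.pixels.shape == (3, 32, 32)

    @pytest.mark.parametrize("matrix", [np.zeros((8, 8)), np.ones((8, 8))])
    def test_constant_matrix_gives_flat_image(self, matrix):
        img = render_image(matrix, "RP", size=(16, 16))
        for c in range(3):
            assert np.ptp(img.pixels[c]) == pytest.approx(0.0, abs=1e-9)

    def test_monotone_grayscale_before_colormap(self, rng):
        """Pointwise-ordered matrices map to ordered grayscale intensities."""
        a = rng.random((8, 8))
        b = a + 0.1
        ga = (a - a.min()) / np.ptp(a)
        gb = (b - b.min()) / np.ptp(b)
        order = np.argsort(ga.ravel())
        assert np.all(np.diff(gb.ravel()[order]) >= -1e-12)

    def test_normalize_constant_255_channel_fixed_point(self):
        img = TFRImage(np.full((3, 4, 4), 255.0), "RP")
        out = normalize_image(img)
        np.testing.assert_allclose(out.pixels, 1.0)

    def test_normalize_two_step_arithmetic(self):
        px = np.zeros((3, 1, 2))
        px[:, 0] = [0.0, 255.0]
        out = normalize_image(TFRImage(px, "RP"))
        for c in range(3):
            np.testing.assert_allclose(out.pixels[c, 0], [0.0, 2.0])

    def test_normalize_zero_channel_warns_and_stays_zero(self):
        with pytest.warns(RuntimeWarning, match="zeros"):
            out = normalize_image(TFRImage(np.zeros((3, 4, 4)), "RP"))
        assert np.all(out.pixels == 0)

    def test_nonzero_channel_mean_is_one(self, rng):
        img = encode_window(rng.normal(size=128), FS, "STFT", size=(32, 32))
        for c in range(3):
            assert img.pixels[c].mean() == pytest.approx(1.0)

    @pytest.mark.parametrize("encoding", ["RP", "STFT", "DWT", "PWVD"])
    def test_encode_window_every_encoding(self, rng, encoding):
        img = encode_window(rng.normal(size=128), FS, encoding, size=(32, 32))
        assert img.pixels.shape == (3, 32, 32)
        assert np.all(np.isfinite(img.pixels))
        assert img.encoding == encoding
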