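"""Preprocessing chain: Butterworth band-pass, resampling, length
normalization and STFT, checked against analytic signals and the designed
filter's own frequency response."""

import numpy as np
import pytest

from liquidecg.preprocess import (
    FilterSpec,
    PreprocessConfig,
    STFTConfig,
    bandpass_filter,
    normalize_length,
    preprocess_pipeline,
    resample,
    stft,
)
from liquidecg.recording import InvalidInputError, InvalidSpecError, Recording


def make_rec(signal, fs=500.0, **kw):
    return Recording(signal=np.atleast_2d(signal), fs=fs, **kw)


def sine(freq, fs, n, n_ch=1):
    t = np.arange(n) / fs
    return np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))


class TestBandpass:
    def test_zero_in_zero_out(self):
        rec = make_rec(np.zeros((12, 5000)))
        out = bandpass_filter(rec)
        assert np.all(out.signal == 0) and out.signal.shape == (12, 5000)

    def test_powerline_rejection_matches_designed_response(self):
        """50 Hz output RMS < 0.2x input and agrees with |H(50)|^2 (zero-phase)."""
        rec = make_rec(sine(50, 500, 5000))
        out = bandpass_filter(rec)
        mid = slice(1000, 4000)  # avoid filter edge transients
        ratio = np.sqrt(np.mean(out.signal[0, mid] ** 2) / np.mean(rec.signal[0, mid] ** 2))
        assert ratio < 0.2
        expected = FilterSpec().magnitude(50.0, 500.0)[0] ** 2  # forward-backward
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_in_band_passes_within_5pct(self):
        rec = make_rec(sine(10, 500, 5000))
        out = bandpass_filter(rec)
        mid = slice(1000, 4000)
        ratio = np.sqrt(np.mean(out.signal[0, mid] ** 2) / np.mean(rec.signal[0, mid] ** 2))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_linearity(self, rng):
        x = rng.normal(size=(1, 4000))
        y = rng.normal(size=(1, 4000))
        a, b = 2.5, -1.3
        fx = bandpass_filter(make_rec(x)).signal
        fy = bandpass_filter(make_rec(y)).signal
        fxy = bandpass_filter(make_rec(a * x + b * y)).signal
        np.testing.assert_allclose(fxy, a * fx + b * fy, rtol=1e-9, atol=1e-12)

    def test_50hz_attenuated_below_10hz(self):
        mag = FilterSpec().magnitude(np.array([10.0, 50.0]), 500.0)
        assert mag[1] < mag[0]

    def test_channels_filtered_independently(self, rng):
        sig = rng.normal(size=(3, 2000))
        out = bandpass_filter(make_rec(sig))
        single = bandpass_filter(make_rec(sig[1:2]))
        np.testing.assert_allclose(out.signal[1], single.signal[0], rtol=1e-12)

    def test_invalid_spec_and_input(self):
        with pytest.raises(InvalidSpecError):
            bandpass_filter(make_rec(np.ones((1, 100))), FilterSpec(high_hz=300.0))
        bad = make_rec(np.ones((1, 100)))
        bad.signal[0, 3] = np.nan
        with pytest.raises(InvalidInputError):
            bandpass_filter(bad)


class TestResample:
    def test_400_to_500(self):
        rec = make_rec(np.zeros((12, 4000)), fs=400)
        out = resample(rec, 500)
        assert out.signal.shape == (12, 5000) and out.fs == 500

    def test_identity(self, rng):
        rec = make_rec(rng.normal(size=(2, 1000)), fs=400)
        out = resample(rec, 400)
        assert out.n_samples == 1000
        np.testing.assert_allclose(out.signal, rec.signal, atol=1e-12)

    def test_sine_preserved(self):
        fs, n = 400, 4000
        rec = make_rec(sine(5, fs, n), fs=fs)
        out = resample(rec, 500)
        t_new = np.arange(out.n_samples) / 500.0
        expected = np.sin(2 * np.pi * 5 * t_new)
        core = slice(100, out.n_samples - 100)
        assert np.max(np.abs(out.signal[0, core] - expected[core])) < 1e-3

    def test_empty_output_error(self):
        rec = make_rec(np.ones((1, 10)), fs=400)
        with pytest.raises(InvalidSpecError):
            resample(rec, 1e-3)


class TestNormalizeLength:
    def test_truncates_to_first_4096(self, rng):
        sig = rng.normal(size=(12, 5000))
        out = normalize_length(make_rec(sig))
        np.testing.assert_array_equal(out.signal, sig[:, :4096])

    def test_identity(self, rng):
        sig = rng.normal(size=(12, 4096))
        out = normalize_length(make_rec(sig))
        np.testing.assert_array_equal(out.signal, sig)

    def test_pads_tail_with_zeros(self, rng):
        sig = rng.normal(size=(12, 3000))
        out = normalize_length(make_rec(sig))
        assert out.signal.shape == (12, 4096)
        np.testing.assert_array_equal(out.signal[:, :3000], sig)
        assert np.all(out.signal[:, 3000:] == 0)

    def test_idempotent(self, rng):
        rec = make_rec(rng.normal(size=(2, 5000)))
        once = normalize_length(rec)
        twice = normalize_length(once)
        np.testing.assert_array_equal(once.signal, twice.signal)


class TestSTFT:
    def test_zero_signal(self):
        out = stft(make_rec(np.zeros((3, 1000))))
        assert np.all(out.values == 0)
        assert out.n_freq_bins == 128 // 2 + 1

    def test_unit_impulse_flat_spectrum(self):
        n = 64
        x = np.zeros((1, n))
        x[0, 0] = 1.0
        cfg = STFTConfig(window_len=n, hop=n, window_fn="rectangular")
        out = stft(make_rec(x), cfg)
        assert out.n_frames == 1
        np.testing.assert_allclose(np.abs(out.values[0, :, 0]), 1.0, atol=1e-12)

    def test_bin_aligned_sine_concentrates_energy(self):
        fs, n, k0 = 500.0, 512, 10
        cfg = STFTConfig(window_len=128, hop=128, window_fn="rectangular")
        rec = make_rec(sine(k0 * fs / 128, fs, n), fs=fs)
        out = stft(rec, cfg)
        energy = out.values[0] ** 2
        assert np.all(energy[k0] / energy.sum(axis=0) > 0.99)

    def test_frame_count_formula(self, rng):
        rec = make_rec(rng.normal(size=(1, 1000)))
        cfg = STFTConfig(window_len=128, hop=64)
        assert stft(rec, cfg).n_frames == (1000 - 128) // 64 + 1

    def test_parseval_per_frame(self, rng):
        """Rectangular window, hop = window: frame energy is conserved
        (one-sided spectrum doubles interior bins)."""
        n = 256
        sig = rng.normal(size=(1, n))
        cfg = STFTConfig(window_len=64, hop=64, window_fn="rectangular")
        out = stft(make_rec(sig), cfg)
        for f in range(out.n_frames):
            frame = sig[0, f * 64 : f * 64 + 64]
            spec2 = out.values[0, :, f] ** 2
            spectral = (2 * spec2.sum() - spec2[0] - spec2[-1]) / 64
            assert spectral == pytest.approx(np.sum(frame**2), rel=1e-6)

    def test_window_longer_than_signal_errors(self):
        with pytest.raises(InvalidSpecError):
            stft(make_rec(np.ones((1, 100))), STFTConfig(window_len=128, hop=64))

    def test_invalid_hop(self):
        with pytest.raises(InvalidSpecError):
            STFTConfig(window_len=64, hop=65)


class TestPipeline:
    def test_shapes_from_config_only(self, rng):
        out = []
        for _ in range(2):
            rec = make_rec(rng.normal(size=(12, 4000)), fs=400)
            out.append(preprocess_pipeline(rec))
        assert out[0].values.shape == out[1].values.shape
        assert out[0].n_channels == 12
        # 4096-sample input, window 128, hop 64
        assert out[0].n_frames == (4096 - 128) // 64 + 1

    def test_deterministic(self, rng):
        sig = rng.normal(size=(12, 4000))
        a = preprocess_pipeline(make_rec(sig, fs=400))
        b = preprocess_pipeline(make_rec(sig.copy(), fs=400))
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_values_rejected(self, rng):
        sig = rng.normal(size=(12, 4000))
        sig[4, :] = np.nan
        with pytest.raises(InvalidInputError):
            preprocess_pipeline(make_rec(sig, fs=400))

    def test_config_bundle_applies(self, rng):
        rec = make_rec(rng.normal(size=(12, 4000)), fs=400)
        a = PreprocessConfig().apply(rec)
        b = preprocess_pipeline(rec)
        np.testing.assert_array_equal(a.values, b.values)
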