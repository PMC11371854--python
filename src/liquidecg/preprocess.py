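"""Raw ECG -> model-ready spectrogram tensor.

The chain is: Butterworth band-pass (0.5–40 Hz, applied forward-backward so
the P/QRS/T morphology is not delayed), polyphase resampling to a common
rate, normalization to a fixed length of 4096 samples (truncate the tail /
zero-pad the tail), then a per-channel short-time Fourier transform whose
magnitude is the classifier input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .recording import InvalidInputError, InvalidSpecError, Recording

TARGET_LEN_DEFAULT = 4096


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; family is fixed to Butterworth."""

    low_hz: float = 0.5
    high_hz: float = 40.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise InvalidSpecError(f"need 0 < low_hz < high_hz, got {self}")
        if self.high_hz >= fs / 2:
            raise InvalidSpecError(
                f"high_hz={self.high_hz} must be below Nyquist {fs / 2}"
            )
        if self.order < 1:
            raise InvalidSpecError("filter order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order sections of the designed Butterworth band-pass."""
        self.validate(fs)
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs, output="sos"
        )

    def magnitude(self, freqs_hz, fs: float) -> np.ndarray:
        """Single-pass magnitude response of the designed filter at ``freqs_hz``."""
        _, h = sps.sosfreqz(self.sos(fs), worN=np.atleast_1d(freqs_hz), fs=fs)
        return np.abs(h)


@dataclass(frozen=True)
class STFTConfig:
    """Windowed-DFT analysis parameters.

    ``window_len`` is the DFT length N, ``hop`` the stride between window
    starts; frames are fully contained in the signal (no padding), so
    ``n_frames = floor((n_samples - window_len)/hop) + 1``.
    """

    window_len: int = 128
    hop: int = 64
    window_fn: str = "hann"
    output_mode: str = "magnitude"  # or "complex"

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.window_len):
            raise InvalidSpecError(f"need 0 < hop <= window_len, got {self}")
        if self.output_mode not in ("magnitude", "complex"):
            raise InvalidSpecError(f"unknown output_mode {self.output_mode!r}")

    def window(self) -> np.ndarray:
        name = "boxcar" if self.window_fn in ("rect", "rectangular") else self.window_fn
        w = sps.get_window(name, self.window_len, fftbins=True)
        if w.min() < 0 or not np.isclose(w.max(), 1.0):
            raise InvalidSpecError("window weights must be non-negative with max 1")
        return w


@dataclass
class SpectrogramTensor:
    """Per-channel time-frequency array, the classifier's input."""

    values: np.ndarray  # (n_channels, n_freq_bins, n_frames)
    freq_axis: np.ndarray  # Hz per bin
    time_axis: np.ndarray  # window-center time in seconds per frame
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_freq_bins(self) -> int:
        return self.values.shape[1]

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class PreprocessConfig:
    """Bundle of all preprocessing-stage parameters."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    stft: STFTConfig = field(default_factory=STFTConfig)
    target_fs: float = 500.0
    target_len: int = TARGET_LEN_DEFAULT

    def apply(self, rec: Recording) -> "SpectrogramTensor":
        return preprocess_pipeline(
            rec, self.filter, self.stft, self.target_fs, self.target_len
        )


def bandpass_filter(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Apply the Butterworth band-pass independently to every channel.

    Zero-phase by default (forward-backward), so the effective magnitude is
    the squared single-pass response and there is no group-delay shift.
    """
    spec = spec or FilterSpec()
    rec.require_finite()
    sos = spec.sos(rec.fs)
    if spec.zero_phase:
        out = sps.sosfiltfilt(sos, rec.signal, axis=1)
    else:
        out = sps.sosfilt(sos, rec.signal, axis=1)
    return rec.replace(signal=np.ascontiguousarray(out))


def resample(rec: Recording, target_fs: float) -> Recording:
    """Band-limited polyphase resampling to ``target_fs``."""
    if not target_fs > 0:
        raise InvalidSpecError(f"target_fs must be positive, got {target_fs}")
    n_out = int(round(rec.n_samples * target_fs / rec.fs))
    if n_out < 1:
        raise InvalidSpecError("resampling would produce an empty signal")
    if target_fs == rec.fs:
        return rec.replace()
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.signal, ratio.numerator, ratio.denominator, axis=1)
    # resample_poly yields ceil(n*up/down) samples; enforce the rounded length
    if out.shape[1] > n_out:
        out = out[:, :n_out]
    elif out.shape[1] < n_out:
        out = np.pad(out, ((0, 0), (0, n_out - out.shape[1])))
    return rec.replace(signal=np.ascontiguousarray(out), fs=float(target_fs))


def normalize_length(rec: Recording, target_len: int = TARGET_LEN_DEFAULT) -> Recording:
    """Fix every channel to exactly ``target_len`` samples.

    Longer recordings keep their first ``target_len`` samples (the onset);
    shorter ones are zero-padded at the tail.
    """
    if target_len < 1:
        raise InvalidSpecError("target_len must be positive")
    n = rec.n_samples
    if n == target_len:
        return rec.replace()
    if n > target_len:
        out = rec.signal[:, :target_len].copy()
    else:
        out = np.pad(rec.signal, ((0, 0), (0, target_len - n)))
    return rec.replace(signal=out)


def stft(rec: Recording, cfg: STFTConfig | None = None) -> SpectrogramTensor:
    """Short-time Fourier transform of every channel.

    Frame f, bin k holds the DFT of the f-th windowed segment; real input, so
    only the ``window_len//2 + 1`` non-negative frequency bins are kept.
    """
    cfg = cfg or STFTConfig()
    n = rec.n_samples
    if cfg.window_len > n:
        raise InvalidSpecError(
            f"window_len={cfg.window_len} exceeds signal length {n}"
        )
    w = cfg.window()
    n_frames = (n - cfg.window_len) // cfg.hop + 1
    starts = np.arange(n_frames) * cfg.hop
    # frames: (n_channels, n_frames, window_len)
    idx = starts[:, None] + np.arange(cfg.window_len)[None, :]
    frames = rec.signal[:, idx] * w[None, None, :]
    spec = np.fft.rfft(frames, axis=2)  # (n_channels, n_frames, n_bins)
    spec = np.transpose(spec, (0, 2, 1))
    values = np.abs(spec) if cfg.output_mode == "magnitude" else spec
    freq_axis = np.fft.rfftfreq(cfg.window_len, d=1.0 / rec.fs)
    time_axis = (starts + cfg.window_len / 2) / rec.fs
    return SpectrogramTensor(
        values=values,
        freq_axis=freq_axis,
        time_axis=time_axis,
        meta={"fs": rec.fs, "stft": cfg, "record_id": rec.record_id},
    )


def preprocess_pipeline(
    rec: Recording,
    filter_spec: FilterSpec | None = None,
    stft_cfg: STFTConfig | None = None,
    target_fs: float = 500.0,
    target_len: int = TARGET_LEN_DEFAULT,
) -> SpectrogramTensor:
    """Full deterministic chain: band-pass -> resample -> fixed length -> STFT.

    Recordings with missing readings are rejected up front.
    """
    rec.require_finite()
    out = bandpass_filter(rec, filter_spec)
    out = resample(out, target_fs)
    out = normalize_length(out, target_len)
    return stft(out, stft_cfg)
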