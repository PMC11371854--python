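"""End-to-end classifier: ConvLSTM feature extractor -> NCP liquid network.

The spectrogram tensor is consumed as a sequence of STFT frames: the 12
leads are the convolution input channels, the frequency bins form the
spatial axis, and time frames drive the recurrence. A single ConvLSTM layer
extracts per-frame features which are averaged within a few frequency bands,
densely projected onto 75 sensory neurons (tanh-bounded), and fed to the
sparse NCP network built from LTC or CfC cells. The final motor-neuron state
passes through a sigmoid, yielding six independent abnormality scores —
multi-label by construction (no softmax anywhere).

The two variants, CLTC (LTC cell) and CCfC (CfC cell), share every other
component bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .cells import CfCCell, LTCCell
from .preprocess import SpectrogramTensor
from .recording import N_CLASSES
from .wiring import WiringConfig, build_wiring

VARIANTS = ("cltc", "ccfc")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the classifier.

    ``max_freq_hz`` crops the spectrogram to the band the band-pass filter
    actually passes before the ConvLSTM sees it; ``pool_bands`` controls how
    many frequency bands are averaged into the per-frame feature vector.
    """

    variant: str = "cltc"
    conv_filters: int = 8
    kernel_size: int = 3
    pool_bands: int = 13
    forget_bias: float = 2.0
    max_freq_hz: float | None = 50.0
    n_sensory: int = 75
    wiring: WiringConfig = field(default_factory=WiringConfig)
    n_classes: int = N_CLASSES
    delta: float = 0.25
    n_unfold: int = 2
    input_transform: str = "log1p"  # or "none"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.wiring.n_motor != self.n_classes:
            raise ValueError(
                f"wiring has {self.wiring.n_motor} motor neurons but the model "
                f"needs {self.n_classes} output classes"
            )
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding convolution)")
        if self.input_transform not in ("log1p", "none"):
            raise ValueError(f"unknown input_transform {self.input_transform!r}")


class ECGClassifier:
    """CLTC/CCfC classifier over preprocessed spectrogram tensors.

    Deterministic given (config, seed): the wiring graph is drawn from the
    wiring config's own seed, parameter initialization from ``seed``.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        dtype = np.dtype(config.dtype).type
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        nf, k, cin = config.conv_filters, config.kernel_size, 12

        def t(a):
            return Tensor(np.asarray(a, dtype=dtype), requires_grad=True)

        # ConvLSTM gate convolutions (i, f, o, g stacked along the last axis)
        sx = 1.0 / np.sqrt(k * cin)
        sh = 1.0 / np.sqrt(k * nf)
        self.Wx = t(rng.normal(0.0, sx, size=(k, cin, 4 * nf)))
        self.Wh = t(rng.normal(0.0, sh, size=(k, nf, 4 * nf)))
        b = np.zeros(4 * nf)
        b[nf : 2 * nf] = config.forget_bias  # forget-gate bias: remember by default
        self.b = t(b)

        # dense projection of band-pooled features onto the sensory neurons
        n_feat = config.pool_bands * nf
        self.Wd = t(rng.normal(0.0, 1.0 / np.sqrt(n_feat), size=(n_feat, config.n_sensory)))
        self.bd = t(np.zeros(config.n_sensory))

        self.wiring_graph = build_wiring(config.wiring)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        if config.variant == "cltc":
            self.cell = LTCCell(
                self.wiring_graph, seed=cell_seed, delta=config.delta,
                n_unfold=config.n_unfold, dtype=dtype,
            )
        else:
            self.cell = CfCCell(self.wiring_graph, seed=cell_seed, delta=config.delta, dtype=dtype)

    # -- parameter bookkeeping ------------------------------------------------

    def parameters(self) -> list[Tensor]:
        return [self.Wx, self.Wh, self.b, self.Wd, self.bd] + self.cell.parameters()

    def named_parameters(self) -> dict[str, Tensor]:
        names = ["conv.Wx", "conv.Wh", "conv.b", "dense.W", "dense.b"]
        cell_names = {
            "cltc": ["cell.raw_cm", "cell.raw_gl", "cell.x_leak", "cell.raw_w", "cell.gamma", "cell.mu"],
            "ccfc": ["cell.Wf", "cell.bf", "cell.Wg", "cell.bg", "cell.Wh", "cell.bh"],
        }[self.config.variant]
        return dict(zip(names + cell_names, self.parameters()))

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    @property
    def n_ncp_neurons(self) -> int:
        return self.wiring_graph.n_hidden

    # -- input mapping --------------------------------------------------------

    def prepare_input(self, spect: SpectrogramTensor) -> np.ndarray:
        """Map a spectrogram tensor to the (n_channels, n_bins, n_frames)
        array the network consumes: crop to ``max_freq_hz`` and compress
        magnitudes with log1p."""
        v = np.abs(spect.values)
        if self.config.max_freq_hz is not None:
            keep = spect.freq_axis <= self.config.max_freq_hz
            v = v[:, keep, :]
        if self.config.input_transform == "log1p":
            v = np.log1p(v)
        return np.ascontiguousarray(v, dtype=self.dtype)

    # -- forward pass ---------------------------------------------------------

    def _conv(self, v: Tensor, w: Tensor) -> Tensor:
        """Same-padded 1-D convolution over the frequency axis.

        v: (B, F, C_in), w: (K, C_in, C_out) -> (B, F, C_out)."""
        k = w.shape[0]
        pad = k // 2
        f = v.shape[1]
        vp = ad.pad_axis(v, 1, pad, pad)
        out = vp[:, 0:f, :] @ w[0]
        for d in range(1, k):
            out = out + vp[:, d : d + f, :] @ w[d]
        return out

    def forward_batch(self, x: np.ndarray) -> Tensor:
        """Scores for a batch of prepared inputs (B, 12, n_bins, n_frames)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != 12:
            raise ValueError(f"expected (batch, 12, n_bins, n_frames), got {x.shape}")
        bsz, _, n_bins, n_frames = x.shape
        nf = self.config.conv_filters
        # (T*B, F, C) frame-major layout: the input-to-gate convolution does
        # not depend on the recurrent state, so it is applied to every frame
        # in one shot
        seq = np.ascontiguousarray(np.transpose(x, (3, 0, 2, 1))).reshape(
            n_frames * bsz, n_bins, 12
        )
        if self.config.pool_bands > n_bins:
            raise ValueError(
                f"pool_bands={self.config.pool_bands} exceeds the {n_bins} "
                "frequency bins of the prepared input"
            )
        zx_all = self._conv(Tensor(seq), self.Wx) + self.b
        edges = np.linspace(0, n_bins, self.config.pool_bands + 1).astype(int)

        h = Tensor(np.zeros((bsz, n_bins, nf), dtype=self.dtype))
        c = Tensor(np.zeros((bsz, n_bins, nf), dtype=self.dtype))
        hs = []
        for k in range(n_frames):
            z = zx_all[k * bsz : (k + 1) * bsz] + self._conv(h, self.Wh)
            i = ad.sigmoid(z[:, :, 0:nf])
            f = ad.sigmoid(z[:, :, nf : 2 * nf])
            o = ad.sigmoid(z[:, :, 2 * nf : 3 * nf])
            g = ad.tanh(z[:, :, 3 * nf : 4 * nf])
            c = f * c + i * g
            h = o * ad.tanh(c)
            hs.append(h)

        # per-frame features: average within frequency bands, then a dense
        # tanh projection onto the sensory neurons (one matmul for all frames)
        h_all = ad.concat(hs, axis=0)  # (T*B, F, nf)
        bands = [h_all[:, lo:hi, :].mean(axis=1) for lo, hi in zip(edges[:-1], edges[1:])]
        feats = ad.concat(bands, axis=1)  # (T*B, pool_bands * nf)
        sensory_all = ad.tanh(feats @ self.Wd + self.bd)

        state = Tensor(np.zeros((bsz, self.cell.n_hidden), dtype=self.dtype))
        for k in range(n_frames):
            state = self.cell.frame_step(
                state, sensory_all[k * bsz : (k + 1) * bsz], frame_index=k
            )
        motor = state[:, self.cell.n_hidden - self.cell.n_motor :]
        return ad.sigmoid(motor)

    def predict_batch(self, x: np.ndarray) -> np.ndarray:
        """Inference-only scores, no autodiff graph."""
        with ad.no_grad():
            return self.forward_batch(x).data

    def predict(self, spect: SpectrogramTensor) -> np.ndarray:
        """Six class scores in (0,1) for a single spectrogram tensor."""
        return self.predict_batch(self.prepare_input(spect)[None])[0]


def build_model(config: ModelConfig | None = None, seed: int = 0) -> ECGClassifier:
    """Construct a seeded CLTC or CCfC classifier."""
    return ECGClassifier(config or ModelConfig(), seed=seed)


def forward(model: ECGClassifier, spect: SpectrogramTensor) -> np.ndarray:
    """Prediction scores for one spectrogram tensor (six values in (0,1))."""
    return model.predict(spect)
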