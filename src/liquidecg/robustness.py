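"""Perturbation harness: white-noise injection and channel blanking.

Perturbations are applied to the raw recording before preprocessing (they
emulate acquisition-time disturbance), never in place. The three protocols
are: per-channel white noise of a given standard deviation, blanking of
single channels, and progressive random blanking of 1..6 of the 12 leads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import EvalReport, evaluate_scores
from .preprocess import PreprocessConfig
from .recording import Recording
from .train import score_records


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation condition: noise or blanking on a channel set."""

    kind: str  # "noise" | "blank"
    channels: tuple[int, ...]
    noise_std: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("noise", "blank"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if any(c < 0 or c >= 12 for c in self.channels):
            raise ValueError(f"channel indices must lie in [0,12), got {self.channels}")


@dataclass
class RobustnessCurve:
    """Per-condition evaluation reports plus the seeds that produced them."""

    protocol: str
    conditions: list[dict] = field(default_factory=list)

    def add(self, condition, report: EvalReport, **extra) -> None:
        self.conditions.append({"condition": condition, "report": report, **extra})

    def macro_f1(self) -> list[float]:
        return [c["report"].macro_f1 for c in self.conditions]

    def macro_auroc(self) -> list[float]:
        return [c["report"].macro_auroc for c in self.conditions]

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "conditions": [
                {
                    **{k: v for k, v in c.items() if k != "report"},
                    "report": c["report"].to_dict(),
                }
                for c in self.conditions
            ],
        }


def add_white_noise(
    rec: Recording, channels, std: float, seed: int = 0
) -> Recording:
    """Add i.i.d. zero-mean Gaussian noise of the given std to the listed
    channels; other channels are bit-identical. Deterministic under seed."""
    if std < 0:
        raise ValueError("std must be >= 0")
    channels = _check_channels(rec, channels)
    out = rec.replace()
    if std == 0 or not channels:
        return out
    rng = np.random.default_rng(seed)
    for ch in channels:
        out.signal[ch] += rng.normal(0.0, std, size=rec.n_samples)
    return out


def blank_channels(rec: Recording, channels) -> Recording:
    """Zero out the listed channels; idempotent, never mutates the input."""
    channels = _check_channels(rec, channels)
    out = rec.replace()
    for ch in channels:
        out.signal[ch] = 0.0
    return out


def _check_channels(rec: Recording, channels) -> list[int]:
    channels = [int(c) for c in np.atleast_1d(np.asarray(channels, dtype=int))] if np.size(channels) else []
    for c in channels:
        if c < 0 or c >= rec.n_channels:
            raise ValueError(f"channel index {c} out of range [0,{rec.n_channels})")
    return channels


def _evaluate_perturbed(
    model, records, perturb, threshold: float, preprocess_cfg, batch_size: int
) -> EvalReport:
    perturbed = [perturb(r) for r in records]
    scores, labels = score_records(model, perturbed, preprocess_cfg, batch_size)
    return evaluate_scores(scores, labels, threshold)


def noise_sweep(
    model,
    records: list[Recording],
    std: float = 0.1,
    seed: int = 0,
    threshold: float = 0.5,
    preprocess_cfg: PreprocessConfig | None = None,
    batch_size: int = 64,
) -> RobustnessCurve:
    """One condition per channel 0..11: noise that channel on every record."""
    curve = RobustnessCurve(protocol="white_noise")
    rng = np.random.default_rng(seed)
    for ch in range(12):
        ch_seed = int(rng.integers(0, 2**31 - 1))
        report = _evaluate_perturbed(
            model,
            records,
            lambda r: add_white_noise(r, [ch], std, seed=ch_seed),
            threshold,
            preprocess_cfg,
            batch_size,
        )
        curve.add({"channel": ch, "noise_std": std}, report, seed=ch_seed)
    return curve


def blanking_sweep(
    model,
    records: list[Recording],
    threshold: float = 0.5,
    preprocess_cfg: PreprocessConfig | None = None,
    batch_size: int = 64,
) -> RobustnessCurve:
    """One condition per channel 0..11: blank that channel on every record."""
    curve = RobustnessCurve(protocol="single_channel_blanking")
    for ch in range(12):
        report = _evaluate_perturbed(
            model, records, lambda r: blank_channels(r, [ch]),
            threshold, preprocess_cfg, batch_size,
        )
        curve.add({"channel": ch}, report)
    return curve


def progressive_blanking_sweep(
    model,
    records: list[Recording],
    k_range=range(1, 7),
    n_draws: int = 20,
    seed: int = 0,
    threshold: float = 0.5,
    preprocess_cfg: PreprocessConfig | None = None,
    batch_size: int = 64,
) -> RobustnessCurve:
    """Blank k random leads (k = 1..6 by default), aggregating macro F1/AUROC
    over ``n_draws`` random k-subsets per condition. k = 0 acts as an
    unperturbed control."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    curve = RobustnessCurve(protocol="progressive_blanking")
    rng = np.random.default_rng(seed)
    for k in k_range:
        if k > 12:
            raise ValueError(f"cannot blank {k} of 12 channels")
        f1s, aurocs, draws = [], [], []
        for _ in range(max(1, n_draws) if k > 0 else 1):
            subset = sorted(rng.choice(12, size=k, replace=False).tolist()) if k else []
            report = _evaluate_perturbed(
                model, records, lambda r: blank_channels(r, subset),
                threshold, preprocess_cfg, batch_size,
            )
            f1s.append(report.macro_f1)
            aurocs.append(report.macro_auroc)
            draws.append({"channels": subset, "report": report})
        curve.add(
            {"k": int(k), "n_draws": len(draws)},
            draws[-1]["report"],
            mean_macro_f1=float(np.mean(f1s)),
            mean_macro_auroc=float(np.mean(aurocs)),
            draws=[d["channels"] for d in draws],
            seed=seed,
        )
    return curve
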