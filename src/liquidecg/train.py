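"""Training protocol: stratified 80/20 split, positive-instance duplication,
Adam on mean binary cross-entropy over the six labels.

Class imbalance in multi-label ECG sets is handled by duplicating every
training instance carrying at least one positive label ``factor`` extra
times (default 2, i.e. positives appear three times); the validation
partition is never touched. The optimizer runs a fixed schedule — no early
stopping, no learning-rate decay.
"""

from __future__ import annotations

import gc

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, log, no_grad
from .model import ECGClassifier
from .preprocess import PreprocessConfig
from .recording import Recording

BCE_EPS = 1e-7


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    epochs: int = 300
    learning_rate: float = 0.01
    positive_duplication_factor: int = 2
    validation_fraction: float = 0.2
    seed: int = 0


@dataclass
class TrainLog:
    """Per-epoch loss and per-label binary accuracy (threshold 0.5)."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_dict(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss,
            "val_accuracy": self.val_accuracy,
        }


# -- dataset handling ---------------------------------------------------------


def split_dataset(
    records: list[Recording],
    fraction: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[list[Recording], list[Recording]]:
    """Disjoint train/validation split, stratified by the any-positive flag."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"validation fraction must be in (0,1), got {fraction}")
    if len(records) < 5:
        raise ValueError("need at least 5 records to split")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(records))
    if stratify:
        flags = np.array(
            [0 if r.labels is None else int(r.labels.any()) for r in records]
        )
        groups = [idx[flags == v] for v in np.unique(flags)]
    else:
        groups = [idx]
    val_idx: list[int] = []
    for g in groups:
        g = rng.permutation(g)
        n_val = int(round(len(g) * fraction))
        val_idx.extend(g[:n_val].tolist())
    val_set = set(val_idx)
    train = [records[i] for i in idx if i not in val_set]
    val = [records[i] for i in sorted(val_set)]
    return train, val


def duplicate_positives(
    records: list[Recording], factor: int = 2, seed: int | None = None
) -> list[Recording]:
    """Append ``factor`` extra copies of every record with >= 1 positive label.

    All-negative records appear once. With a seed the result is shuffled.
    """
    if factor < 0 or int(factor) != factor:
        raise ValueError("duplication factor must be a non-negative integer")
    out = list(records)
    for r in records:
        if r.labels is not None and r.labels.any():
            out.extend([r] * int(factor))
    if seed is not None:
        rng = np.random.default_rng(seed)
        out = [out[i] for i in rng.permutation(len(out))]
    return out


def stack_inputs(
    model: ECGClassifier,
    records: list[Recording],
    preprocess_cfg: PreprocessConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess records once and stack model inputs and labels."""
    cfg = preprocess_cfg or PreprocessConfig()
    xs, ys = [], []
    for r in records:
        xs.append(model.prepare_input(cfg.apply(r)))
        ys.append(r.labels if r.labels is not None else np.zeros(6, dtype=int))
    return np.stack(xs), np.stack(ys).astype(float)


def score_records(
    model: ECGClassifier,
    records: list[Recording],
    preprocess_cfg: PreprocessConfig | None = None,
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Model scores and labels for a list of recordings."""
    x, y = stack_inputs(model, records, preprocess_cfg)
    scores = np.concatenate(
        [model.predict_batch(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    )
    return scores, y.astype(int)


# -- optimization -------------------------------------------------------------


class Adam:
    """Adam with bias correction, operating on a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def bce_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over batch and classes, scores clipped away
    from {0,1} by 1e-7."""
    y = np.asarray(target, dtype=pred.data.dtype)
    p = pred.clip(BCE_EPS, 1.0 - BCE_EPS)
    return -(Tensor(y) * log(p) + Tensor(1.0 - y) * log(1.0 - p)).mean()


def _binary_accuracy(scores: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> float:
    return float(np.mean((scores >= threshold).astype(int) == y.astype(int)))


def train_model(
    model: ECGClassifier,
    train_records: list[Recording],
    val_records: list[Recording],
    cfg: TrainConfig | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
    verbose: bool = False,
) -> tuple[ECGClassifier, TrainLog]:
    """Train in place; returns (model, per-epoch TrainLog).

    Recordings are preprocessed once up front; positive duplication is
    applied to training indices only, so validation records are untouched.
    """
    cfg = cfg or TrainConfig()
    if not train_records or not val_records:
        raise ValueError("training and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    x_train, y_train = stack_inputs(model, train_records, preprocess_cfg)
    x_val, y_val = stack_inputs(model, val_records, preprocess_cfg)

    # duplication by index: positives appear 1 + factor times
    pos = y_train.any(axis=1)
    index = np.concatenate(
        [np.arange(len(x_train))]
        + [np.flatnonzero(pos)] * int(cfg.positive_duplication_factor)
    )

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    log_out = TrainLog()
    # the autodiff graph is acyclic and reference-counted; generational GC
    # scans over its many small nodes only add pauses during the hot loop
    gc_was_enabled = gc.isenabled()
    gc.disable()
    try:
        _run_epochs(model, opt, cfg, x_train, y_train, x_val, y_val, index, rng, log_out, verbose)
    finally:
        if gc_was_enabled:
            gc.enable()
        gc.collect()
    return model, log_out


def _run_epochs(model, opt, cfg, x_train, y_train, x_val, y_val, index, rng, log_out, verbose):
    for epoch in range(cfg.epochs):
        order = rng.permutation(index)
        losses, accs = [], []
        for lo in range(0, len(order), cfg.batch_size):
            batch = order[lo : lo + cfg.batch_size]
            opt.zero_grad()
            pred = model.forward_batch(x_train[batch])
            loss = bce_loss(pred, y_train[batch])
            if not np.isfinite(loss.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch {lo // cfg.batch_size}"
                )
            loss.backward()
            opt.step()
            losses.append(loss.item())
            accs.append(_binary_accuracy(pred.data, y_train[batch]))
        with no_grad():
            val_pred = np.concatenate(
                [
                    model.forward_batch(x_val[i : i + cfg.batch_size]).data
                    for i in range(0, len(x_val), cfg.batch_size)
                ]
            )
        vp = np.clip(val_pred, BCE_EPS, 1 - BCE_EPS)
        v_loss = float(np.mean(-(y_val * np.log(vp) + (1 - y_val) * np.log(1 - vp))))
        log_out.train_loss.append(float(np.mean(losses)))
        log_out.train_accuracy.append(float(np.mean(accs)))
        log_out.val_loss.append(v_loss)
        log_out.val_accuracy.append(_binary_accuracy(val_pred, y_val))
        if verbose:
            print(
                f"epoch {epoch + 1}/{cfg.epochs}: "
                f"loss {log_out.train_loss[-1]:.4f} acc {log_out.train_accuracy[-1]:.3f} "
                f"val_loss {v_loss:.4f} val_acc {log_out.val_accuracy[-1]:.3f}"
            )
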