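"""Core domain containers: the 12-lead ECG recording and its label space."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The six abnormality classes, in the fixed label order used everywhere:
#: first-degree AV block, right/left bundle branch block, sinus bradycardia,
#: atrial fibrillation, sinus tachycardia.
CLASSES: tuple[str, ...] = ("1dAVb", "RBBB", "LBBB", "SB", "AF", "ST")

#: Standard 12-lead order; readers canonicalize to this sequence.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

N_CLASSES = len(CLASSES)
N_LEADS = len(LEAD_NAMES)


class InvalidInputError(ValueError):
    """A recording violates an input contract (missing values, bad shape)."""


class InvalidSpecError(ValueError):
    """A processing configuration is inconsistent with the data."""


@dataclass
class Recording:
    """A multichannel ECG trace in millivolts.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        One row per lead, in the standard 12-lead order for pipeline use.
    fs : float
        Sampling rate in Hz.
    labels : ndarray of {0,1}, shape (6,), optional
        Multi-label annotation over :data:`CLASSES`.
    record_id : str
        Opaque identifier carried through the pipeline.
    """

    signal: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    record_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise InvalidInputError(
                f"signal must be 2-D [n_channels x n_samples], got shape {self.signal.shape}"
            )
        if not self.fs > 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (N_CLASSES,):
                raise InvalidInputError(
                    f"labels must be a {N_CLASSES}-vector, got shape {self.labels.shape}"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise InvalidInputError("labels must be binary")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def require_finite(self) -> None:
        """Reject recordings with missing/non-finite readings."""
        if not np.isfinite(self.signal).all():
            raise InvalidInputError(
                f"recording {self.record_id!r} contains missing or non-finite readings"
            )

    def replace(self, **changes) -> "Recording":
        """Return a copy with the given fields replaced (signal is copied)."""
        fields = dict(
            signal=self.signal.copy(),
            fs=self.fs,
            labels=None if self.labels is None else self.labels.copy(),
            record_id=self.record_id,
            meta=dict(self.meta),
        )
        fields.update(changes)
        return Recording(**fields)
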