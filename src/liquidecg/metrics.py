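"""Multi-label evaluation: per-class and macro precision, recall, F1, AUROC.

Precision = TP/(TP+FP), Recall = TP/(TP+FN) and F1 is their harmonic mean.
Zero-denominator cases are reported as 0 together with an ``undefined`` flag
so they can be identified rather than silently propagating NaNs into macro
averages. AUROC is the Mann-Whitney probability that a random positive
outscores a random negative (ties counted half) and is undefined when only
one label value is present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .recording import CLASSES


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    auroc: float | None
    precision_defined: bool = True
    recall_defined: bool = True

    @property
    def defined(self) -> bool:
        return self.auroc is not None


@dataclass
class EvalReport:
    """Per-class and macro metrics for one labeled evaluation set.

    Macro values are unweighted means over the classes for which the metric
    is defined (classes with a single label value are flagged undefined).
    """

    per_class: dict[str, ClassMetrics]
    threshold: float
    n_records: int
    meta: dict = field(default_factory=dict)

    def _macro(self, attr: str) -> float:
        vals = [
            getattr(m, attr)
            for m in self.per_class.values()
            if getattr(m, attr) is not None
        ]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def macro_precision(self) -> float:
        return self._macro("precision")

    @property
    def macro_recall(self) -> float:
        return self._macro("recall")

    @property
    def macro_f1(self) -> float:
        return self._macro("f1")

    @property
    def macro_auroc(self) -> float:
        return self._macro("auroc")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_records": self.n_records,
            "per_class": {
                name: {
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "auroc": m.auroc,
                    "precision_defined": m.precision_defined,
                    "recall_defined": m.recall_defined,
                }
                for name, m in self.per_class.items()
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
                "auroc": self.macro_auroc,
            },
        }


def report_schema() -> dict:
    """The bundled JSON schema the serialized EvalReport conforms to."""
    import json
    from importlib import resources

    with resources.files("liquidecg.schemas").joinpath(
        "eval_report.schema.json"
    ).open() as f:
        return json.load(f)


def validate_report_dict(d: dict) -> list[str]:
    """Structural validation of a serialized report against the bundled
    schema (implemented directly; returns human-readable violations)."""
    errors: list[str] = []
    for key in ("threshold", "n_records", "per_class", "macro"):
        if key not in d:
            errors.append(f"missing key {key!r}")
    if errors:
        return errors
    if not (isinstance(d["threshold"], (int, float)) and 0 < d["threshold"] < 1):
        errors.append("threshold must be a number in (0,1)")
    if not (isinstance(d["n_records"], int) and d["n_records"] >= 1):
        errors.append("n_records must be a positive integer")
    for name, m in d["per_class"].items():
        for field_name in ("precision", "recall", "f1", "auroc"):
            if field_name not in m:
                errors.append(f"class {name}: missing {field_name}")
                continue
            v = m[field_name]
            if v is None and field_name == "auroc":
                continue
            if not (isinstance(v, (int, float)) and 0 <= v <= 1):
                errors.append(f"class {name}: {field_name} out of [0,1]")
    for field_name in ("precision", "recall", "f1", "auroc"):
        if field_name not in d["macro"]:
            errors.append(f"macro: missing {field_name}")
    return errors


def binarize(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold scores into hard labels; a score equal to the threshold is
    called positive."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    return (np.asarray(scores) >= threshold).astype(int)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
    )


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); zero-denominator cases yield 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else 0.0
    f1 = f1_score(p, r)
    return p, r, f1


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean 2 P R / (P + R); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Mann-Whitney AUROC; None (undefined) when only one class is present."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    class_names: tuple[str, ...] = CLASSES,
) -> EvalReport:
    """Report from a (n_records, n_classes) score matrix and label matrix."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.ndim != 2 or scores.shape != labels.shape:
        raise ValueError(f"scores {scores.shape} and labels {labels.shape} must match")
    if scores.shape[0] == 0:
        raise ValueError("cannot evaluate an empty record set")
    preds = binarize(scores, threshold)
    per_class: dict[str, ClassMetrics] = {}
    for j, name in enumerate(class_names):
        counts = confusion_counts(labels[:, j], preds[:, j])
        p, r, f1 = precision_recall_f1(counts)
        per_class[name] = ClassMetrics(
            precision=p,
            recall=r,
            f1=f1,
            auroc=auroc(scores[:, j], labels[:, j]),
            precision_defined=counts.tp + counts.fp > 0,
            recall_defined=counts.tp + counts.fn > 0,
        )
    return EvalReport(per_class=per_class, threshold=threshold, n_records=scores.shape[0])


def evaluate(model, records, threshold: float = 0.5, batch_size: int = 64) -> EvalReport:
    """Preprocess, score and evaluate a list of labeled recordings."""
    from .train import score_records  # local import: avoids a module cycle

    scores, labels = score_records(model, records, batch_size=batch_size)
    report = evaluate_scores(scores, labels, threshold)
    report.meta["n_records"] = len(records)
    return report
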