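"""Evaluation mathematics: one-vs-rest confusion statistics, inception score,
and class-coverage diagnostics for conditional generators.

A multiclass confusion matrix (rows = true labels, columns = predicted)
is reduced per class to binary TP/FP/FN/TN counts, from which
sensitivity (recall), specificity, precision, and F1 are computed.
"Average accuracy" is the micro form trace/total, reported as a
percentage.  F1 is the harmonic mean of precision and recall.

The inception score of a generated set is exp of the mean KL divergence
between per-image predictive class distributions p(y|x) and their
marginal p(y); any calibrated classifier can play the scorer role.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "InceptionScoreResult",
    "one_vs_rest",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "f1_score",
    "report",
    "format_percent",
    "inception_score",
    "class_coverage",
]


class DegenerateRateWarning(UserWarning):
    """Raised when a rate's denominator is zero (rate reported as 0)."""


@dataclass
class ConfusionMatrix:
    """C x C count matrix; rows are true labels, columns predictions."""

    counts: np.ndarray
    class_names: Sequence[str] = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if not self.class_names:
            self.class_names = tuple(f"class_{i}" for i in range(self.counts.shape[0]))
        elif len(self.class_names) != self.counts.shape[0]:
            raise ValueError("class_names length must match matrix size")

    @classmethod
    def from_labels(cls, y_true, y_pred, class_names: Sequence[str]) -> "ConfusionMatrix":
        c = len(class_names)
        counts = np.zeros((c, c), dtype=np.int64)
        for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
            counts[int(t), int(p)] += 1
        return cls(counts, tuple(class_names))

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        names = list(self.class_names)
        lines = ["true\\pred," + ",".join(names)]
        for name, row in zip(names, self.counts):
            lines.append(name + "," + ",".join(str(int(v)) for v in row))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def one_vs_rest(cm: ConfusionMatrix, class_index: int):
    """Reduce to (TP, FP, FN, TN) for one class against the rest."""
    c = cm.n_classes
    if not 0 <= class_index < c:
        raise IndexError(f"class index {class_index} out of range for {c} classes")
    m = cm.counts
    tp = int(m[class_index, class_index])
    fn = int(m[class_index].sum()) - tp
    fp = int(m[:, class_index].sum()) - tp
    tn = cm.total - tp - fp - fn
    return tp, fp, fn, tn


def _rate(num: int, den: int, name: str) -> float:
    if num < 0 or den < num:
        raise ValueError(f"negative counts passed to {name}")
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", DegenerateRateWarning)
        return 0.0
    return num / den


def sensitivity(tp: int, fn: int) -> float:
    """Recall, TP / (TP + FN)."""
    if tp < 0 or fn < 0:
        raise ValueError("negative counts")
    return _rate(tp, tp + fn, "sensitivity")


def specificity(tn: int, fp: int) -> float:
    """TN / (TN + FP)."""
    if tn < 0 or fp < 0:
        raise ValueError("negative counts")
    return _rate(tn, tn + fp, "specificity")


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP)."""
    if tp < 0 or fp < 0:
        raise ValueError("negative counts")
    return _rate(tp, tp + fp, "precision")


def accuracy(cm: ConfusionMatrix) -> float:
    """Micro average accuracy, trace/total, as a percentage in [0, 100]."""
    total = cm.total
    if total == 0:
        warnings.warn("accuracy: empty confusion matrix, reporting 0", DegenerateRateWarning)
        return 0.0
    return float(np.trace(cm.counts)) / total * 100.0


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError(f"precision/recall must be in [0,1], got {p}, {r}")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def format_percent(value: float, decimals: int = 2) -> str:
    """Truncate (not round) a percentage for display, e.g. 72.6384 -> '72.63'."""
    scale = 10 ** decimals
    return f"{np.floor(value * scale) / scale:.{decimals}f}"


@dataclass
class MetricsReport:
    """Per-class one-vs-rest statistics plus micro average accuracy."""

    class_names: Sequence[str]
    per_class: list            # dicts: tp/fp/fn/tn, recall, specificity, precision, f1
    average_accuracy: float    # percent
    degenerate: bool = False
    confusion: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "per_class": self.per_class,
            "average_accuracy_percent": self.average_accuracy,
            "degenerate": self.degenerate,
            "confusion": None if self.confusion is None else self.confusion.tolist(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_csv(self, path) -> None:
        header = "class,tp,fp,fn,tn,recall,specificity,precision,f1"
        lines = [header]
        for name, row in zip(self.class_names, self.per_class):
            lines.append(
                f"{name},{row['tp']},{row['fp']},{row['fn']},{row['tn']},"
                f"{row['recall']:.7f},{row['specificity']:.7f},"
                f"{row['precision']:.7f},{row['f1']:.7f}"
            )
        lines.append(f"average_accuracy_percent,{self.average_accuracy:.4f}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def report(cm: ConfusionMatrix) -> MetricsReport:
    """Assemble recall/specificity/precision/F1 per class + average accuracy."""
    rows = []
    degenerate = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DegenerateRateWarning)
        for i in range(cm.n_classes):
            tp, fp, fn, tn = one_vs_rest(cm, i)
            r = sensitivity(tp, fn)
            s = specificity(tn, fp)
            p = precision(tp, fp)
            rows.append({
                "tp": tp, "fp": fp, "fn": fn, "tn": tn,
                "recall": r, "specificity": s, "precision": p,
                "f1": f1_score(p, r),
            })
        acc = accuracy(cm)
        degenerate = any(issubclass(w.category, DegenerateRateWarning) for w in caught)
    return MetricsReport(tuple(cm.class_names), rows, acc,
                         degenerate=degenerate, confusion=cm.counts.copy())


# ---------------------------------------------------------------------------
# generative-model diagnostics


@dataclass
class InceptionScoreResult:
    mean: float
    std: float
    n_splits: int


def inception_score(images: np.ndarray, scorer, n_splits: int = 10) -> InceptionScoreResult:
    """exp(mean KL(p(y|x) || p(y))) averaged over ``n_splits`` equal parts.

    ``scorer`` must expose ``predict_proba(images) -> (n, C)``.  The score
    lies in [1, C]: 1 when every predictive distribution equals the
    marginal, C when predictions are one-hot and uniformly spread.
    """
    images = np.asarray(images)
    n = images.shape[0]
    if n < n_splits:
        raise ValueError(f"need at least n_splits={n_splits} images, got {n}")
    probs = np.asarray(scorer.predict_proba(images), dtype=np.float64)
    probs = np.clip(probs, 1e-12, 1.0)
    probs /= probs.sum(axis=1, keepdims=True)
    scores = []
    for part in np.array_split(probs, n_splits):
        marginal = part.mean(axis=0, keepdims=True)
        kl = (part * (np.log(part) - np.log(marginal))).sum(axis=1)
        scores.append(float(np.exp(kl.mean())))
    return InceptionScoreResult(float(np.mean(scores)), float(np.std(scores)), n_splits)


def class_coverage(requested_labels: np.ndarray, images: np.ndarray, scorer,
                   n_classes: int = 3, threshold: float = 0.5) -> dict:
    """Label fidelity per requested class and overall class coverage.

    fidelity[c] = fraction of images requested as class ``c`` whose scorer
    argmax equals ``c``; coverage = (# classes with fidelity > threshold) / C.
    Diagnoses mode collapse: a collapsed conditional generator has high
    fidelity for some classes and ~0 for the missing ones.
    """
    requested_labels = np.asarray(requested_labels)
    images = np.asarray(images)
    if images.shape[0] == 0:
        raise ValueError("no images supplied")
    pred = np.argmax(scorer.predict_proba(images), axis=1)
    fidelity = {}
    for c in range(n_classes):
        sel = requested_labels == c
        fidelity[c] = float((pred[sel] == c).mean()) if sel.any() else float("nan")
    covered = sum(1 for c in range(n_classes)
                  if not np.isnan(fidelity[c]) and fidelity[c] > threshold)
    return {"fidelity": fidelity, "coverage": covered / n_classes}
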