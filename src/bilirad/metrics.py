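"""Confusion matrix and the full evaluation suite.

Every metric is one-vs-rest per class: when scoring the negative class,
only true negatives count as positives of the binary problem and the
positive/obscure labels together form its negatives, and likewise for the
other two classes. The suite covers per-class precision / recall
(sensitivity) / F1 with their n/N count pairs, AUROC (midrank
Mann-Whitney), AUPRC (step-wise average precision, no interpolation),
overall accuracy (trace / total) and Cohen's kappa for inter-annotator
agreement.

Display rounding follows radiology-report benchmarking convention:
percentages to 0.1, F1 to integer percent, areas to 0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, cohen_kappa_score, roc_auc_score

from .reports import LABELS, Label

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "confusion",
    "one_vs_rest_prf",
    "accuracy",
    "auroc",
    "auprc",
    "cohens_kappa",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts; rows = true class, columns = predicted class, in the
    fixed order (NEGATIVE, POSITIVE, OBSCURE)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("confusion matrix must be 3x3 nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _label_values(labels: Sequence[Label | int | str]) -> np.ndarray:
    out = []
    for l in labels:
        if isinstance(l, Label):
            out.append(l.value)
        elif isinstance(l, str):
            out.append(Label.from_string(l).value)
        else:
            out.append(int(l))
    return np.asarray(out, dtype=int)


def confusion(true_labels: Sequence, predicted_labels: Sequence) -> ConfusionMatrix:
    t = _label_values(true_labels)
    p = _label_values(predicted_labels)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts)


def one_vs_rest_prf(cm: ConfusionMatrix, cls: Label) -> tuple[float, float, float]:
    """Precision = TP/column-sum, recall = TP/row-sum, F1 harmonic mean;
    0/0 conventions resolve to 0."""
    i = cls.value
    tp = float(cm.counts[i, i])
    pred = float(cm.counts[:, i].sum())
    actual = float(cm.counts[i, :].sum())
    precision = tp / pred if pred > 0 else 0.0
    recall = tp / actual if actual > 0 else 0.0
    f1 = 2 * tp / (pred + actual) if (pred + actual) > 0 else 0.0
    return precision, recall, f1


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def auroc(scores: Sequence[float], positives: Sequence[int]) -> float:
    """Midrank Mann-Whitney AUROC: the probability a random positive
    outranks a random negative, ties counted one half."""
    y = np.asarray(positives, dtype=int)
    if y.min() == y.max():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], positives: Sequence[int]) -> float:
    """Average precision: sum over recall steps of precision at each
    threshold, no interpolation."""
    y = np.asarray(positives, dtype=int)
    if y.sum() == 0:
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """kappa = (p_o - p_e) / (1 - p_e) with p_e from marginal products.
    Two constant identical labelings (p_e = 1) define kappa = 1."""
    a = _label_values(labels_a)
    b = _label_values(labels_b)
    if len(a) != len(b):
        raise ValueError("length mismatch")
    if len(set(a)) == 1 and len(set(b)) == 1 and a[0] == b[0]:
        return 1.0  # degenerate: perfect agreement on a single class
    return float(cohen_kappa_score(a, b, labels=[0, 1, 2]))


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    tp: int
    predicted: int
    auroc: Optional[float] = None
    auprc: Optional[float] = None


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    confusion_matrix: ConfusionMatrix
    accuracy: float
    kappa: Optional[float] = None

    # -- display -----------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "confusion": self.confusion_matrix.counts.tolist(),
            "per_class": {
                name: {k: v for k, v in vars(m).items()} for name, m in self.per_class.items()
            },
        }

    def to_json(self, path: Optional[str | Path] = None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(s, encoding="utf-8")
        return s

    @classmethod
    def from_json(cls, s: str) -> "MetricsReport":
        d = json.loads(s)
        per_class = {k: ClassMetrics(**v) for k, v in d["per_class"].items()}
        return cls(
            per_class=per_class,
            confusion_matrix=ConfusionMatrix(np.asarray(d["confusion"])),
            accuracy=d["accuracy"],
            kappa=d.get("kappa"),
        )

    def to_markdown(self) -> str:
        """Markdown table with the conventional columns: Precision n/N (%),
        Recall n/N (%), F1 (%), AUROC, AUPRC."""
        lines = [
            "| Class | Precision, n/N (%) | Recall, n/N (%) | F1 score (%) | AUROC | AUPRC |",
            "|---|---|---|---|---|---|",
        ]
        for name, m in self.per_class.items():
            p = f"{m.tp}/{m.predicted} ({100 * m.precision:.1f})" if m.predicted else "0/0 (0.0)"
            r = f"{m.tp}/{m.support} ({100 * m.recall:.1f})" if m.support else "0/0 (0.0)"
            roc = f"{m.auroc:.2f}" if m.auroc is not None else "-"
            prc = f"{m.auprc:.2f}" if m.auprc is not None else "-"
            lines.append(f"| {name.capitalize()} | {p} | {r} | {round(100 * m.f1)} | {roc} | {prc} |")
        lines.append(f"\nAccuracy: {100 * self.accuracy:.2f}%")
        if self.kappa is not None:
            lines.append(f"Cohen's kappa: {self.kappa:.2f}")
        return "\n".join(lines)


def evaluate(
    predictions: Sequence,
    true_labels: Sequence[Label],
    kappa_labels: Optional[Sequence[Label]] = None,
) -> MetricsReport:
    """Assemble the full per-class + overall report.

    ``predictions`` may be AttentionPrediction objects (their probability
    vectors feed AUROC/AUPRC), bare labels (threshold metrics only), or a
    (labels, probability-matrix) tuple.
    """
    probs: Optional[np.ndarray] = None
    if isinstance(predictions, tuple) and len(predictions) == 2:
        pred_labels, probs = predictions
        probs = np.asarray(probs, dtype=float)
    elif predictions and hasattr(predictions[0], "probabilities"):
        probs = np.stack([p.probabilities for p in predictions])
        pred_labels = [p.predicted_label for p in predictions]
    else:
        pred_labels = list(predictions)
    if len(pred_labels) != len(true_labels):
        raise ValueError("predictions and true labels differ in length")

    cm = confusion(true_labels, pred_labels)
    y = _label_values(true_labels)
    per_class: dict[str, ClassMetrics] = {}
    for lab in LABELS:
        p, r, f1 = one_vs_rest_prf(cm, lab)
        i = lab.value
        roc = prc = None
        if probs is not None:
            binary = (y == i).astype(int)
            if 0 < binary.sum() < len(binary):
                roc = auroc(probs[:, i], binary)
                prc = auprc(probs[:, i], binary)
        per_class[lab.name.lower()] = ClassMetrics(
            precision=p, recall=r, f1=f1,
            support=int(cm.counts[i, :].sum()), tp=int(cm.counts[i, i]),
            predicted=int(cm.counts[:, i].sum()), auroc=roc, auprc=prc,
        )
    kappa = None
    if kappa_labels is not None:
        kappa = cohens_kappa(true_labels, kappa_labels)
    return MetricsReport(per_class=per_class, confusion_matrix=cm, accuracy=accuracy(cm), kappa=kappa)
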