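"""Confusion matrices, precision/recall/F1 with macro averages, ROC/AUC.

Per-class precision, recall and F1 are computed from the confusion matrix
(rows = true class, columns = predicted); macro averages are unweighted
means over classes with defined values.  A ``truncate2`` presentation option
floors values to two decimals, the convention used when quoting metric
tables.  ROC curves are one-vs-rest on per-class scores, AUC by the
trapezoidal rule over thresholds swept across the unique scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import sklearn.metrics

from .errors import ValidationError


def truncate2(x: float) -> float:
    """Floor to two decimals (0.9975 -> 0.99), the table convention."""
    return math.floor(x * 100.0 + 1e-9) / 100.0


def confusion_matrix(true_labels, pred_labels, class_order) -> np.ndarray:
    """Counts[i][j] = #(true == class_order[i], pred == class_order[j])."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValidationError("true and predicted label lists differ in length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        if t not in index:
            raise ValidationError(f"unknown true label {t!r}")
        if p not in index:
            raise ValidationError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return counts


def f1_score(precision: float, recall: float) -> float:
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_average(values) -> float:
    """Unweighted mean over per-class metric values (defined values only)."""
    vals = [v for v in values if v is not None]
    if not vals:
        return 0.0
    return float(np.mean(vals))


def prf(confusion: np.ndarray, class_order=None, report_truncate2: bool = False):
    """Per-class and macro precision/recall/F1 from a confusion matrix.

    Zero-denominator metrics are reported as 0 and listed under ``flags``.
    With ``report_truncate2`` every reported value is floored to two
    decimals after computation.
    """
    confusion = np.asarray(confusion)
    n_classes = confusion.shape[0]
    if n_classes < 2 or confusion.shape[1] != n_classes:
        raise ValidationError("confusion matrix must be square with >= 2 classes")
    if class_order is None:
        class_order = [str(i) for i in range(n_classes)]
    per_class: dict[str, dict[str, float]] = {}
    flags: list[str] = []
    for i, cls in enumerate(class_order):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        if tp + fp == 0:
            precision = 0.0
            flags.append(f"{cls}:precision_zero_denominator")
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall = 0.0
            flags.append(f"{cls}:recall_zero_denominator")
        else:
            recall = tp / (tp + fn)
        per_class[cls] = {
            "precision": precision,
            "recall": recall,
            "f1": f1_score(precision, recall),
        }
    macro = {
        metric: macro_average([per_class[c][metric] for c in class_order])
        for metric in ("precision", "recall", "f1")
    }
    if report_truncate2:
        per_class = {
            c: {m: truncate2(v) for m, v in d.items()} for c, d in per_class.items()
        }
        macro = {m: truncate2(v) for m, v in macro.items()}
    return {"per_class": per_class, "macro": macro, "flags": flags}


def roc_curve(true_binary, scores):
    """One-vs-rest ROC points and trapezoidal AUC.

    Thresholds sweep the unique scores in descending order with ties grouped;
    both classes must be present.
    """
    true_binary = np.asarray(true_binary, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(true_binary)) < 2:
        raise ValidationError("both classes must be present for a ROC curve")
    fpr, tpr, thresholds = sklearn.metrics.roc_curve(true_binary, scores)
    auc = float(sklearn.metrics.auc(fpr, tpr))
    return fpr, tpr, thresholds, auc


@dataclass
class EvaluationReport:
    """Confusion matrix plus derived metrics for one evaluation run."""

    class_order: list[str]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    accuracy: float
    roc: dict[str, dict] | None = None   # class -> {fpr, tpr, auc}
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        roc = None
        if self.roc is not None:
            roc = {
                c: {
                    "fpr": list(map(float, v["fpr"])),
                    "tpr": list(map(float, v["tpr"])),
                    "auc": (None if v["auc"] is None else float(v["auc"])),
                }
                for c, v in self.roc.items()
            }
        return {
            "class_order": list(self.class_order),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "macro": self.macro,
            "accuracy": self.accuracy,
            "roc": roc,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        roc = d.get("roc")
        if roc is not None:
            roc = {
                c: {"fpr": np.asarray(v["fpr"]), "tpr": np.asarray(v["tpr"]),
                    "auc": v["auc"]}
                for c, v in roc.items()
            }
        return cls(
            class_order=list(d["class_order"]),
            confusion=np.asarray(d["confusion"], dtype=int),
            per_class=d["per_class"],
            macro=d["macro"],
            accuracy=float(d["accuracy"]),
            roc=roc,
            flags=list(d.get("flags", [])),
        )


def make_report(true_labels, pred_labels, class_order,
                scores: np.ndarray | None = None) -> EvaluationReport:
    """Assemble a full report; ``scores`` is the (n, C) per-class score
    matrix (softmax outputs) enabling one-vs-rest ROC/AUC."""
    cm = confusion_matrix(true_labels, pred_labels, class_order)
    metrics = prf(cm, class_order)
    accuracy = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    roc: dict[str, dict] | None = None
    if scores is not None:
        true_labels = np.asarray(true_labels)
        roc = {}
        for i, cls in enumerate(class_order):
            binary = (true_labels == cls).astype(int)
            if len(np.unique(binary)) < 2:
                roc[cls] = {"fpr": np.empty(0), "tpr": np.empty(0), "auc": None}
                metrics["flags"].append(f"{cls}:roc_undefined_single_class")
                continue
            fpr, tpr, _, auc = roc_curve(binary, scores[:, i])
            roc[cls] = {"fpr": fpr, "tpr": tpr, "auc": auc}
    return EvaluationReport(
        class_order=list(class_order),
        confusion=cm,
        per_class=metrics["per_class"],
        macro=metrics["macro"],
        accuracy=accuracy,
        roc=roc,
        flags=metrics["flags"],
    )
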