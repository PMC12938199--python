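"""Evaluation metrics and network-prediction modes.

Six confusion-matrix metrics (sensitivity, specificity, precision,
F1-score, MCC, accuracy), threshold-free curves (ROC/AUC, PR/AUPR),
precision among the top-u scored pairs, and thresholded edge extraction
for interaction / non-interaction network prediction.

Any metric whose denominator is zero is reported as 0 and flagged as
degenerate rather than raising, so extreme-threshold sweeps never crash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (precision_recall_curve, roc_auc_score,
                             roc_curve)

from .io_formats import Pair


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricReport:
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    accuracy: float
    degenerate: set = field(default_factory=set)

    def as_dict(self) -> dict:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "precision": self.precision, "f1": self.f1, "mcc": self.mcc,
                "accuracy": self.accuracy}


def _safe_div(num: float, den: float, name: str, degenerate: set) -> float:
    if den == 0:
        degenerate.add(name)
        return 0.0
    return num / den


def confusion_metrics(counts: ConfusionCounts) -> MetricReport:
    """The six confusion-matrix metrics.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); F1 = 2·precision·sensitivity/(precision+sensitivity);
    MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN));
    accuracy = (TP+TN)/total.  Zero denominators yield 0 with a flag.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    deg: set = set()
    sens = _safe_div(tp, tp + fn, "sensitivity", deg)
    spec = _safe_div(tn, tn + fp, "specificity", deg)
    prec = _safe_div(tp, tp + fp, "precision", deg)
    f1 = _safe_div(2 * prec * sens, prec + sens, "f1", deg)
    mcc_den = math.sqrt(float(tp + fn) * (tn + fp) * (tp + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc", deg)
    acc = (tp + tn) / counts.total
    return MetricReport(sensitivity=sens, specificity=spec, precision=prec,
                        f1=f1, mcc=mcc, accuracy=acc, degenerate=deg)


def roc_auc(probabilities: np.ndarray, labels: np.ndarray
            ) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC-AUC (the tie-corrected Mann–Whitney rank statistic) plus the
    (FPR, TPR) curve points from a sweep over unique scores."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    area = float(roc_auc_score(labels, probabilities))
    fpr, tpr, _ = roc_curve(labels, probabilities)
    return area, fpr, tpr


def pr_aupr(probabilities: np.ndarray, labels: np.ndarray
            ) -> tuple[float, np.ndarray, np.ndarray]:
    """Precision–recall curve and its area by the step-wise rule."""
    labels = np.asarray(labels).astype(int)
    if labels.sum() == 0:
        raise ValueError("PR curve requires at least one positive")
    precision, recall, _ = precision_recall_curve(labels, probabilities)
    # step-wise area: sum of precision * recall increments
    area = float(-np.sum(np.diff(recall) * precision[:-1]))
    return area, recall, precision


def top_u_precision(probabilities: np.ndarray, labels: np.ndarray, u: int) -> float:
    """Fraction of true positives among the u highest-scored pairs.

    Ties are broken by stable input order (earlier pairs first).
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = probabilities.shape[0]
    if n < u:
        raise ValueError(f"top-u precision needs at least u={u} pairs, got {n}")
    order = np.argsort(-probabilities, kind="stable")[:u]
    return float(labels[order].mean())


def network_predict(scores: np.ndarray, pairs: list[Pair], threshold: float,
                    mode: str = "interaction") -> list[tuple[str, str, float]]:
    """Thresholded edge extraction for network prediction.

    ``interaction`` mode keeps pairs scoring strictly above the threshold
    (the stringent default in application settings is 0.98);
    ``non_interaction`` mode keeps pairs strictly below it (stringent
    default 0.01).  Returns (id_a, id_b, score) edges.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(pairs):
        raise ValueError("scores and pairs are not aligned")
    if mode == "interaction":
        keep = scores > threshold
    elif mode == "non_interaction":
        keep = scores < threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [(p.id_a, p.id_b, float(s))
            for p, s, k in zip(pairs, scores, keep) if k]


def member_dispersion(member_probs: np.ndarray, y_true: np.ndarray,
                      threshold: float = 0.5) -> dict:
    """Mean, standard deviation and variance of each metric across the
    ensemble members' individual predictions (the 'mean ± sd' convention of
    per-member reporting; variance is also given since both conventions
    appear in practice)."""
    per_member = []
    for probs in member_probs:
        counts = ConfusionCounts.from_predictions(y_true, (probs > threshold).astype(int))
        per_member.append(confusion_metrics(counts).as_dict())
    keys = per_member[0].keys()
    out = {}
    for key in keys:
        vals = np.array([m[key] for m in per_member])
        out[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0)),
                    "variance": float(vals.var(ddof=0))}
    return out


def write_metric_table(path, report: MetricReport, extra: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key, value in report.as_dict().items():
            fh.write(f"{key}\t{value:.6f}\n")
        for key, value in (extra or {}).items():
            fh.write(f"{key}\t{value:.6f}\n")


def write_curve(path, xs: np.ndarray, ys: np.ndarray) -> None:
    with open(path, "w") as fh:
        for x, y in zip(xs, ys):
            fh.write(f"{x:.6f}\t{y:.6f}\n")


def write_edges(path, edges: list[tuple[str, str, float]]) -> None:
    with open(path, "w") as fh:
        for a, b, s in edges:
            fh.write(f"{a}\t{b}\t{s:.6f}\n")
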