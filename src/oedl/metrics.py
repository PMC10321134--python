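"""Multiclass confusion matrix and macro-averaged one-vs-rest metrics.

Accuracy is the trace of the confusion matrix over the total count.  Macro
precision / recall are unweighted means of the per-class one-vs-rest
ratios, and macro-F1 is the harmonic mean of those two macro values (not
the mean of per-class F1 scores).  Per-class AUC uses the Mann-Whitney
tie-aware convention (ties count 1/2), computed by a trapezoid sweep over
the class's probability column; macro-AUC is the unweighted mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASSES, labels_to_int


@dataclass
class ConfusionMatrix3:
    """3x3 count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 3x3 with nonnegative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class(self) -> dict[str, np.ndarray]:
        """Per-class one-vs-rest TP, FP, FN, TN (each a length-3 vector)."""
        tp = np.diag(self.counts).astype(int)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


@dataclass
class MetricReport:
    acc: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_auc: float | None = None
    per_class_auc: dict[str, float] | None = None
    confusion: ConfusionMatrix3 | None = None
    roc_points: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "acc": self.acc,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }
        if self.macro_auc is not None:
            out["macro_auc"] = self.macro_auc
        if self.per_class_auc is not None:
            out["per_class_auc"] = dict(self.per_class_auc)
        if self.confusion is not None:
            out["confusion"] = self.confusion.counts.tolist()
        return out


def confusion(y_true, y_pred) -> ConfusionMatrix3:
    """Exact 3x3 confusion counts from class-letter (or coded) vectors."""
    t = labels_to_int(pd.Series(y_true).to_numpy())
    p = labels_to_int(pd.Series(y_pred).to_numpy())
    if len(t) == 0:
        raise ValueError("empty prediction set")
    if len(t) != len(p):
        raise ValueError("y_true and y_pred lengths differ")
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix3(counts)


def macro_metrics(cm: ConfusionMatrix3) -> MetricReport:
    """ACC + macro precision/recall/F1 from a confusion matrix.

    A class with a zero denominator (never predicted, or absent from the
    truth) contributes 0 to the corresponding macro mean, with a warning.
    """
    d = cm.per_class()
    tp, fp, fn = d["TP"], d["FP"], d["FN"]
    acc = float(tp.sum()) / cm.total

    def _safe_ratio(num, den, what):
        out = np.zeros(3, dtype=float)
        for i in range(3):
            if den[i] == 0:
                warnings.warn(
                    f"class {CLASSES[i]}: zero denominator for {what}; contributes 0",
                    stacklevel=3,
                )
            else:
                out[i] = num[i] / den[i]
        return out

    prec = _safe_ratio(tp, tp + fp, "precision")
    rec = _safe_ratio(tp, tp + fn, "recall")
    macro_p = float(prec.mean())
    macro_r = float(rec.mean())
    if macro_p + macro_r == 0:
        macro_f1 = 0.0
    else:
        macro_f1 = 2 * macro_p * macro_r / (macro_p + macro_r)
    return MetricReport(acc, macro_p, macro_r, macro_f1, confusion=cm)


def roc_ovr(y_true, probs: np.ndarray, class_label: str) -> np.ndarray:
    """One-vs-rest ROC points (fpr, tpr) for one class, threshold sweep.

    Thresholds are the distinct scores of that class's probability column
    plus the +/- infinity endpoints; returns an (n_points, 2) array sorted
    by increasing FPR.
    """
    t = labels_to_int(pd.Series(y_true).to_numpy())
    probs = np.asarray(probs, dtype=float)
    ci = CLASSES.index(class_label)
    pos = t == ci
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(f"class {class_label} one-vs-rest split is degenerate")
    scores = probs[:, ci]
    # descending threshold sweep; ties handled by grouping equal scores
    order = np.argsort(-scores, kind="stable")
    sorted_pos = pos[order]
    sorted_scores = scores[order]
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(~sorted_pos)
    # keep only the last index of each tied score block
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    return np.column_stack([fpr, tpr])


def auc_ovr(y_true, probs: np.ndarray, class_label: str) -> float:
    """Area under the one-vs-rest ROC curve by the trapezoid rule."""
    pts = roc_ovr(y_true, probs, class_label)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def macro_auc(y_true, probs: np.ndarray) -> tuple[float, dict[str, float]]:
    """Unweighted mean of the three per-class one-vs-rest AUCs."""
    per = {c: auc_ovr(y_true, probs, c) for c in CLASSES}
    return float(np.mean(list(per.values()))), per


def evaluate(y_true, y_pred, probs: np.ndarray | None = None) -> MetricReport:
    """Full metric report; AUCs included when probabilities are given."""
    report = macro_metrics(confusion(y_true, y_pred))
    if probs is not None:
        m_auc, per = macro_auc(y_true, probs)
        report.macro_auc = m_auc
        report.per_class_auc = per
        report.roc_points = {c: roc_ovr(y_true, probs, c) for c in CLASSES}
    return report
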