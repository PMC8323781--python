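"""Binary classification metrics: Sn, Sp, F1, Acc, MCC and ROC/AUC.

Definitions (TP/TN/FP/FN are confusion-matrix counts):

    Sn  = TP / (TP + FN)                      sensitivity / recall
    Sp  = TN / (TN + FP)                      specificity
    F1  = 2 TP / (2 TP + FP + FN)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

A metric whose denominator is zero is reported as *undefined with a reason*
rather than silently coerced to 0 or NaN: a zero marginal means the
classifier (or the evaluation set) is degenerate and the caller should know.

AUC is the Mann-Whitney rank statistic — the probability that a random
positive outscores a random negative, ties counted half — which equals the
area under the ROC curve.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .errors import DatasetError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer (got {v})")
        if self.total < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class EvalReport:
    """Metric bundle; a metric that could not be computed is None with its
    reason recorded in ``undefined``."""

    counts: ConfusionCounts
    sn: float | None
    sp: float | None
    f1: float | None
    acc: float
    mcc: float | None
    auc: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "sn": self.sn,
            "sp": self.sp,
            "f1": self.f1,
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
        }
        if self.undefined:
            d["undefined"] = dict(self.undefined)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary_row(self) -> str:
        def fmt(v):
            return "undef" if v is None else f"{v:.4f}"

        c = self.counts
        return (
            f"TP={c.tp} TN={c.tn} FP={c.fp} FN={c.fn}  "
            f"Sn={fmt(self.sn)} Sp={fmt(self.sp)} F1={fmt(self.f1)} "
            f"Acc={self.acc:.4f} MCC={fmt(self.mcc)} AUC={fmt(self.auc)}"
        )


def compute_metrics(counts: ConfusionCounts) -> EvalReport:
    """Sn, Sp, F1, Acc and MCC from confusion counts (AUC needs scores)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    undefined: dict[str, str] = {}

    def ratio(num, den, name, reason):
        if den == 0:
            undefined[name] = reason
            return None
        return num / den

    sn = ratio(tp, tp + fn, "sn", "no positive samples (TP+FN=0)")
    sp = ratio(tn, tn + fp, "sp", "no negative samples (TN+FP=0)")
    f1 = ratio(2 * tp, 2 * tp + fp + fn, "f1", "no positive samples or predictions")
    acc = (tp + tn) / counts.total
    mcc_den_sq = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    if mcc_den_sq == 0:
        undefined["mcc"] = "a confusion-matrix marginal is zero"
        mcc = None
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den_sq)
    return EvalReport(counts, sn, sp, f1, acc, mcc, undefined=undefined)


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """Rank-statistic AUC and the ROC point list.

    Returns ``(auc, points)`` where ``points`` is an array of
    (fpr, tpr, threshold) rows from a threshold sweep.

    Raises
    ------
    DatasetError
        If only one class is present or any score is non-finite.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise DatasetError("scores must be finite")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise DatasetError("roc_auc needs both classes present")
    # Mann-Whitney: midranks give half credit to ties across classes.
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    points = np.column_stack([fpr, tpr, thresholds])
    return float(auc), points


def evaluate_predictions(y_true, y_pred, scores=None) -> EvalReport:
    """Full report from hard predictions and optional decision scores."""
    report = compute_metrics(ConfusionCounts.from_predictions(y_true, y_pred))
    if scores is not None:
        report.auc, _ = roc_auc(scores, y_true)
    return report
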