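"""Binary deepfake-detection evaluation.

The positive class is fixed as *real* throughout (a false negative is a
real image classified as fake).  Confusion counts, scalar metrics, and
ROC/PR curves are computed with scikit-learn behind this module's surface;
the area under the ROC curve is integrated by the trapezoid rule over the
threshold sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = ["POSITIVE_CLASS", "ConfusionMatrix", "CurvePair", "confusion",
           "scalar_metrics", "roc_pr_auc", "write_report", "plot_curves"]

POSITIVE_CLASS = "real"
_LABEL_TO_INT = {"real": 1, "fake": 0, 1: 1, 0: 0, True: 1, False: 0}


def _as_binary(seq) -> np.ndarray:
    try:
        return np.array([_LABEL_TO_INT[v] for v in seq], dtype=int)
    except KeyError as exc:
        raise ValueError(f"labels must be real/fake or 0/1, got {exc}") from exc


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with positive = real."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_array(self) -> np.ndarray:
        """Rows = true (real, fake), columns = predicted (real, fake)."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]], dtype=float)

    def normalized(self) -> np.ndarray:
        """Row-normalized form (each true-class row sums to 1)."""
        arr = self.as_array()
        sums = arr.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return arr / sums


def confusion(labels, predictions) -> ConfusionMatrix:
    y_true = _as_binary(labels)
    y_pred = _as_binary(predictions)
    if len(y_true) != len(y_pred):
        raise ValueError("labels and predictions differ in length")
    tn, fp, fn, tp = _sk_confusion(y_true, y_pred, labels=[0, 1]).ravel()
    return ConfusionMatrix(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


def scalar_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, recall, F1 (positive = real) plus macro averages.

    A zero denominator yields NaN (flagged missing), never a silent 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den else float("nan")

    precision = ratio(cm.tp, cm.tp + cm.fp)
    recall = ratio(cm.tp, cm.tp + cm.fn)
    f1 = ratio(2 * precision * recall, precision + recall) \
        if not (np.isnan(precision) or np.isnan(recall)) else float("nan")
    # the same metrics with fake treated as positive, for macro averaging
    precision_f = ratio(cm.tn, cm.tn + cm.fn)
    recall_f = ratio(cm.tn, cm.tn + cm.fp)
    f1_f = ratio(2 * precision_f * recall_f, precision_f + recall_f) \
        if not (np.isnan(precision_f) or np.isnan(recall_f)) else float("nan")
    return {
        "accuracy": (cm.tp + cm.tn) / cm.total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "macro_precision": np.nanmean([precision, precision_f]),
        "macro_recall": np.nanmean([recall, recall_f]),
        "macro_f1": np.nanmean([f1, f1_f]),
    }


@dataclass
class CurvePair:
    """ROC and PR curves from one threshold sweep, with trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float


def roc_pr_auc(labels, scores) -> CurvePair:
    """Threshold sweep over the real-class scores.

    ``scores`` are probabilities for the positive (real) class.  AUC is the
    trapezoidal integral of TPR over FPR.
    """
    y = _as_binary(labels)
    s = np.asarray(scores, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    prec, rec, _ = precision_recall_curve(y, s)
    return CurvePair(fpr=fpr, tpr=tpr, roc_thresholds=thr,
                     precision=prec, recall=rec, auc=auc)


def write_report(cm: ConfusionMatrix, curves: CurvePair | None,
                 path: str | Path):
    report = {
        "positive_class": POSITIVE_CLASS,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "confusion_normalized": cm.normalized().tolist(),
        "metrics": {k: (None if np.isnan(v) else float(v))
                    for k, v in scalar_metrics(cm).items()},
    }
    if curves is not None:
        report["auc"] = curves.auc
    Path(path).write_text(json.dumps(report, indent=2))
    return report


def plot_curves(curves: CurvePair, out_dir: str | Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots()
    ax.plot(curves.fpr, curves.tpr, label=f"AUC = {curves.auc:.4f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title("ROC (positive = real)")
    ax.legend()
    fig.savefig(out_dir / "roc.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.plot(curves.recall, curves.precision)
    ax.set_xlabel("Recall")
    ax.set_ylabel("Precision")
    ax.set_title("Precision-Recall (positive = real)")
    fig.savefig(out_dir / "pr.png", dpi=120)
    plt.close(fig)
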