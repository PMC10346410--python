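"""Segmentation and measurement-agreement metrics.

Pixel-level segmentation quality is summarized from a (K+1)x(K+1)
confusion matrix (background plus K object classes).  For class i with
true positives TP_i, false positives FP_i and false negatives FN_i:

    IoU_i       = TP_i / (TP_i + FP_i + FN_i)
    MIoU        = mean_i IoU_i
    precision_i = TP_i / (TP_i + FP_i)
    recall_i    = TP_i / (TP_i + FN_i)

The reported precision/recall are averaged over classes (macro by
default, frequency-weighted optionally) and the reported F1 is the
harmonic mean of those two averages.  A class absent from both truth
and prediction has no defined ratio; it contributes 0 and a warning is
emitted rather than silently inflating the average.

Agreement between manual measurements t_i and automatic estimates m_i
is quantified by the coefficient of determination and the root mean
squared error:

    R^2  = 1 - sum((t_i - m_i)^2) / sum((t_i - tbar)^2)
    RMSE = sqrt(mean((t_i - m_i)^2))
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["confusion", "seg_metrics", "agreement", "SegReport"]


def confusion(truth: np.ndarray, pred: np.ndarray, num_classes: int | None = None) -> np.ndarray:
    """Pixel-count confusion matrix; rows are truth, columns prediction."""
    t = np.asarray(truth)
    p = np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: truth {t.shape} vs pred {p.shape}")
    t = t.ravel().astype(np.int64)
    p = p.ravel().astype(np.int64)
    if t.min(initial=0) < 0 or p.min(initial=0) < 0:
        raise ValueError("class labels must be non-negative")
    if num_classes is None:
        num_classes = int(max(t.max(initial=0), p.max(initial=0))) + 1
    cm = np.bincount(t * num_classes + p, minlength=num_classes * num_classes)
    return cm.reshape(num_classes, num_classes)


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    if not ok.all():
        warnings.warn(
            f"{what} undefined for class(es) {np.nonzero(~ok)[0].tolist()}; "
            "contributing 0",
            RuntimeWarning,
            stacklevel=3,
        )
    out[ok] = num[ok] / den[ok]
    return out


@dataclass(frozen=True)
class SegReport:
    """Per-class and averaged segmentation metrics."""

    miou: float
    precision: float
    recall: float
    f1: float
    iou_per_class: np.ndarray
    precision_per_class: np.ndarray
    recall_per_class: np.ndarray

    def as_dict(self) -> dict:
        return {
            "miou": self.miou,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "iou_per_class": self.iou_per_class.tolist(),
            "precision_per_class": self.precision_per_class.tolist(),
            "recall_per_class": self.recall_per_class.tolist(),
        }


def seg_metrics(cm: np.ndarray, average: str = "macro") -> SegReport:
    """Summarize a confusion matrix into MIoU / precision / recall / F1.

    Parameters
    ----------
    cm
        Square pixel-count confusion matrix, rows = truth.
    average
        ``"macro"`` (unweighted class mean, default) or ``"weighted"``
        (classes weighted by their truth pixel frequency).
    """
    cm = np.asarray(cm, dtype=np.int64)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if cm.sum() == 0:
        raise ValueError("confusion matrix has no counts")
    if average not in ("macro", "weighted"):
        raise ValueError(f"unknown average mode {average!r}")

    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp

    iou = _safe_ratio(tp, tp + fp + fn, "IoU")
    prec = _safe_ratio(tp, tp + fp, "precision")
    rec = _safe_ratio(tp, tp + fn, "recall")

    if average == "macro":
        weights = np.full(cm.shape[0], 1.0 / cm.shape[0])
    else:
        weights = cm.sum(axis=1) / cm.sum()
    miou = float(iou @ weights)
    p = float(prec @ weights)
    r = float(rec @ weights)
    f1 = 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0
    return SegReport(miou, p, r, f1, iou, prec, rec)


def agreement(t: np.ndarray, m: np.ndarray) -> dict:
    """R^2 and RMSE between manual values ``t`` and estimates ``m``.

    Returns a dict with keys ``r2``, ``rmse`` and ``n``.  R^2 is
    undefined (returned as NaN) when ``t`` is constant.
    """
    t = np.asarray(t, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    if t.shape != m.shape:
        raise ValueError("t and m must have equal length")
    n = t.size
    if n < 2:
        raise ValueError("need at least 2 measurement pairs")
    ss_res = float(np.sum((t - m) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / n))
    if ss_tot == 0.0:
        warnings.warn("manual values are constant; R^2 undefined", RuntimeWarning, stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return {"r2": r2, "rmse": rmse, "n": n}
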