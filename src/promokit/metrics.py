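"""Confusion counts and the four classification metrics (Acc, Sn, Sp, MCC).

Binary metrics follow the standard definitions with 1 = promoter = positive:

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC with any zero factor in the denominator is reported as 0 (the
conventional limit); an undefined sensitivity or specificity (empty class)
is reported as NaN rather than 0. Multiclass runs report overall accuracy,
unweighted macro one-vs-rest sensitivity/specificity, and the
multi-category MCC computed from the full confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion",
    "compute_metrics",
    "multiclass_metrics",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    acc: float
    sn: float
    sp: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"Acc": self.acc, "Sn": self.sn, "Sp": self.sp, "MCC": self.mcc}

    def __str__(self) -> str:  # printed to 2 decimals, stored unrounded
        return (
            f"Acc={self.acc:.2f} Sn={self.sn:.2f} "
            f"Sp={self.sp:.2f} MCC={self.mcc:.2f}"
        )


def confusion(y_true, y_pred) -> ConfusionCounts:
    """2x2 cross-tabulation of binary labels (1 = positive)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("binary confusion requires labels in {0, 1}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Evaluate Acc, Sn, Sp and MCC from confusion counts."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    acc = (c.tp + c.tn) / c.total
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else math.nan
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return Metrics(acc=acc, sn=sn, sp=sp, mcc=mcc)


def multiclass_metrics(y_true, y_pred, n_classes: int) -> Metrics:
    """Overall accuracy, macro Sn/Sp and multi-category MCC.

    Sensitivity and specificity are unweighted one-vs-rest macro averages
    over the ``n_classes`` classes; MCC is the generalisation computed from
    the full confusion matrix (reducing to the binary MCC at n_classes=2).
    """
    yt = np.asarray(y_true, dtype=np.int64)
    yp = np.asarray(y_pred, dtype=np.int64)
    if yt.shape != yp.shape:
        raise ValueError("length mismatch")
    if yt.size == 0:
        raise ValueError("cannot compute metrics on zero samples")
    for arr in (yt, yp):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"labels must lie in [0, {n_classes})")
    C = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(C, (yt, yp), 1)
    n = C.sum()
    acc = np.trace(C) / n

    sns, sps = [], []
    for c in range(n_classes):
        tp = C[c, c]
        fn = C[c].sum() - tp
        fp = C[:, c].sum() - tp
        tn = n - tp - fn - fp
        sns.append(tp / (tp + fn) if (tp + fn) else math.nan)
        sps.append(tn / (tn + fp) if (tn + fp) else math.nan)
    sn = float(np.nanmean(sns))
    sp = float(np.nanmean(sps))

    # multi-category MCC from the confusion matrix
    t = C.sum(axis=1).astype(float)  # true counts per class
    p = C.sum(axis=0).astype(float)  # predicted counts per class
    cov_tp = np.trace(C) * n - t @ p
    cov_tt = n * n - t @ t
    cov_pp = n * n - p @ p
    mcc = cov_tp / math.sqrt(cov_tt * cov_pp) if cov_tt and cov_pp else 0.0
    return Metrics(acc=float(acc), sn=sn, sp=sp, mcc=float(mcc))
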