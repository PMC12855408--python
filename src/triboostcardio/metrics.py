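"""Confusion-matrix tallies and the ten-metric diagnostic report.

All metrics derive from the four counts (TP, TN, FP, FN) of a binary
classifier: sensitivity/specificity, accuracy, precision (= PPV), F1, NPV,
false-positive/negative rates and the Matthews correlation coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "compute_metrics",
    "majority_vote",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies; invariant tp+tn+fp+fn == number of samples."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Ten diagnostic metrics; all in [0, 1] except mcc in [-1, 1]."""

    sen: float
    spe: float
    acc: float
    pre: float
    ppv: float
    f1: float
    npv: float
    fpr: float
    fnr: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion(y_true, y_pred, positive=1) -> ConfusionCounts:
    """Tally exact TP/TN/FP/FN counts with an explicit positive label.

    Raises ``ValueError`` on length mismatch or a label value that is
    neither the positive label nor one single other (negative) value.
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    labels = set(np.unique(yt)) | set(np.unique(yp))
    others = labels - {positive}
    if len(others) > 1:
        raise ValueError(f"non-binary labels {sorted(labels)!r} for positive={positive!r}")
    t_pos = yt == positive
    p_pos = yp == positive
    return ConfusionCounts(
        tp=int(np.sum(t_pos & p_pos)),
        tn=int(np.sum(~t_pos & ~p_pos)),
        fp=int(np.sum(~t_pos & p_pos)),
        fn=int(np.sum(t_pos & ~p_pos)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator in {name}; returning 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive the full metric suite from confusion counts.

    Zero-denominator metrics are reported as 0 with a ``RuntimeWarning``.
    """
    if c.total <= 0:
        raise ValueError("empty confusion counts")
    tp, tn, fp, fn = float(c.tp), float(c.tn), float(c.fp), float(c.fn)
    sen = _ratio(tp, tp + fn, "sensitivity")
    spe = _ratio(tn, tn + fp, "specificity")
    acc = (tp + tn) / c.total
    pre = _ratio(tp, tp + fp, "precision")
    npv = _ratio(tn, tn + fn, "NPV")
    f1 = _ratio(2 * pre * sen, pre + sen, "F1")
    fpr = _ratio(fp, fp + tn, "FPR")
    fnr = _ratio(fn, fn + tp, "FNR")
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "MCC")
    return MetricsReport(sen=sen, spe=spe, acc=acc, pre=pre, ppv=pre, f1=f1,
                         npv=npv, fpr=fpr, fnr=fnr, mcc=mcc)


def majority_vote(pred_a, pred_b, pred_c):
    """Per-sample modal label of three binary {0,1} prediction vectors.

    With three binary voters no tie is possible, so the mode is always
    well defined.
    """
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    c = np.asarray(pred_c)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("prediction vectors must have equal length")
    for v in (a, b, c):
        if not np.isin(v, (0, 1)).all():
            raise ValueError("votes must be binary {0, 1}")
    return ((a + b + c) >= 2).astype(int)
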