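"""Exact confusion-matrix metrics for the binary healthy/OSCC task.

The six measures — accuracy (AC), misclassification (MC), precision (PR),
sensitivity (SE), specificity (SP) and F1-score (FS) — are reported on the
percent scale rounded to four decimals, the convention used throughout the
oral-histology classification literature this package targets.  Rounding is
half-away-from-zero and is performed in exact rational arithmetic so the
reported numbers are bit-reproducible regression anchors, not floating-point
approximations.

A curated fixture of 72 reference confusion matrices with their published
percent-scale metrics ships with the package (``load_reference_metrics``) and
is used to regression-test the formulas to all four decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "RocCurve",
    "confusion",
    "metrics",
    "roc",
    "load_reference_metrics",
    "POSITIVE_LABEL",
]

#: the positive class everywhere in this package
POSITIVE_LABEL = "OSCC"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion-matrix counts.  Positive class = OSCC."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fn, self.tn, self.fp)


@dataclass(frozen=True)
class MetricReport:
    """Percent-scale metrics rounded to 4 decimals; ``None`` marks an
    undefined value (zero denominator), never a silent 0 or 100."""

    ac: float
    mc: float
    pr: float | None
    se: float | None
    sp: float | None
    fs: float | None

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            k for k in ("pr", "se", "sp", "fs") if getattr(self, k) is None
        )

    def as_dict(self) -> dict[str, float | None]:
        return {k.upper(): getattr(self, k) for k in ("ac", "mc", "pr", "se", "sp", "fs")}


def _round4(q: Fraction) -> float:
    """Half-away-from-zero rounding of an exact rational to 4 decimals."""
    scaled = q * 10_000
    if scaled >= 0:
        r = math.floor(scaled + Fraction(1, 2))
    else:
        r = math.ceil(scaled - Fraction(1, 2))
    return r / 10_000


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return _round4(Fraction(100 * num, den))


def confusion(y_true, y_pred, positive_label=POSITIVE_LABEL) -> ConfusionMatrix:
    """Count TP/FN/TN/FP for binary label sequences.

    Labels may be any hashable values; at most two distinct labels are
    allowed across both sequences and ``positive_label`` identifies the
    positive class.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError(
            f"label sequences must be 1-D and equal length, got shapes "
            f"{y_true.shape} and {y_pred.shape}"
        )
    labels = set(y_true.tolist()) | set(y_pred.tolist())
    if len(labels) > 2:
        raise ValueError(f"labels must be binary, got {sorted(map(str, labels))}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
    )


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """AC/MC/PR/SE/SP/FS from the counts, percent scale, 4 decimals.

    AC = (TP+TN)/total, MC = 100 − AC, PR = TP/(TP+FP), SE = TP/(TP+FN),
    SP = TN/(TN+FP), FS = 2TP/(2TP+FN+FP), each ×100.  Zero-denominator
    metrics come back as ``None`` with the name listed in ``undefined``.
    """
    tp, fn, tn, fp = cm.as_tuple()
    ac_exact = Fraction(100 * (tp + tn), cm.total)
    return MetricReport(
        ac=_round4(ac_exact),
        mc=_round4(100 - ac_exact),
        pr=_pct(tp, tp + fp),
        se=_pct(tp, tp + fn),
        sp=_pct(tn, tn + fp),
        fs=_pct(2 * tp, 2 * tp + fn + fp),
    )


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc(scores, labels, positive_label=POSITIVE_LABEL) -> RocCurve:
    """ROC curve and trapezoid-rule area for positive-class scores.

    Tied scores collapse into a single operating point (the curve is the
    standard stepwise one over distinct thresholds).  Constant scores give
    the chance diagonal, area 0.5, with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive_label).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present to build a ROC curve")
    if np.ptp(scores) == 0:
        warnings.warn("constant scores: ROC is the chance diagonal, AUC = 0.5")
        return RocCurve(
            fpr=np.array([0.0, 1.0]),
            tpr=np.array([0.0, 1.0]),
            thresholds=np.array([np.inf, scores[0]]),
            auc=0.5,
        )
    fpr, tpr, thr = _sk_roc_curve(y, scores)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_sk_auc(fpr, tpr)))


def load_reference_metrics() -> pd.DataFrame:
    """Reference fixture: 72 published confusion matrices with their
    percent-scale metrics, from oral-histology classification experiments
    at 100x/400x magnification over six feature sets and five classifiers.

    Columns: table, magnification, model, tp, fn, tn, fp, ac, mc, pr, se,
    sp, fs, note.  ``note == 'mc_typo'`` flags the single row whose printed
    MC cell contradicts AC (excluded from exact regression).
    """
    with resources.files("oralfuse.data").joinpath(
        "reference_confusion_matrices.csv"
    ).open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    return df
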