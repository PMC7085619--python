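"""Confusion-based performance metrics, ROC curves and leave-one-out CV.

For a binary task with a designated positive class:

    SE  = TP / (TP + FN)          sensitivity (recall, TPR)
    SP  = TN / (TN + FP)          specificity (TNR)
    ACC = (TP + TN) / total
    PPV = TP / (TP + FP)          precision
    F1s = 2 PPV SE / (PPV + SE)

Metrics with a zero denominator are reported as ``None`` (undefined), never
as 0.  The leave-one-out error refits the model Q times, once per held-out
sample, with no shortcuts; folds whose training set loses a class entirely
are flagged and excluded from both numerator and denominator.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["Confusion", "MetricsReport", "confusion", "performance",
           "roc_curve", "LoocvResult", "loocv_error"]


@dataclass(frozen=True)
class Confusion:
    """Binary confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Performance metrics; ``None`` marks an undefined (0/0) metric."""

    se: float | None
    sp: float | None
    acc: float | None
    ppv: float | None
    f1s: float | None
    undefined: tuple[str, ...] = ()


def confusion(y_true: Sequence, y_pred: Sequence, positive) -> Confusion:
    """Count TP/TN/FP/FN with ``positive`` as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    seen = set(y_true.tolist()) | set(y_pred.tolist())
    if positive not in seen:
        raise ValueError(f"positive class {positive!r} not among labels {sorted(map(str, seen))}")
    tpos = y_true == positive
    ppos = y_pred == positive
    return Confusion(
        tp=int(np.sum(tpos & ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def performance(conf: Confusion) -> MetricsReport:
    """Evaluate the metric formulas exactly from the confusion counts."""
    se = _ratio(conf.tp, conf.tp + conf.fn)
    sp = _ratio(conf.tn, conf.tn + conf.fp)
    acc = _ratio(conf.tp + conf.tn, conf.total)
    ppv = _ratio(conf.tp, conf.tp + conf.fp)
    if se is None or ppv is None or (ppv + se) == 0:
        f1s = None
    else:
        f1s = 2.0 * ppv * se / (ppv + se)
    undefined = tuple(
        name for name, v in
        (("SE", se), ("SP", sp), ("ACC", acc), ("PPV", ppv), ("F1s", f1s))
        if v is None
    )
    return MetricsReport(se=se, sp=sp, acc=acc, ppv=ppv, f1s=f1s, undefined=undefined)


def roc_curve(
    scores: Sequence[float], y_true: Sequence, positive
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC staircase and trapezoidal area from positive-class scores.

    Tied scores are grouped into single operating points, which makes the
    trapezoidal area equal to the probability of concordance with ties
    counted half.

    Returns
    -------
    fpr, tpr : ndarray
        Monotone curves from (0, 0) to (1, 1).
    auc : float
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.size != y_true.size:
        raise ValueError("scores and labels must have equal length")
    pos = y_true == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative sample")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    # group equal scores
    boundary = np.append(np.nonzero(np.diff(s))[0], s.size - 1)
    tp = np.cumsum(p)[boundary]
    fp = np.cumsum(~p)[boundary]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class LoocvResult:
    """Outcome of a leave-one-out run."""

    error: float
    n_evaluated: int
    flagged_folds: list[int] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return 1.0 - self.error


def loocv_error(
    model_factory: Callable[[], object],
    X: np.ndarray,
    y: Sequence,
    *,
    min_classes: int = 2,
) -> LoocvResult:
    """Leave-one-out cross-validation error of a classifier family.

    Parameters
    ----------
    model_factory : callable
        Returns a fresh unfitted classifier (fit/predict contract).
    X : (Q, R) array
    y : length-Q labels; Q >= 3.

    Returns
    -------
    LoocvResult
        ``error`` = misclassified / evaluated folds.  Folds whose training
        set holds fewer than ``min_classes`` classes are flagged and not
        evaluated.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    q = X.shape[0]
    if q < 3:
        raise ValueError("LOOCV needs Q >= 3 samples")
    errors = 0
    evaluated = 0
    flagged: list[int] = []
    idx = np.arange(q)
    for i in range(q):
        mask = idx != i
        if np.unique(y[mask]).size < min_classes:
            flagged.append(i)
            continue
        model = model_factory()
        model.fit(X[mask], y[mask])
        pred = model.predict(X[i:i + 1])
        evaluated += 1
        if pred[0] != y[i]:
            errors += 1
    if evaluated == 0:
        raise ValueError("no evaluable folds")
    return LoocvResult(error=errors / evaluated, n_evaluated=evaluated,
                       flagged_folds=flagged)
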