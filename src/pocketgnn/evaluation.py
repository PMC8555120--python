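"""Score-based binary-classification evaluation for virtual screening.

Implements the screening metrics the method is judged by: confusion
counts at a probability threshold, TPR = #TP/(#TP+#FN) and
FPR = #FP/(#FP+#TN), the ROC curve and its trapezoidal area (AUROC),
and precision/recall/F1.  Tied scores are handled so that AUROC equals
the Mann–Whitney pairwise statistic — concordant (active above decoy)
pairs plus half the ties, over all active×decoy pairs — which the test
suite checks against a brute-force pairwise count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

DEFAULT_THRESHOLD = 0.5  # softmax p_active decision boundary


class UndefinedMetric(ArithmeticError):
    """A ratio with a zero denominator, or AUROC on one class."""


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvalReport:
    auroc: float
    precision: float
    recall: float
    f1: float
    confusion: ConfusionCounts
    roc_points: list[tuple[float, float]]  # (FPR, TPR) along the curve


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1 or s.size == 0:
        raise ValueError("scores and labels must be equal-length 1-d, non-empty")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return s, y.astype(int)


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally counts with 'predicted positive' meaning score >= threshold."""
    s, y = _check(scores, labels)
    pred = s >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        FP=int(np.sum(pred & (y == 0))),
        TN=int(np.sum(~pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def tpr(c: ConfusionCounts) -> float:
    if c.TP + c.FN == 0:
        raise UndefinedMetric("TPR undefined: no positives")
    return c.TP / (c.TP + c.FN)


def fpr(c: ConfusionCounts) -> float:
    if c.FP + c.TN == 0:
        raise UndefinedMetric("FPR undefined: no negatives")
    return c.FP / (c.FP + c.TN)


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs from (0,0) to (1,1), non-decreasing in both."""
    s, y = _check(scores, labels)
    if len(set(y)) < 2:
        raise UndefinedMetric("ROC undefined: only one class present")
    f, t, _ = roc_curve(y, s, drop_intermediate=False)
    return list(zip(f.tolist(), t.tolist()))


def auroc(scores, labels) -> float:
    """Area under the ROC curve by trapezoidal integration.

    Equals the tie-corrected Mann–Whitney statistic
    P(score_active > score_decoy) + ½·P(tie).
    """
    pts = roc_points(scores, labels)
    f = np.array([p[0] for p in pts])
    t = np.array([p[1] for p in pts])
    return float(np.trapezoid(t, f))


def f1(scores, labels, threshold: float = DEFAULT_THRESHOLD
       ) -> tuple[float, float, float]:
    """(precision, recall, F1) at a probability threshold.

    With zero true positives all three are defined as 0 — the standard
    convention that keeps per-target tables total.
    """
    c = confusion_at_threshold(scores, labels, threshold)
    if c.TP == 0:
        return 0.0, 0.0, 0.0
    precision = c.TP / (c.TP + c.FP)
    recall = c.TP / (c.TP + c.FN)
    return precision, recall, 2 * precision * recall / (precision + recall)


def evaluate(scores, labels, threshold: float = DEFAULT_THRESHOLD) -> EvalReport:
    """Full report: AUROC, ROC points, confusion and F1 at the threshold."""
    p, r, f = f1(scores, labels, threshold)
    return EvalReport(
        auroc=auroc(scores, labels),
        precision=p, recall=r, f1=f,
        confusion=confusion_at_threshold(scores, labels, threshold),
        roc_points=roc_points(scores, labels),
    )


def report_table(
    grouped: dict[str, tuple[list[float], list[int]]],
    threshold: float = DEFAULT_THRESHOLD,
) -> str:
    """Tab-separated per-target table (target_id, auroc, f1) + Average row."""
    lines = ["target_id\tauroc\tf1"]
    aurocs, f1s = [], []
    for target_id in grouped:
        scores, labels = grouped[target_id]
        a = auroc(scores, labels)
        _, _, f = f1(scores, labels, threshold)
        aurocs.append(a)
        f1s.append(f)
        lines.append(f"{target_id}\t{a:.3f}\t{f:.3f}")
    lines.append(f"Average\t{np.mean(aurocs):.3f}\t{np.mean(f1s):.3f}")
    return "\n".join(lines) + "\n"
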