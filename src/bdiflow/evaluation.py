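"""Clinical evaluation statistics for the three-class response prediction.

Everything derives from the 3×3 predicted-vs-actual confusion matrix over
the surgically graded patients: overall and per-class accuracy, binary
sensitivity / specificity / PPV / NPV after collapsing a chosen positive
class set, ROC curves built from the three-class likelihoods, and binomial
confidence intervals (normal-approximation Wald for planning, exact
Clopper–Pearson for reporting). All fractions are carried as exact integer
numerator/denominator pairs; percentages are rendered to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import GRADES

__all__ = [
    "CLASS_ORDER",
    "ConfusionMatrix3",
    "BinaryMetrics",
    "ROCResult",
    "confusion_matrix",
    "three_class_accuracy",
    "per_class_accuracy",
    "binary_collapse_metrics",
    "two_class_score",
    "roc_auc",
    "wald_ci",
    "exact_ci",
    "table4_per_subject",
]

CLASS_ORDER = GRADES  # ("0", "1", "23")


@dataclass
class ConfusionMatrix3:
    """3×3 counts, rows = predicted class, columns = actual class."""

    counts: np.ndarray
    class_order: tuple[str, str, str] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative 3x3 matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinaryMetrics:
    """Binary classification metrics as exact fractions; None = undefined."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    fractions: dict[str, tuple[int, int]]  # metric -> (numerator, denominator)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    positive_class_definition: str = ""


def confusion_matrix(
    predictions: Mapping[str, str], truths: Mapping[str, str]
) -> ConfusionMatrix3:
    """Cross-tabulate per-patient predicted vs actual grade."""
    pred = dict(predictions)
    true = dict(truths)
    if set(pred) != set(true):
        only = set(pred).symmetric_difference(true)
        raise ValueError(f"patients present in only one input: {sorted(only)}")
    if not pred:
        raise ValueError("no patients to score")
    idx = {g: i for i, g in enumerate(CLASS_ORDER)}
    counts = np.zeros((3, 3), dtype=int)
    for pid in pred:
        counts[idx[str(pred[pid])], idx[str(true[pid])]] += 1
    return ConfusionMatrix3(counts=counts)


def three_class_accuracy(cm: ConfusionMatrix3) -> tuple[float, tuple[int, int]]:
    """Overall agreement: trace over total, with the exact integer pair."""
    correct = int(np.trace(cm.counts))
    return correct / cm.total, (correct, cm.total)


def per_class_accuracy(cm: ConfusionMatrix3) -> dict[str, tuple[float | None, tuple[int, int]]]:
    """Diagonal over column total, by actual class; None when class is absent."""
    out = {}
    for j, grade in enumerate(cm.class_order):
        total = int(cm.counts[:, j].sum())
        hit = int(cm.counts[j, j])
        out[grade] = (hit / total if total else None, (hit, total))
    return out


def binary_collapse_metrics(
    cm: ConfusionMatrix3, positive: set[str] | Sequence[str]
) -> BinaryMetrics:
    """Collapse the 3×3 matrix onto positive-vs-rest and score it.

    A metric whose denominator is zero is reported as ``None`` (with the
    0-denominator fraction retained), never silently as 0.
    """
    pos = {str(g) for g in positive}
    if not pos or not pos.issubset(set(cm.class_order)):
        raise ValueError(f"positive set must be a nonempty subset of {cm.class_order}")
    pos_idx = [i for i, g in enumerate(cm.class_order) if g in pos]
    neg_idx = [i for i, g in enumerate(cm.class_order) if g not in pos]
    c = cm.counts
    tp = int(c[np.ix_(pos_idx, pos_idx)].sum())
    fp = int(c[np.ix_(pos_idx, neg_idx)].sum())
    fn = int(c[np.ix_(neg_idx, pos_idx)].sum())
    tn = int(c[np.ix_(neg_idx, neg_idx)].sum())

    def frac(num: int, den: int) -> float | None:
        return num / den if den else None

    fractions = {
        "sensitivity": (tp, tp + fn),
        "specificity": (tn, tn + fp),
        "ppv": (tp, tp + fp),
        "npv": (tn, tn + fn),
        "accuracy": (tp + tn, tp + tn + fp + fn),
    }
    return BinaryMetrics(
        sensitivity=frac(*fractions["sensitivity"]),
        specificity=frac(*fractions["specificity"]),
        ppv=frac(*fractions["ppv"]),
        npv=frac(*fractions["npv"]),
        accuracy=frac(*fractions["accuracy"]),
        fractions=fractions,
    )


def two_class_score(
    likelihoods: np.ndarray | Sequence[float],
    positive_classes: set[str] | Sequence[str],
    negative_classes: set[str] | Sequence[str],
) -> float:
    """Signed two-class score in [−1, 1] from three-class likelihoods.

    Sum of positive-class likelihoods minus sum of negative-class
    likelihoods; classes in neither set contribute 0 (so a patient fully
    assigned to an excluded class scores 0).
    """
    p = np.asarray(likelihoods, dtype=float)
    if p.shape != (3,):
        raise ValueError("likelihoods must be a 3-vector")
    pos = {str(g) for g in positive_classes}
    neg = {str(g) for g in negative_classes}
    if pos & neg:
        raise ValueError("positive and negative class sets overlap")
    s = 0.0
    for i, g in enumerate(CLASS_ORDER):
        if g in pos:
            s += p[i]
        elif g in neg:
            s -= p[i]
    return float(s)


def roc_auc(scores: Sequence[float], truths: Sequence[bool]) -> ROCResult:
    """ROC by threshold sweep over the unique scores; AUC by trapezoid.

    The curve runs from (0, 0) (threshold above every score) to (1, 1); by
    construction the trapezoid area equals the Mann–Whitney statistic
    ``P(s_pos > s_neg) + ½ P(tie)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truths, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and truths must be matching 1-D sequences")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.array([(s[y] >= t).sum() / n_pos for t in thresholds])
    fpr = np.array([(s[~y] >= t).sum() / n_neg for t in thresholds])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def wald_ci(p_hat: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Normal-approximation binomial CI, clipped to [0, 1].

    Degenerate at p̂ ∈ {0, 1}; prefer :func:`exact_ci` there.
    """
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be positive")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


def exact_ci(successes: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact Clopper–Pearson binomial CI from beta quantiles."""
    if not (0 <= successes <= n) or n < 1:
        raise ValueError("need 0 <= successes <= n with n >= 1")
    lo = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2.0, successes, n - successes + 1)
    )
    hi = 1.0 if successes == n else float(
        stats.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes)
    )
    return (lo, hi)


def table4_per_subject() -> pd.DataFrame:
    """Per-subject predicted/actual grades consistent with the published cross-tab.

    The 18 surgically graded patients break down, by (predicted, actual)
    grade, as 6+1+1 predicted complete response, 0+3+1 predicted marked
    response, and 0+2+4 predicted partial/no response. Subject identities are
    synthetic (the per-subject appendix is not public); only the cell counts
    are constrained.
    """
    cells = [
        ("0", "0", 6), ("0", "1", 1), ("0", "23", 1),
        ("1", "0", 0), ("1", "1", 3), ("1", "23", 1),
        ("23", "0", 0), ("23", "1", 2), ("23", "23", 4),
    ]
    rows = []
    k = 1
    for pred, actual, count in cells:
        for _ in range(count):
            rows.append({"patient_id": f"S{k:02d}", "predicted": pred, "actual": actual})
            k += 1
    return pd.DataFrame(rows)
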