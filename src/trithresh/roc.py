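"""Core ROC arithmetic: confusion counts, Se/Sp/CCR, ROC curves and AUC.

Conventions used throughout the package:

* higher scores indicate a higher measure of disorder (label 1);
* a subject is called *positive* when its score is greater than or equal to
  the decision threshold (ties go positive);
* sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP), correct
  classification rate CCR = (TP+TN)/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LabeledScores",
    "ConfusionCounts",
    "RocCurve",
    "confusion_at",
    "roc_points",
    "empirical_auc",
    "binormal_auc",
]


@dataclass(frozen=True)
class LabeledScores:
    """A paired sample of test scores and binary reference-standard labels.

    Parameters
    ----------
    scores : array-like of float
        One test score (or predicted probability) per subject.
    labels : array-like of {0, 1}
        Reference standard: 0 = condition absent ("healthy"),
        1 = condition present ("diseased").
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float).ravel()
        labels = np.asarray(self.labels).ravel()
        if scores.shape[0] != labels.shape[0]:
            raise ValueError(
                f"scores and labels must have equal length "
                f"({scores.shape[0]} != {labels.shape[0]})"
            )
        if scores.shape[0] == 0:
            raise ValueError("empty sample: no subjects")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        uniq = np.unique(labels)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(f"labels must be 0 or 1, got values {uniq!r}")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(np.int8))

    @property
    def n(self) -> int:
        return int(self.scores.shape[0])

    @property
    def n0(self) -> int:
        """Number of condition-absent subjects."""
        return int(np.sum(self.labels == 0))

    @property
    def n1(self) -> int:
        """Number of condition-present subjects."""
        return int(np.sum(self.labels == 1))

    @property
    def negatives(self) -> np.ndarray:
        """Scores of condition-absent subjects."""
        return self.scores[self.labels == 0]

    @property
    def positives(self) -> np.ndarray:
        """Scores of condition-present subjects."""
        return self.scores[self.labels == 1]

    def require_two_classes(self) -> None:
        if self.n0 == 0 or self.n1 == 0:
            raise ValueError(
                "both classes must be present (have "
                f"{self.n0} negatives, {self.n1} positives)"
            )

    def flipped(self) -> "LabeledScores":
        """Return a copy with negated scores (reverses orientation)."""
        return LabeledScores(-self.scores, self.labels)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts at a threshold or within a score zone."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def se(self) -> float:
        """Sensitivity TP/(TP+FN); nan when no positives in scope."""
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def sp(self) -> float:
        """Specificity TN/(TN+FP); nan when no negatives in scope."""
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ccr(self) -> float:
        """Correct classification rate (accuracy) over the subjects in scope."""
        return (self.tp + self.tn) / self.n if self.n else float("nan")


@dataclass(frozen=True)
class RocCurve:
    """Se and Sp evaluated at every distinct score plus ±inf sentinels.

    ``thresholds`` is sorted ascending; ``se_at`` is non-increasing and
    ``sp_at`` non-decreasing along it.  The sentinel at -inf has
    (Se, Sp) = (1, 0); the one at +inf has (0, 1).
    """

    thresholds: np.ndarray
    se_at: np.ndarray
    sp_at: np.ndarray

    auc: float = field(default=float("nan"))

    def at(self, threshold: float) -> tuple[float, float]:
        """(Se, Sp) at an exact grid threshold."""
        i = int(np.searchsorted(self.thresholds, threshold))
        if i >= len(self.thresholds) or self.thresholds[i] != threshold:
            raise KeyError(f"threshold {threshold!r} not on the grid")
        return float(self.se_at[i]), float(self.sp_at[i])


def confusion_at(data: LabeledScores, threshold: float) -> ConfusionCounts:
    """Dichotomize at ``threshold`` (score >= threshold called positive)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pos_call = data.scores >= threshold
    is_pos = data.labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pos_call & is_pos)),
        fp=int(np.sum(pos_call & ~is_pos)),
        tn=int(np.sum(~pos_call & ~is_pos)),
        fn=int(np.sum(~pos_call & is_pos)),
    )


def roc_points(data: LabeledScores) -> RocCurve:
    """Se and Sp over all distinct observed scores, with sentinel endpoints."""
    data.require_two_classes()
    uniq = np.unique(data.scores)
    thresholds = np.concatenate(([-np.inf], uniq, [np.inf]))
    # Se(t) = P(score >= t | pos); Sp(t) = P(score < t | neg)
    pos = np.sort(data.positives)
    neg = np.sort(data.negatives)
    n1, n0 = pos.size, neg.size
    se = (n1 - np.searchsorted(pos, thresholds, side="left")) / n1
    sp = np.searchsorted(neg, thresholds, side="left") / n0
    return RocCurve(
        thresholds=thresholds,
        se_at=se,
        sp_at=sp,
        auc=empirical_auc(data),
    )


def empirical_auc(data: LabeledScores) -> float:
    """Mann-Whitney estimate of the area under the ROC curve.

    Over all (diseased, healthy) pairs: the proportion in which the diseased
    subject outscores the healthy one, ties counted 1/2.  Equals the
    trapezoidal area under the empirical ROC curve.
    """
    data.require_two_classes()
    ranks = stats.rankdata(data.scores)
    n1 = data.n1
    n0 = data.n0
    r1 = float(np.sum(ranks[data.labels == 1]))
    return (r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1)


def binormal_auc(mu0: float, sd0: float, mu1: float, sd1: float) -> float:
    """Analytic AUC of a binormal pair: Phi((mu1-mu0)/sqrt(sd0^2+sd1^2)).

    Independent of prevalence.
    """
    if sd0 <= 0 or sd1 <= 0:
        raise ValueError("standard deviations must be positive")
    return float(stats.norm.cdf((mu1 - mu0) / np.hypot(sd0, sd1)))
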