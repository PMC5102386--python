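"""Nonparametric Two-Graph ROC (TG-ROC).

TG-ROC plots Se(t) and Sp(t) against the decision threshold t and defines an
Intermediate Range between the largest threshold still attaining Se >= level
and the smallest threshold attaining Sp >= level (level 0.9 or 0.95).
Scores outside that range form the Valid Range: below it called negative,
above it positive.  For strong tests the two bounding thresholds cross
(the Se/Sp intersection exceeds the level); the bounds are then swapped
back ("re-reversed") and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roc import LabeledScores, roc_points
from .uncertain import TriQuality, quality_threshold

__all__ = ["LevelUnattainableError", "TgrocResult", "tgroc_thresholds"]


class LevelUnattainableError(RuntimeError):
    """The requested Se or Sp level is not reached by any candidate threshold."""


@dataclass(frozen=True)
class TgrocResult:
    level: float
    lower: float
    upper: float
    reversed: bool
    quality: TriQuality

    @property
    def width(self) -> float:
        return self.upper - self.lower


def tgroc_thresholds(data: LabeledScores, level: float = 0.9) -> TgrocResult:
    """Determine TG-ROC's Intermediate Range at a pre-selected Se/Sp level.

    Candidate thresholds are the distinct observed scores; Se(t) is the
    fraction of positives with score >= t and Sp(t) the fraction of
    negatives with score < t.  The lower bound is the largest candidate
    with Se >= level, the upper bound the smallest with Sp >= level; if
    they cross, they are swapped and ``reversed`` is set.

    Raises
    ------
    LevelUnattainableError
        Naming the curve (Se or Sp) on which the level is never reached.
    """
    if not 0.5 < level < 1.0:
        raise ValueError(f"level must be in (0.5, 1), got {level}")
    curve = roc_points(data)
    cand = curve.thresholds[1:-1]
    se = curve.se_at[1:-1]
    sp = curve.sp_at[1:-1]

    eps = 1e-12
    se_ok = np.flatnonzero(se >= level - eps)
    sp_ok = np.flatnonzero(sp >= level - eps)
    if se_ok.size == 0:
        raise LevelUnattainableError(
            f"sensitivity never reaches {level} on the candidate grid"
        )
    if sp_ok.size == 0:
        raise LevelUnattainableError(
            f"specificity never reaches {level} on the candidate grid"
        )
    lower = float(cand[se_ok[-1]])   # Se is non-increasing in t
    upper = float(cand[sp_ok[0]])    # Sp is non-decreasing in t
    rev = lower > upper
    if rev:
        lower, upper = upper, lower
    return TgrocResult(
        level=level,
        lower=lower,
        upper=upper,
        reversed=rev,
        quality=quality_threshold(data, lower, upper),
    )
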