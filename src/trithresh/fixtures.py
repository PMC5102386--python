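"""Synthetic clinical fixture.

A deterministic 380-subject score/label set that reproduces, zone by zone,
the published decision tables of the prostate capsular-penetration example
(227 subjects without the condition, 153 with it; Uncertain Interval
[0.226, 0.632]; within-interval split 47/39 vs 26/31 at the intersection).
Only the counts carry meaning: scores are placed evenly inside each zone,
so any count-based statistic on this fixture is exact while the raw
clinical data itself is not distributed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roc import LabeledScores

__all__ = ["ClinicalFixture", "make_clinical_fixture"]

UI_LOWER = 0.226
UI_UPPER = 0.632
INTERSECTION = 0.430

# (zone score band, negatives, positives); bands avoid the zone boundaries
# except for the interval endpoints, which are observed scores by design.
_ZONES = (
    ((0.010, 0.210), 124, 13),           # below the Uncertain Interval
    ((UI_LOWER, 0.425), 47, 26),         # inside, at or below the intersection
    ((0.435, UI_UPPER), 39, 31),         # inside, above the intersection
    ((0.650, 0.950), 17, 83),            # above the Uncertain Interval
)


@dataclass(frozen=True)
class ClinicalFixture:
    data: LabeledScores
    lower: float
    upper: float
    intersection: float


def _band(lo: float, hi: float, k: int, inset: float) -> np.ndarray:
    if k == 0:
        return np.empty(0)
    span = hi - lo
    return np.linspace(lo + inset * span, hi - inset * span, k)


def make_clinical_fixture() -> ClinicalFixture:
    """Build the synthetic clinical sample (380 subjects, 227/153 per class)."""
    scores: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for (lo, hi), n0, n1 in _ZONES:
        neg = _band(lo, hi, n0, inset=0.0)      # negatives own the band edges
        pos = _band(lo, hi, n1, inset=0.004)
        scores.extend([neg, pos])
        labels.extend([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    data = LabeledScores(np.concatenate(scores), np.concatenate(labels))
    return ClinicalFixture(
        data=data, lower=UI_LOWER, upper=UI_UPPER, intersection=INTERSECTION
    )
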