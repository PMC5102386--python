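"""Classical single-decision-threshold (dichotomization) criteria.

Seven comparator criteria: maximized Youden index, maxSe, maxSp, MinPvalue,
ROC01, SpEqualSe and a fixed user-supplied cutpoint.  Candidate thresholds
are the distinct observed scores; among equally optimal candidates the
smallest threshold is returned (after each method's stated tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .roc import LabeledScores, confusion_at, roc_points

__all__ = ["ThresholdResult", "METHODS", "optimal_threshold"]

METHODS = ("youden", "maxSe", "maxSp", "minPvalue", "roc01", "spEqualSe", "fixed")


@dataclass(frozen=True)
class ThresholdResult:
    method: str
    threshold: float
    se: float
    sp: float
    ccr: float

    @property
    def youden_index(self) -> float:
        return self.se + self.sp - 1.0


def _chisq_pvalues(se: np.ndarray, sp: np.ndarray, n1: int, n0: int) -> np.ndarray:
    """Pearson chi-square p-value (no continuity correction) of the 2x2
    classification table at each threshold; p = 1 for degenerate margins."""
    tp = se * n1
    fn = n1 - tp
    tn = sp * n0
    fp = n0 - tn
    n = float(n0 + n1)
    pos_calls = tp + fp  # column margins of the called-positive table
    neg_calls = tn + fn
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (tp * tn - fp * fn) ** 2 / (n1 * n0 * pos_calls * neg_calls)
    chi2 = np.where((pos_calls == 0) | (neg_calls == 0), 0.0, chi2)
    return stats.chi2.sf(chi2, df=1)


def optimal_threshold(
    data: LabeledScores,
    method: str,
    fixed_value: float | None = None,
) -> ThresholdResult:
    """Select a single decision threshold by one of the classical criteria.

    Parameters
    ----------
    data : LabeledScores
        Two-class sample; a subject is called positive at score >= threshold.
    method : str
        One of ``youden`` (maximize Se+Sp-1), ``maxSe`` (maximize Se, ties
        broken by Sp), ``maxSp`` (maximize Sp, ties broken by Se),
        ``minPvalue`` (minimize the Pearson chi-square p of the 2x2 table),
        ``roc01`` (minimize the distance of (1-Sp, Se) to (0, 1)),
        ``spEqualSe`` (minimize \\|Sp - Se\\|) or ``fixed``.
    fixed_value : float, optional
        The cutpoint itself; required for (and only used by) ``fixed``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    data.require_two_classes()

    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method 'fixed' requires fixed_value")
        c = confusion_at(data, fixed_value)
        return ThresholdResult("fixed", float(fixed_value), c.se, c.sp, c.ccr)

    curve = roc_points(data)
    # candidate grid: distinct observed scores only (drop the +-inf sentinels)
    cand = curve.thresholds[1:-1]
    se = curve.se_at[1:-1]
    sp = curve.sp_at[1:-1]

    if method == "youden":
        keys = (se + sp,)
    elif method == "maxSe":
        keys = (se, sp)
    elif method == "maxSp":
        keys = (sp, se)
    elif method == "minPvalue":
        keys = (-_chisq_pvalues(se, sp, data.n1, data.n0),)
    elif method == "roc01":
        keys = (-np.hypot(1.0 - se, 1.0 - sp),)
    else:  # spEqualSe
        keys = (-np.abs(sp - se),)

    best = np.ones(cand.shape[0], dtype=bool)
    for key in keys:
        kmax = np.max(key[best])
        best &= np.isclose(key, kmax, rtol=0.0, atol=1e-12)
    i = int(np.flatnonzero(best)[0])  # smallest optimal threshold

    n0, n1 = data.n0, data.n1
    ccr = (se[i] * n1 + sp[i] * n0) / (n0 + n1)
    return ThresholdResult(method, float(cand[i]), float(se[i]), float(sp[i]), float(ccr))
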