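"""The Uncertain Interval method: trichotomization around the distribution
intersection.

A diagnostic test with overlapping class distributions carries no information
at the score where the two class densities cross.  The Uncertain Interval
(UI) is the widest score interval around that intersection in which correct
and false calls remain nearly balanced: within the interval, sensitivity and
specificity (computed against the intersection as an internal cut) must both
stay at or below a pre-selected value (default 0.55, i.e. TP/FN <= 1.22 and
TN/FP <= 1.22).  Scores outside the UI form the More Certain Interval (MCI):
below-interval scores are called negative, above-interval positive, and the
classification rate there is systematically higher than at any single
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .roc import ConfusionCounts, LabeledScores

__all__ = [
    "IntersectionNotFoundError",
    "UncertainIntervalResult",
    "TriQuality",
    "UncertainQualityReport",
    "estimate_intersection",
    "ui_counts",
    "find_uncertain_interval",
    "quality_threshold",
    "quality_threshold_uncertain",
    "chisq_yates",
    "welch_t",
]

KDE_GRID_SIZE = 512


class IntersectionNotFoundError(RuntimeError):
    """No density crossing exists between the two class means."""


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, 0.9 min(sd, IQR/1.34) n^(-1/5).

    The robust form (taking the smaller of the sd and the normalized IQR),
    which is the standard default for univariate kernel density estimation.
    """
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("bandwidth undefined for zero-spread data")
    return 0.9 * spread * x.size ** (-0.2)


def _class_kde(x: np.ndarray) -> stats.gaussian_kde:
    bw = silverman_bandwidth(x)
    return stats.gaussian_kde(x, bw_method=bw / np.std(x, ddof=1))


@dataclass(frozen=True)
class UncertainIntervalResult:
    """Outcome of the Uncertain Interval search.

    ``lower``/``upper`` are inclusive score bounds; ``ui_counts`` splits the
    within-interval subjects at the intersection (TN/FN at or below it,
    FP/TP above).  ``found`` is False when no feasible interval exists, with
    the reason in ``reason``.
    """

    found: bool
    lower: float = float("nan")
    upper: float = float("nan")
    intersection: float = float("nan")
    ui_counts: ConfusionCounts | None = None
    ui_se: float = float("nan")
    ui_sp: float = float("nan")
    ui_ccr: float = float("nan")
    select: float = 0.55
    reason: str = ""

    @property
    def n_inside(self) -> int:
        return self.ui_counts.n if self.ui_counts is not None else 0

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class TriQuality:
    """3x2 decision table (below/inside/above x condition no/yes) and the
    More-Certain-Interval metrics computed over the two outer zones."""

    decision_table: pd.DataFrame
    mci_ccr: float
    mci_se: float
    mci_sp: float
    n_inside: int
    n_outside: int
    mci_defined: bool


@dataclass(frozen=True)
class UncertainQualityReport:
    """Within-interval quality: counts split at the intersection, Se/Sp/CCR,
    a Yates-corrected chi-square on the balance of the split, and a Welch
    t-test comparing within-interval scores of the two classes."""

    counts: ConfusionCounts
    ui_se: float
    ui_sp: float
    ui_ccr: float
    chi2: float
    chi2_df: int
    chi2_p: float
    t: float
    t_df: float
    t_p: float
    mean_diff: float
    tests_defined: bool


def _normal_crossings(m0: float, s0: float, m1: float, s1: float) -> np.ndarray:
    """Real roots of N(m0, s0^2) density == N(m1, s1^2) density."""
    if np.isclose(s0, s1):
        if np.isclose(m0, m1):
            return np.array([])
        return np.array([(m0 + m1) / 2.0])
    a = 1.0 / s1**2 - 1.0 / s0**2
    b = 2.0 * (m0 / s0**2 - m1 / s1**2)
    c = m1**2 / s1**2 - m0**2 / s0**2 - 2.0 * np.log(s0 / s1)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return np.array([])
    r = np.sqrt(disc)
    return np.array([(-b - r) / (2 * a), (-b + r) / (2 * a)])


def estimate_intersection(data: LabeledScores, method: str = "kde") -> float:
    """Locate the score where the two class densities cross, between the
    class means.

    ``kde`` (default) evaluates per-class Gaussian kernel density estimates
    (Silverman bandwidth) on a shared 512-point grid and returns the crossing
    nearest the midpoint of the class means.  ``normal`` fits a normal
    distribution per class and solves the log-density equation exactly.

    Raises
    ------
    IntersectionNotFoundError
        If no crossing lies between the two class means.
    """
    data.require_two_classes()
    neg, pos = data.negatives, data.positives
    if neg.size < 2 or pos.size < 2:
        raise ValueError("intersection estimation needs >= 2 subjects per class")
    m0, m1 = float(np.mean(neg)), float(np.mean(pos))
    s0, s1 = float(np.std(neg, ddof=1)), float(np.std(pos, ddof=1))
    lo, hi = min(m0, m1), max(m0, m1)
    # Accept crossings in the between-means interval widened by half a class
    # sd on each side: the crossing of two near-equal-spread densities can sit
    # slightly beyond a sample mean, and rejecting it there would discard
    # samples the method handles fine.
    s_lo, s_hi = (s0, s1) if m0 <= m1 else (s1, s0)
    win_lo, win_hi = lo - 0.5 * s_lo, hi + 0.5 * s_hi

    if method == "normal":
        if s0 <= 0 or s1 <= 0:
            raise ValueError("method 'normal' needs positive per-class sd")
        cross = _normal_crossings(m0, s0, m1, s1)
    elif method == "kde":
        grid = np.linspace(data.scores.min(), data.scores.max(), KDE_GRID_SIZE)
        try:
            d0 = _class_kde(neg)(grid)
            d1 = _class_kde(pos)(grid)
        except (np.linalg.LinAlgError, ValueError) as exc:  # zero-variance class
            raise ValueError("kde needs positive per-class variance") from exc
        diff = d0 - d1
        sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
        # linear interpolation of each bracketed crossing
        x0, x1 = grid[sign_change], grid[sign_change + 1]
        y0, y1 = diff[sign_change], diff[sign_change + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(y1 != y0, y0 / (y0 - y1), 0.0)
        cross = x0 + frac * (x1 - x0)
    else:
        raise ValueError(f"unknown intersection method {method!r}")

    cross = cross[np.isfinite(cross) & (cross > win_lo) & (cross < win_hi)]
    if cross.size == 0:
        raise IntersectionNotFoundError(
            f"no density crossing between the class means "
            f"(window {win_lo:.4g}, {win_hi:.4g})"
        )
    mid = (m0 + m1) / 2.0
    return float(cross[np.argmin(np.abs(cross - mid))])


def ui_counts(
    data: LabeledScores, lower: float, upper: float, intersection: float
) -> ConfusionCounts:
    """Split the subjects with lower <= score <= upper at the intersection.

    TN/FN are negatives/positives at or below the intersection; FP/TP are
    negatives/positives above it.  An empty interval yields all-zero counts.
    """
    if not lower <= intersection <= upper:
        raise ValueError("need lower <= intersection <= upper")
    inside = (data.scores >= lower) & (data.scores <= upper)
    below = data.scores <= intersection
    is_pos = data.labels == 1
    return ConfusionCounts(
        tn=int(np.sum(inside & below & ~is_pos)),
        fn=int(np.sum(inside & below & is_pos)),
        fp=int(np.sum(inside & ~below & ~is_pos)),
        tp=int(np.sum(inside & ~below & is_pos)),
    )


def find_uncertain_interval(
    data: LabeledScores,
    select: float = 0.55,
    intersection: float | None = None,
    intersection_method: str = "kde",
) -> UncertainIntervalResult:
    """Search for the Uncertain Interval.

    Candidate bounds range over the distinct observed scores with
    lower <= intersection <= upper.  A candidate is feasible when all four
    within-interval cells (TN, FN, FP, TP split at the intersection) are at
    least 1 and the within-interval Se and Sp are both <= ``select``.  Among
    feasible candidates the one containing the most subjects wins (ties:
    widest score range, then smallest lower bound).

    Returns a result with ``found=False`` (and a reason) when the
    intersection cannot be determined or no candidate is feasible.
    """
    if not 0.5 < select < 1.0:
        raise ValueError(f"select must be in (0.5, 1), got {select}")
    data.require_two_classes()

    if intersection is None:
        try:
            intersection = estimate_intersection(data, method=intersection_method)
        except IntersectionNotFoundError as exc:
            return UncertainIntervalResult(
                found=False, select=select, reason=str(exc)
            )
    intersection = float(intersection)

    uniq = np.unique(data.scores)
    lows = uniq[uniq <= intersection]
    ups = uniq[uniq >= intersection]
    if lows.size == 0 or ups.size == 0:
        return UncertainIntervalResult(
            found=False, intersection=intersection, select=select,
            reason="intersection outside the observed score range",
        )

    neg = np.sort(data.negatives)
    pos = np.sort(data.positives)
    neg_le_i = int(np.searchsorted(neg, intersection, side="right"))
    pos_le_i = int(np.searchsorted(pos, intersection, side="right"))
    # per-lower-bound counts in [L, intersection]
    tn = neg_le_i - np.searchsorted(neg, lows, side="left")
    fn = pos_le_i - np.searchsorted(pos, lows, side="left")
    # per-upper-bound counts in (intersection, U]
    fp = np.searchsorted(neg, ups, side="right") - neg_le_i
    tp = np.searchsorted(pos, ups, side="right") - pos_le_i

    tn_c, fn_c = tn[:, None], fn[:, None]
    fp_c, tp_c = fp[None, :], tp[None, :]
    eps = 1e-9
    feasible = (
        (tn_c >= 1) & (fn_c >= 1) & (fp_c >= 1) & (tp_c >= 1)
        & (tp_c <= select * (tp_c + fn_c) + eps)   # ui_se <= select
        & (tn_c <= select * (tn_c + fp_c) + eps)   # ui_sp <= select
    )
    if not feasible.any():
        return UncertainIntervalResult(
            found=False, intersection=intersection, select=select,
            reason="no candidate interval satisfies the balance constraints",
        )

    totals = np.where(feasible, (tn_c + fn_c) + (fp_c + tp_c), -1)
    best = totals == totals.max()
    widths = np.where(best, ups[None, :] - lows[:, None], -np.inf)
    best &= widths == widths.max()
    i, j = map(int, np.argwhere(best)[0])  # rows ascend in L: smallest lower

    lower, upper = float(lows[i]), float(ups[j])
    counts = ConfusionCounts(
        tn=int(tn[i]), fn=int(fn[i]), fp=int(fp[j]), tp=int(tp[j])
    )
    return UncertainIntervalResult(
        found=True,
        lower=lower,
        upper=upper,
        intersection=intersection,
        ui_counts=counts,
        ui_se=counts.se,
        ui_sp=counts.sp,
        ui_ccr=counts.ccr,
        select=select,
    )


def quality_threshold(
    data: LabeledScores, lower: float, upper: float
) -> TriQuality:
    """Trichotomous decision table for the zones score < lower,
    lower <= score <= upper, and score > upper.

    The MCI metrics treat below-zone subjects as called negative and
    above-zone subjects as called positive; inside-zone subjects receive no
    decision.  With ``lower == upper`` (and no score exactly there) this
    reduces to the ordinary dichotomous confusion table.
    """
    if lower > upper:
        raise ValueError("need lower <= upper")
    s, y = data.scores, data.labels
    below = s < lower
    above = s > upper
    inside = ~below & ~above
    table = pd.DataFrame(
        {
            0: [int(np.sum(below & (y == 0))), int(np.sum(inside & (y == 0))),
                int(np.sum(above & (y == 0)))],
            1: [int(np.sum(below & (y == 1))), int(np.sum(inside & (y == 1))),
                int(np.sum(above & (y == 1)))],
        },
        index=["below", "inside", "above"],
    )
    tn = table.loc["below", 0]
    fn = table.loc["below", 1]
    fp = table.loc["above", 0]
    tp = table.loc["above", 1]
    n_out = int(tn + fn + fp + tp)
    n_in = int(table.loc["inside"].sum())
    if n_out == 0 or (tp + fn) == 0 or (tn + fp) == 0:
        return TriQuality(table, float("nan"), float("nan"), float("nan"),
                          n_in, n_out, mci_defined=False)
    return TriQuality(
        decision_table=table,
        mci_ccr=(tp + tn) / n_out,
        mci_se=tp / (tp + fn),
        mci_sp=tn / (tn + fp),
        n_inside=n_in,
        n_outside=n_out,
        mci_defined=True,
    )


def quality_threshold_uncertain(
    data: LabeledScores, ui: UncertainIntervalResult
) -> UncertainQualityReport:
    """Quality report for the subjects inside a found Uncertain Interval.

    Splits the within-interval subjects at the intersection, reports Se, Sp
    and CCR of that split, the Yates-corrected chi-square on the 2x2 balance
    table [[TN, FN], [FP, TP]], and a Welch t-test comparing the
    within-interval scores of the two classes (healthy first, so a negative
    t means the diseased score mean is higher).
    """
    if not ui.found:
        raise ValueError("quality_threshold_uncertain requires a found interval")
    counts = ui_counts(data, ui.lower, ui.upper, ui.intersection)
    inside = (data.scores >= ui.lower) & (data.scores <= ui.upper)
    x0 = data.scores[inside & (data.labels == 0)]
    x1 = data.scores[inside & (data.labels == 1)]

    defined = True
    chi2 = chi2_p = t = t_df = t_p = mean_diff = float("nan")
    if x0.size == 0 or x1.size == 0:
        defined = False
    else:
        mean_diff = float(np.mean(x1) - np.mean(x0))
        try:
            chi2, _, chi2_p = chisq_yates(
                [[counts.tn, counts.fn], [counts.fp, counts.tp]]
            )
        except ValueError:
            defined = False
        try:
            t, t_df, t_p = welch_t(x0, x1)
        except ValueError:
            defined = False
    return UncertainQualityReport(
        counts=counts,
        ui_se=counts.se,
        ui_sp=counts.sp,
        ui_ccr=counts.ccr,
        chi2=chi2,
        chi2_df=1,
        chi2_p=chi2_p,
        t=t,
        t_df=t_df,
        t_p=t_p,
        mean_diff=mean_diff,
        tests_defined=defined,
    )


def chisq_yates(table) -> tuple[float, int, float]:
    """Yates-corrected Pearson chi-square for a 2x2 table.

    statistic = sum (max(|O - E| - 0.5, 0))^2 / E, df = 1, p from the
    chi-square(1) upper tail.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("both margins must be positive")
    expected = np.outer(rows, cols) / obs.sum()
    dev = np.maximum(np.abs(obs - expected) - 0.5, 0.0)
    statistic = float(np.sum(dev**2 / expected))
    return statistic, 1, float(stats.chi2.sf(statistic, df=1))


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test (unequal variances, Welch-Satterthwaite df).

    Returns (t, df, two-sided p).  Identical samples give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    if np.var(x, ddof=1) + np.var(y, ddof=1) <= 0:
        raise ValueError("degenerate variance: both samples are constant")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
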