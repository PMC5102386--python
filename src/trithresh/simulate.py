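"""Binormal Monte-Carlo comparison of Youden, Uncertain Interval and TG-ROC.

The study grid crosses three diseased-class means (3, 2, 1), three
diseased-class standard deviations (0.6, 1.0, 1.5) and three prevalences
(0.5, 0.2, 0.1) into 27 binormal test models; the healthy class is always
N(0, 1) and higher scores indicate more disorder.  Each replicate draws a
sample of fixed class sizes, fits the maximized-Youden threshold, searches
for the Uncertain Interval (recording when none exists) and determines
TG-ROC's Intermediate Range; per-model aggregates mirror the usual summary
layout (AUC, thresholds, zone sizes, CCR/Se/Sp, the proportion of
replicates without a feasible interval, and the proportion with a
significant within-range Welch t-test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .roc import LabeledScores, binormal_auc, empirical_auc
from .tgroc import LevelUnattainableError, tgroc_thresholds
from .thresholds import optimal_threshold
from .uncertain import (
    find_uncertain_interval,
    quality_threshold,
    quality_threshold_uncertain,
    welch_t,
)

__all__ = [
    "BinormalModel",
    "MODEL_GRID",
    "get_model",
    "binormal_sample",
    "run_model",
    "run_grid",
    "SimulationSummary",
    "table5_frame",
    "table6_frame",
]

MU1_LEVELS = (3.0, 2.0, 1.0)
SD1_LEVELS = (0.6, 1.0, 1.5)
PREV_LEVELS = (0.5, 0.2, 0.1)


@dataclass(frozen=True)
class BinormalModel:
    """One row of the 27-model grid: healthy N(0,1) vs diseased N(mu1, sd1^2)."""

    model_id: int
    mu1: float
    sd1: float
    prevalence: float
    mu0: float = 0.0
    sd0: float = 1.0

    @property
    def auc(self) -> float:
        """Analytic binormal AUC (prevalence-free)."""
        return binormal_auc(self.mu0, self.sd0, self.mu1, self.sd1)


MODEL_GRID: tuple[BinormalModel, ...] = tuple(
    BinormalModel(model_id=i + 1, mu1=m, sd1=s, prevalence=p)
    for i, (m, s, p) in enumerate(
        (m, s, p) for m in MU1_LEVELS for s in SD1_LEVELS for p in PREV_LEVELS
    )
)


def get_model(model_id: int) -> BinormalModel:
    if not 1 <= model_id <= 27:
        raise ValueError(f"model_id must be 1..27, got {model_id}")
    return MODEL_GRID[model_id - 1]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def binormal_sample(model: BinormalModel, n: int, seed) -> LabeledScores:
    """Draw a sample of n subjects with fixed class sizes.

    n1 = round(n * prevalence) positives from N(mu1, sd1^2) and n - n1
    negatives from N(mu0, sd0^2); deterministic given the seed.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    n1 = int(round(n * model.prevalence))
    n0 = n - n1
    if n1 < 1 or n0 < 1:
        raise ValueError(
            f"degenerate class sizes (n0={n0}, n1={n1}) for n={n}, "
            f"prevalence={model.prevalence}"
        )
    rng = _rng(seed)
    neg = rng.normal(model.mu0, model.sd0, size=n0)
    pos = rng.normal(model.mu1, model.sd1, size=n1)
    return LabeledScores(
        np.concatenate([neg, pos]),
        np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]),
    )


@dataclass(frozen=True)
class SimulationSummary:
    """Per-model Monte-Carlo aggregate; UI quantities are averaged over the
    replicates where an interval was found, TG-ROC quantities over the
    replicates where the level was attainable."""

    model: BinormalModel
    reps: int
    n: int
    select: float
    level: float
    auc_mean: float
    auc_analytic: float
    # maximized Youden
    youden_dt_mean: float
    youden_ccr_mean: float
    youden_se_mean: float
    youden_sp_mean: float
    # Uncertain Interval / More Certain Interval
    n_found: int
    p_na: float
    ui_lower_mean: float
    ui_upper_mean: float
    ui_size_mean: float
    ui_ccr_mean: float
    ui_se_mean: float
    ui_sp_mean: float
    ui_mean_diff_mean: float
    p_t: float
    mci_size_mean: float
    mci_ccr_mean: float
    mci_se_mean: float
    mci_sp_mean: float
    youden_in_ui_rate: float
    # TG-ROC
    n_tg: int
    p_tg_na: float
    p_reversed: float
    tg_lower_mean: float
    tg_upper_mean: float
    tg_vr_size_mean: float
    tg_vr_ccr_mean: float
    tg_vr_se_mean: float
    tg_vr_sp_mean: float
    tg_ir_size_mean: float
    tg_ir_ccr_mean: float
    tg_ir_se_mean: float
    tg_ir_sp_mean: float
    tg_ir_mean_diff_mean: float
    tg_p_t: float
    n_errors: int
    replicates: pd.DataFrame


def _nanmean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    return float(np.nanmean(arr)) if arr.size and not np.all(np.isnan(arr)) else float("nan")


def run_model(
    model: BinormalModel,
    reps: int,
    n: int = 1000,
    seed: int = 0,
    select: float = 0.55,
    level: float = 0.9,
    intersection_method: str = "kde",
) -> SimulationSummary:
    """Run the three-way comparison for one binormal model.

    Per replicate: simulate, maximize the Youden index, search for the
    Uncertain Interval, determine TG-ROC's range, and compute all zone
    quality metrics and within-range Welch t-tests.  Replicate-level
    failures are recorded, never fatal.
    """
    if reps < 1:
        raise ValueError("need reps >= 1")
    rows = []
    n_errors = 0
    for rep in range(reps):
        rng = np.random.default_rng([int(seed), model.model_id, rep])
        try:
            rows.append(
                _one_replicate(model, n, rng, select, level, intersection_method, rep)
            )
        except Exception:  # pragma: no cover - defensive; summaries stay valid
            n_errors += 1
    df = pd.DataFrame(rows)

    found = df[df["ui_found"]]
    tg = df[df["tg_ok"]]
    ui_t_defined = found[np.isfinite(found["ui_t_p"])]
    tg_t_defined = tg[np.isfinite(tg["tg_t_p"])]

    return SimulationSummary(
        model=model,
        reps=reps,
        n=n,
        select=select,
        level=level,
        auc_mean=_nanmean(df["auc"]),
        auc_analytic=model.auc,
        youden_dt_mean=_nanmean(df["youden_dt"]),
        youden_ccr_mean=_nanmean(df["youden_ccr"]),
        youden_se_mean=_nanmean(df["youden_se"]),
        youden_sp_mean=_nanmean(df["youden_sp"]),
        n_found=int(len(found)),
        p_na=1.0 - len(found) / len(df) if len(df) else float("nan"),
        ui_lower_mean=_nanmean(found["ui_lower"]),
        ui_upper_mean=_nanmean(found["ui_upper"]),
        ui_size_mean=_nanmean(found["ui_size"]),
        ui_ccr_mean=_nanmean(found["ui_ccr"]),
        ui_se_mean=_nanmean(found["ui_se"]),
        ui_sp_mean=_nanmean(found["ui_sp"]),
        ui_mean_diff_mean=_nanmean(found["ui_mean_diff"]),
        p_t=(
            float(np.mean(ui_t_defined["ui_t_p"] < 0.05))
            if len(ui_t_defined)
            else float("nan")
        ),
        mci_size_mean=_nanmean(found["mci_size"]),
        mci_ccr_mean=_nanmean(found["mci_ccr"]),
        mci_se_mean=_nanmean(found["mci_se"]),
        mci_sp_mean=_nanmean(found["mci_sp"]),
        youden_in_ui_rate=(
            float(np.mean(found["youden_in_ui"])) if len(found) else float("nan")
        ),
        n_tg=int(len(tg)),
        p_tg_na=1.0 - len(tg) / len(df) if len(df) else float("nan"),
        p_reversed=float(np.mean(tg["tg_reversed"])) if len(tg) else float("nan"),
        tg_lower_mean=_nanmean(tg["tg_lower"]),
        tg_upper_mean=_nanmean(tg["tg_upper"]),
        tg_vr_size_mean=_nanmean(tg["tg_vr_size"]),
        tg_vr_ccr_mean=_nanmean(tg["tg_vr_ccr"]),
        tg_vr_se_mean=_nanmean(tg["tg_vr_se"]),
        tg_vr_sp_mean=_nanmean(tg["tg_vr_sp"]),
        tg_ir_size_mean=_nanmean(tg["tg_ir_size"]),
        tg_ir_ccr_mean=_nanmean(tg["tg_ir_ccr"]),
        tg_ir_se_mean=_nanmean(tg["tg_ir_se"]),
        tg_ir_sp_mean=_nanmean(tg["tg_ir_sp"]),
        tg_ir_mean_diff_mean=_nanmean(tg["tg_ir_mean_diff"]),
        tg_p_t=(
            float(np.mean(tg_t_defined["tg_t_p"] < 0.05))
            if len(tg_t_defined)
            else float("nan")
        ),
        n_errors=n_errors,
        replicates=df,
    )


def _one_replicate(model, n, rng, select, level, intersection_method, rep) -> dict:
    data = binormal_sample(model, n, rng)
    row: dict = {"rep": rep}
    row["auc"] = empirical_auc(data)

    youden = optimal_threshold(data, "youden")
    row.update(
        youden_dt=youden.threshold,
        youden_ccr=youden.ccr,
        youden_se=youden.se,
        youden_sp=youden.sp,
    )

    ui = find_uncertain_interval(
        data, select=select, intersection_method=intersection_method
    )
    row["ui_found"] = ui.found
    nan = float("nan")
    if ui.found:
        rep_q = quality_threshold_uncertain(data, ui)
        tri = quality_threshold(data, ui.lower, ui.upper)
        row.update(
            ui_lower=ui.lower,
            ui_upper=ui.upper,
            ui_size=ui.n_inside,
            ui_ccr=rep_q.ui_ccr,
            ui_se=rep_q.ui_se,
            ui_sp=rep_q.ui_sp,
            ui_mean_diff=rep_q.mean_diff,
            ui_t_p=rep_q.t_p,
            mci_size=tri.n_outside,
            mci_ccr=tri.mci_ccr,
            mci_se=tri.mci_se,
            mci_sp=tri.mci_sp,
            youden_in_ui=bool(ui.lower <= youden.threshold <= ui.upper),
        )
    else:
        row.update(
            ui_lower=nan, ui_upper=nan, ui_size=nan, ui_ccr=nan, ui_se=nan,
            ui_sp=nan, ui_mean_diff=nan, ui_t_p=nan, mci_size=nan,
            mci_ccr=nan, mci_se=nan, mci_sp=nan, youden_in_ui=False,
        )

    try:
        tg = tgroc_thresholds(data, level=level)
    except LevelUnattainableError:
        row.update(
            tg_ok=False, tg_reversed=False, tg_lower=nan, tg_upper=nan,
            tg_vr_size=nan, tg_vr_ccr=nan, tg_vr_se=nan, tg_vr_sp=nan,
            tg_ir_size=nan, tg_ir_ccr=nan, tg_ir_se=nan, tg_ir_sp=nan,
            tg_ir_mean_diff=nan, tg_t_p=nan,
        )
        return row
    inside = (data.scores >= tg.lower) & (data.scores <= tg.upper)
    x0 = data.scores[inside & (data.labels == 0)]
    x1 = data.scores[inside & (data.labels == 1)]
    ir_counts = _inside_counts(data, tg.lower, tg.upper, ui.intersection)
    try:
        _, _, t_p = welch_t(x0, x1)
    except ValueError:
        t_p = nan
    row.update(
        tg_ok=True,
        tg_reversed=tg.reversed,
        tg_lower=tg.lower,
        tg_upper=tg.upper,
        tg_vr_size=tg.quality.n_outside,
        tg_vr_ccr=tg.quality.mci_ccr,
        tg_vr_se=tg.quality.mci_se,
        tg_vr_sp=tg.quality.mci_sp,
        tg_ir_size=tg.quality.n_inside,
        tg_ir_ccr=ir_counts["ccr"],
        tg_ir_se=ir_counts["se"],
        tg_ir_sp=ir_counts["sp"],
        tg_ir_mean_diff=(
            float(np.mean(x1) - np.mean(x0)) if x0.size and x1.size else nan
        ),
        tg_t_p=t_p,
    )
    return row


def _inside_counts(
    data: LabeledScores, lower: float, upper: float, intersection: float
) -> dict:
    """CCR/Se/Sp of the scores inside [lower, upper], split at the estimated
    distribution intersection (clamped into the range); the range midpoint
    stands in when no intersection could be determined."""
    from .uncertain import ui_counts

    cut = intersection if np.isfinite(intersection) else 0.5 * (lower + upper)
    cut = min(max(cut, lower), upper)
    c = ui_counts(data, lower, upper, cut)
    return {"ccr": c.ccr, "se": c.se, "sp": c.sp}


def run_grid(
    reps: int,
    n: int = 1000,
    seed: int = 0,
    select: float = 0.55,
    level: float = 0.9,
    models: Sequence[int] | None = None,
    intersection_method: str = "kde",
) -> list[SimulationSummary]:
    """Run run_model across the grid (all 27 models by default, in grid order)."""
    ids = list(models) if models is not None else [m.model_id for m in MODEL_GRID]
    return [
        run_model(
            get_model(i), reps=reps, n=n, seed=seed, select=select,
            level=level, intersection_method=intersection_method,
        )
        for i in ids
    ]


def table5_frame(summaries: Sequence[SimulationSummary]) -> pd.DataFrame:
    """Youden / More Certain Interval / TG-ROC Valid Range comparison table."""
    return pd.DataFrame(
        {
            "model": s.model.model_id,
            "M1": s.model.mu1,
            "sd1": s.model.sd1,
            "Pr": s.model.prevalence,
            "AUC": s.auc_mean,
            "Youden.Dt": s.youden_dt_mean,
            "Youden.CCR": s.youden_ccr_mean,
            "Youden.Sp": s.youden_sp_mean,
            "Youden.Se": s.youden_se_mean,
            "MCI.lower": s.ui_lower_mean,
            "MCI.upper": s.ui_upper_mean,
            "MCI.Size": s.mci_size_mean,
            "MCI.CCR": s.mci_ccr_mean,
            "MCI.Sp": s.mci_sp_mean,
            "MCI.Se": s.mci_se_mean,
            "p.NA": s.p_na,
            "TG.lower": s.tg_lower_mean,
            "TG.upper": s.tg_upper_mean,
            "VR.Size": s.tg_vr_size_mean,
            "VR.CCR": s.tg_vr_ccr_mean,
            "VR.Sp": s.tg_vr_sp_mean,
            "VR.Se": s.tg_vr_se_mean,
        }
        for s in summaries
    )


def table6_frame(summaries: Sequence[SimulationSummary]) -> pd.DataFrame:
    """Uncertain Interval / TG-ROC Intermediate Range comparison table."""
    return pd.DataFrame(
        {
            "model": s.model.model_id,
            "M1": s.model.mu1,
            "sd1": s.model.sd1,
            "Prev": s.model.prevalence,
            "AUC": s.auc_mean,
            "UI.lower": s.ui_lower_mean,
            "UI.upper": s.ui_upper_mean,
            "UI.Size": s.ui_size_mean,
            "UI.CCR": s.ui_ccr_mean,
            "UI.Sp": s.ui_sp_mean,
            "UI.Se": s.ui_se_mean,
            "UI.dM": s.ui_mean_diff_mean,
            "UI.P(t)": s.p_t,
            "p.NA": s.p_na,
            "IR.lower": s.tg_lower_mean,
            "IR.upper": s.tg_upper_mean,
            "IR.Size": s.tg_ir_size_mean,
            "IR.CCR": s.tg_ir_ccr_mean,
            "IR.Sp": s.tg_ir_sp_mean,
            "IR.Se": s.tg_ir_se_mean,
            "IR.dM": s.tg_ir_mean_diff_mean,
            "IR.P(t)": s.tg_p_t,
        }
        for s in summaries
    )
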