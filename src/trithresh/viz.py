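"""Plot-ready data and figures: mixed probability histograms, TG-ROC curves
and class-density curves with the intersection marked.

Every ``*_data`` function is pure and returns arrays/frames; the ``plot_*``
wrappers render them with matplotlib and work headless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .roc import LabeledScores, roc_points
from .uncertain import KDE_GRID_SIZE, _class_kde, estimate_intersection

__all__ = [
    "MixedHistogram",
    "mixed_probability_histogram",
    "tgroc_curve_data",
    "density_curves",
    "plot_mixed_histogram",
    "plot_tgroc_curves",
    "plot_density_curves",
]


@dataclass(frozen=True)
class MixedHistogram:
    """Overlaid per-class histograms on shared bin edges."""

    bin_edges: np.ndarray
    counts0: np.ndarray
    counts1: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count_healthy": self.counts0,
                "count_diseased": self.counts1,
            }
        )


def mixed_probability_histogram(
    data: LabeledScores,
    bins: int = 20,
    range: tuple[float, float] | None = None,
) -> MixedHistogram:
    """Histogram both classes on identical bin edges.

    The default range is [0, 1] when all scores are probabilities (lie in
    [0, 1]); otherwise the observed score range.  An empty class yields a
    zero row with a warning.
    """
    if bins < 2:
        raise ValueError("need bins >= 2")
    if range is None:
        s = data.scores
        range = (0.0, 1.0) if (s.min() >= 0.0 and s.max() <= 1.0) else (s.min(), s.max())
    edges = np.linspace(range[0], range[1], bins + 1)
    counts0, _ = np.histogram(data.negatives, bins=edges)
    counts1, _ = np.histogram(data.positives, bins=edges)
    if data.n0 == 0 or data.n1 == 0:
        warnings.warn("one class is empty; its histogram row is all zeros")
    return MixedHistogram(bin_edges=edges, counts0=counts0, counts1=counts1)


def tgroc_curve_data(data: LabeledScores) -> pd.DataFrame:
    """Se(t) and Sp(t) series over the threshold grid (TG-ROC graphic)."""
    curve = roc_points(data)
    return pd.DataFrame(
        {"threshold": curve.thresholds, "se": curve.se_at, "sp": curve.sp_at}
    )


def density_curves(
    data: LabeledScores, intersection_method: str = "kde", grid_size: int = KDE_GRID_SIZE
) -> pd.DataFrame:
    """Per-class Gaussian-KDE density curves on a shared grid, with the
    estimated intersection attached as frame metadata (``attrs``)."""
    data.require_two_classes()
    grid = np.linspace(data.scores.min(), data.scores.max(), grid_size)
    d0 = _class_kde(data.negatives)(grid)
    d1 = _class_kde(data.positives)(grid)
    frame = pd.DataFrame({"score": grid, "density_healthy": d0, "density_diseased": d1})
    frame.attrs["intersection"] = estimate_intersection(data, method=intersection_method)
    return frame


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_mixed_histogram(data: LabeledScores, bins: int = 20, ax=None):
    """Render the mixed probability histogram (two overlaid class histograms)."""
    h = mixed_probability_histogram(data, bins=bins)
    ax = _axes(ax)
    width = np.diff(h.bin_edges)
    ax.bar(h.bin_edges[:-1], h.counts0, width=width, align="edge",
           alpha=0.6, label="condition absent (0)")
    ax.bar(h.bin_edges[:-1], h.counts1, width=width, align="edge",
           alpha=0.6, label="condition present (1)")
    ax.set_xlabel("score")
    ax.set_ylabel("count")
    ax.legend()
    return ax


def plot_tgroc_curves(data: LabeledScores, level: float | None = None, ax=None):
    """Render Se and Sp against the decision threshold."""
    frame = tgroc_curve_data(data)
    finite = np.isfinite(frame["threshold"])
    ax = _axes(ax)
    ax.plot(frame.loc[finite, "threshold"], frame.loc[finite, "se"], label="Se")
    ax.plot(frame.loc[finite, "threshold"], frame.loc[finite, "sp"], label="Sp")
    if level is not None:
        ax.axhline(level, linestyle="--", color="grey", label=f"level {level}")
    ax.set_xlabel("decision threshold")
    ax.set_ylabel("proportion")
    ax.legend()
    return ax


def plot_density_curves(data: LabeledScores, ax=None):
    """Render the two class densities with the intersection marked."""
    frame = density_curves(data)
    ax = _axes(ax)
    ax.plot(frame["score"], frame["density_healthy"], label="condition absent (0)")
    ax.plot(frame["score"], frame["density_diseased"], label="condition present (1)")
    ax.axvline(frame.attrs["intersection"], color="k", linestyle=":",
               label="intersection")
    ax.set_xlabel("score")
    ax.set_ylabel("density")
    ax.legend()
    return ax
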