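"""Reading and writing labeled score files (delimited text with a header)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .roc import LabeledScores

__all__ = ["load_labeled_scores", "save_labeled_scores"]


def load_labeled_scores(
    path,
    score_col: str = "score",
    label_col: str = "label",
    flip: bool = False,
    sep: str | None = None,
) -> LabeledScores:
    """Read a CSV/TSV with one row per subject.

    Requires a header with a score column and a binary label column
    (values coercible to 0/1).  ``flip=True`` negates the scores, for tests
    where *lower* values indicate more disorder.  The delimiter is sniffed
    unless ``sep`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:  # sniff the delimiter from the header line
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in (score_col, label_col):
        if col not in df.columns:
            raise ValueError(
                f"missing column {col!r} in {path.name} "
                f"(found: {list(df.columns)})"
            )
    scores = pd.to_numeric(df[score_col], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(scores)):
        bad = df.loc[~np.isfinite(scores), score_col].iloc[0]
        raise ValueError(f"non-numeric or non-finite score value {bad!r}")
    labels = pd.to_numeric(df[label_col], errors="coerce").to_numpy()
    if np.any(pd.isna(labels)) or not np.all(np.isin(labels, [0, 1])):
        bad = df[label_col][~pd.Series(labels).isin([0, 1]).to_numpy()].iloc[0]
        raise ValueError(f"label values must be 0 or 1, got {bad!r}")
    if flip:
        scores = -scores
    return LabeledScores(scores, labels.astype(int))


def save_labeled_scores(data: LabeledScores, path, sep: str = ",") -> None:
    """Write scores and labels with a `score,label` header (round-trips with
    load_labeled_scores)."""
    pd.DataFrame({"score": data.scores, "label": data.labels}).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )
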