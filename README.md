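# trithresh

Trichotomization of diagnostic test scores: the **Uncertain Interval** method,
the **TG-ROC** comparator, and the classical single-threshold criteria, with a
binormal Monte-Carlo harness for comparing them.

## The problem

A continuous diagnostic test (a biomarker level, a risk probability from a
logistic model) is usually dichotomized at a single cutpoint, most often the
one maximizing the Youden index J = Se + Sp − 1. But every cutpoint sits in
the overlap region of the two score distributions — precisely where the test
is least informative — so a fixed share of patients near the cutpoint is
misclassified no matter where it is placed.

The Uncertain Interval method instead *withholds* a decision for scores near
the point where the densities of the condition-absent (D0) and
condition-present (D1) distributions intersect. At the intersection a score
carries no diagnostic information: P(diseased | score) ≈ P(healthy | score).
The method searches for the widest score interval [l, u] around the
intersection in which correct and false calls stay nearly balanced,

- within-interval Se = TP/(TP + FN) ≤ s, and
- within-interval Sp = TN/(TN + FP) ≤ s,

with TN/FN counted at or below the intersection and TP/FP above it, and
s = 0.55 by default (equivalently TP/FN ≤ 1.22 and TN/FP ≤ 1.22 — a small
tolerated bias over perfect balance at 0.5). Scores below the interval are
called negative, scores above it positive; this *More Certain Interval* (MCI)
attains a systematically higher correct classification rate (CCR) than any
single threshold, because most misclassifications live inside the interval.

TG-ROC, the established trichotomization alternative, plots Se(t) and Sp(t)
against the threshold t and declares the scores between the Se-attaining and
Sp-attaining thresholds (at a pre-selected level, 0.90 or 0.95) an
*Intermediate Range*. The package implements the nonparametric variant,
including the boundary re-reversal needed for strong tests, and exposes the
achieved — rather than the claimed — valid-range Se/Sp.

## What the package provides

| module | contents |
| --- | --- |
| `trithresh.roc` | `LabeledScores`, confusion counts, ROC curve, Mann–Whitney and analytic binormal AUC |
| `trithresh.thresholds` | Youden, maxSe, maxSp, MinPvalue, ROC01, SpEqualSe, fixed cutpoints |
| `trithresh.uncertain` | intersection estimation (KDE/normal), the Uncertain Interval search, 3×2 decision tables, Yates χ², Welch t |
| `trithresh.tgroc` | nonparametric TG-ROC with re-reversal |
| `trithresh.simulate` | the 27-model binormal grid, per-model Monte-Carlo summaries |
| `trithresh.viz` | mixed probability histogram, TG-ROC curves, density/intersection plots |
| `trithresh.io` / `trithresh.fixtures` | CSV/TSV reading, the synthetic clinical fixture |

A thin CLI (`trithresh dichotomize|ui|tgroc|simulate|plot|fixture`) wraps the
library; `examples/` holds short narrative scripts, one per capability.

## Worked example

```sh
python examples/find_interval.py
```

```
model 4: diseased N(3.0, 1.0^2), prevalence 0.5, analytic AUC 0.983
empirical AUC 0.981

Youden threshold 1.497: CCR 0.930  Se 0.922  Sp 0.938
Uncertain Interval [1.085, 1.768] around intersection 1.437: 88 subjects, within-interval CCR 0.545
outside it (MCI):  CCR 0.964  Se 0.963  Sp 0.965
TG-ROC intermediate range [1.213, 1.683] (reversed: True); valid-range CCR 0.953
```

Reading: the best single threshold classifies 93.0% of all 1000 subjects
correctly. Declaring the 88 subjects in [1.085, 1.768] "uncertain" — their
within-interval CCR of 0.545 shows a decision there is barely better than a
coin flip — lifts the CCR for the remaining 912 subjects to 0.964.

`examples/clinical_tables.py` prints the 380-subject clinical-style decision
table (MCI CCR 0.873, within-interval CCR 0.545, balance χ² = 0.788 on 1 df),
and `examples/simulation_row.py` reproduces one row of the Monte-Carlo
comparison grid.

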