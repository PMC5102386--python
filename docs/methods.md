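# Methods

## Model and conventions

Scores are real-valued with the fixed orientation *higher = more disorder*;
a subject is called positive when its score is **greater than or equal to**
the decision threshold (ties go positive). Sensitivity, specificity and the
correct classification rate are the usual ratios Se = TP/(TP+FN),
Sp = TN/(TN+FP), CCR = (TP+TN)/n. The empirical AUC is the Mann–Whitney
statistic (ties counted ½), which equals the trapezoidal area under the
empirical ROC curve; for a binormal pair it has the closed form
AUC = Φ((μ₁−μ₀)/√(σ₀²+σ₁²)), independent of prevalence.

Tests whose orientation is reversed should be loaded with the `flip` option
(score negation) rather than handled by per-method branches.

## Intersection estimation

The Uncertain Interval is anchored at the score where the two class
densities cross. Two estimators are provided:

* **kde** (default): a Gaussian kernel density estimate per class with
  Silverman's robust rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5),
  evaluated on a shared 512-point grid over the observed score range;
  crossings are located by sign change with linear interpolation.
* **normal**: per-class mean/sd fits and the exact root of the log-density
  equation (a quadratic; the equal-variance case degenerates to the midpoint
  of the means).

Both return the crossing nearest the midpoint of the class means. Candidate
crossings are accepted inside the between-means interval **widened by half a
class standard deviation on each side**: for nearly-equal-spread classes the
true crossing can sit marginally beyond a *sample* mean, and a strict
between-means rule would spuriously reject a large fraction of weak-test
samples. Spurious tail crossings (KDE wiggle far from the overlap region)
fall outside the window and are ignored. No crossing in the window raises
`IntersectionNotFoundError`; the interval search converts this into a
not-found result rather than an exception.

## The Uncertain Interval search

Candidate bounds (l, u) range over the distinct observed scores with
l ≤ intersection ≤ u. For each candidate the within-interval subjects are
split at the intersection (ties at the intersection go to the lower half):
TN/FN at or below it, FP/TP above it. A candidate is *feasible* when

1. all four cells are ≥ 1 (degenerate Se/Sp are never reported, and
   strong tests with empty overlap correctly yield "not found"), and
2. within-interval Se ≤ s and Sp ≤ s for the pre-selected s ∈ (0.5, 1),
   default 0.55.

Among feasible candidates the search returns the one containing the most
subjects, breaking ties by the widest score range and then the smallest
lower bound — a deterministic completion of the qualitative goal of widening
the interval as far as balance permits. The search is exact (it enumerates
all candidate pairs via per-bound prefix sums), so a brute-force scan
reproduces it on any instance; no lower bound is imposed on within-interval
Se/Sp. Interval bounds are inclusive on both sides.

`quality_threshold` reports the 3×2 decision table for any bound pair
(zones score < l, l ≤ score ≤ u, score > u) and the outer-zone (MCI)
metrics, treating below-zone subjects as called negative and above-zone as
positive. `quality_threshold_uncertain` adds the within-interval balance
diagnostics: a Yates-corrected Pearson χ² — Σ(max(|O−E|−0.5, 0))²/E on the
2×2 table [[TN, FN], [FP, TP]], df = 1 — and a Welch two-sample t-test
(healthy vs diseased within-interval scores, Welch–Satterthwaite df). The
continuity-corrected χ² form is fixed deliberately: it is the variant that
reproduces the reference decision-table statistic exactly.

## Single-threshold criteria

All seven comparators scan the same candidate grid: the distinct observed
scores. Youden maximizes Se+Sp−1; maxSe maximizes Se with Sp as tie-break
(and symmetrically maxSp); MinPvalue minimizes the Pearson χ² p-value of the
dichotomized 2×2 table (no continuity correction; degenerate margins score
p = 1); ROC01 minimizes the Euclidean distance of (1−Sp, Se) to (0, 1);
SpEqualSe minimizes |Sp − Se|; `fixed` evaluates a user cutpoint as-is.
Remaining ties always resolve to the smallest threshold, so results are
reproducible. Candidate thresholds are the observed values themselves, not
midpoints — a convention that can shift reported cutpoints by one gap width.

## TG-ROC

The nonparametric variant only. Se(t) is the fraction of positives ≥ t,
Sp(t) the fraction of negatives < t (mirroring the ties-positive call).
The Intermediate Range runs from the largest threshold attaining
Se ≥ level to the smallest attaining Sp ≥ level. For strong tests these
cross; the bounds are swapped back and flagged (`reversed=True`) instead of
collapsing the range to zero, so results exist for every test strength.
Valid-range Se/Sp are *achieved* values computed from the outer zones — the
package never assumes the pre-selected level is met, because for overlapping
tests it often is not. Within-range Se/Sp/CCR use the estimated distribution
intersection as the internal cut (clamped into the range; midpoint fallback)
so the two trichotomizations are scored identically.

## Simulation design

The grid crosses μ₁ ∈ {3, 2, 1}, σ₁ ∈ {0.6, 1.0, 1.5} and prevalence
∈ {0.5, 0.2, 0.1} (27 models, ordered μ₁ descending, σ₁ ascending,
prevalence descending); the healthy class is always N(0, 1). Replicates use
**fixed class sizes** n₁ = round(n·prev) rather than binomial draws —
lower variance and an unambiguous reading of "n tested individuals at
prevalence p". Per-replicate RNGs are seeded with the triple
(master seed, model id, replicate index), so any replicate can be replayed
in isolation. Per-model aggregates average Uncertain-Interval quantities
over the replicates where an interval was found (their share is reported as
p.NA) and TG-ROC quantities over the replicates where the level was
attainable; the within-range Welch t-test's share of p < 0.05 outcomes is
reported as P(t). Replicate-level failures are counted, never fatal.

Default problem sizes in the tests and the acceptance script are 100–200
replicates of n = 1000 for spot-checked models; the full 1000-replicate ×
27-model grid is supported through `run_grid` / `trithresh simulate` and
simply scales linearly.

## Synthetic data

Two generators stand in for real data:

* `binormal_sample` draws the simulation-grid samples. It emulates exactly
  the binormal world the grid defines — it does **not** produce skewed,
  discrete, bounded or multimodal scores, so passing simulation checks says
  nothing about non-normal tests beyond what the clinical-style fixture
  covers.
* `make_clinical_fixture` places 380 scores deterministically (evenly spaced
  inside each decision zone) so that the zone-by-class counts — and hence
  every count-based statistic: the 3×2 table, MCI and within-interval
  CCR/Se/Sp, the balance χ² — reproduce the reference clinical decision
  tables exactly. Score *values* inside a zone are arbitrary by
  construction; statistics that depend on score magnitudes (the Welch t,
  KDE intersections) are not meaningful on this fixture and are not asserted
  on it.

## Numerical choices and degenerate inputs

* Feasibility/constraint comparisons on count ratios use an absolute
  epsilon of 1e−9 so integer-ratio boundary cases (e.g. Se exactly 0.55)
  are accepted regardless of float rounding.
* An empty candidate interval yields all-zero counts, not an error; MCI
  metrics are flagged undefined when a class is absent from the outer zones.
* `welch_t` requires ≥ 2 observations per sample and non-degenerate
  variance; `chisq_yates` requires positive margins.
* CSV round-trips are bit-exact (`%.17g` on write, round-trip float parsing
  on read).

## Known limitations

* The KDE intersection inherits kernel bias: with strongly unequal spreads
  the estimated crossing shifts by O(bandwidth²), which nudges interval
  bounds; the `normal` estimator is preferable when normality is defensible.
* Aggregates conditioned on "interval found" are means over a
  replicate-dependent subset; for strong tests (large p.NA) they describe
  the easier samples.
* Only two-class problems and a single score column are supported; no
  cost-weighted interval selection, no confidence intervals for AUC.
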