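import numpy as np
import pytest
from scipy import optimize, stats

import trithresh as tt
from _oracles import search_ui_brute, ui_counts_brute
from conftest import random_two_class


def shaped_sample(rng, mu, sd, n):
    """Sample with *exact* sample mean mu and sample sd (ddof=1) sd."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mu + sd * x


def two_normals(rng, mu0, sd0, mu1, sd1, n0=200, n1=200):
    return tt.LabeledScores(
        np.r_[shaped_sample(rng, mu0, sd0, n0), shaped_sample(rng, mu1, sd1, n1)],
        np.r_[np.zeros(n0, int), np.ones(n1, int)],
    )


class TestIntersection:
    def test_equal_variance_midpoint(self):
        d = two_normals(np.random.default_rng(0), 0, 1, 3, 1)
        assert tt.estimate_intersection(d, "normal") == pytest.approx(1.5, abs=1e-9)

    def test_unequal_variance_matches_numeric_root(self):
        # independent oracle: root of the density difference, found numerically
        diff = lambda x: stats.norm.pdf(x, 0, 1) - stats.norm.pdf(x, 3, 0.6)
        root = optimize.brentq(diff, 0.5, 2.9)
        assert root == pytest.approx(1.7746, abs=5e-4)
        d = two_normals(np.random.default_rng(1), 0, 1, 3, 0.6)
        assert tt.estimate_intersection(d, "normal") == pytest.approx(root, abs=1e-6)

    def test_kde_consistent_with_normal(self):
        d = two_normals(np.random.default_rng(2), 0, 1, 2, 1, n0=2000, n1=2000)
        kde = tt.estimate_intersection(d, "kde")
        normal = tt.estimate_intersection(d, "normal")
        assert kde == pytest.approx(normal, abs=0.08)

    def test_no_crossing_raises(self):
        # far-separated identical-spread classes: crossing at the midpoint is
        # outside the widened window only if means coincide; use equal means
        # with equal sds, where no crossing exists at all
        rng = np.random.default_rng(3)
        d = two_normals(rng, 0, 1, 0, 1)
        with pytest.raises(tt.IntersectionNotFoundError):
            tt.estimate_intersection(d, "normal")


class TestUiCounts:
    def test_clinical_within_interval_split(self, clinical):
        c = tt.ui_counts(clinical.data, clinical.lower, clinical.upper,
                         clinical.intersection)
        assert (c.tn, c.fn, c.fp, c.tp) == (47, 26, 39, 31)
        assert round(c.sp, 3) == 0.547
        assert round(c.se, 3) == 0.544
        assert round(c.ccr, 3) == 0.545

    def test_empty_interval_all_zero(self, clinical):
        below = clinical.data.scores.min() - 1.0
        c = tt.ui_counts(clinical.data, below, below, below)
        assert c.n == 0


class TestChisqYates:
    def test_clinical_balance_table(self):
        stat, df, p = tt.chisq_yates([[47, 26], [39, 31]])
        assert round(stat, 3) == 0.788
        assert df == 1
        assert round(p, 3) == 0.375

    def test_balanced_table_is_zero(self):
        stat, _, p = tt.chisq_yates([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_value(self):
        # all expected counts are 15; statistic = 4 * (4.5^2 / 15) = 5.4
        stat, _, _ = tt.chisq_yates([[20, 10], [10, 20]])
        assert stat == pytest.approx(5.4, abs=1e-12)

    def test_matches_scipy_continuity_correction(self):
        table = [[13, 8], [5, 21]]
        stat, _, p = tt.chisq_yates(table)
        ref = stats.chi2_contingency(np.array(table), correction=True)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            tt.chisq_yates([[0, 0], [5, 5]])


class TestWelchT:
    def test_identical_samples(self):
        t, _, p = tt.welch_t([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed(self):
        t, df, _ = tt.welch_t([0.0, 1.0], [10.0, 11.0])
        assert t == pytest.approx(-10 / np.sqrt(0.5), abs=1e-9)
        assert df == pytest.approx(2.0, abs=1e-9)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            tt.welch_t([1.0, 1.0], [2.0, 2.0])


class TestFindUncertainInterval:
    def test_complete_mixing_covers_most_subjects(self):
        rng = np.random.default_rng(7)
        d = tt.LabeledScores(
            np.r_[rng.normal(0, 1, 400), rng.normal(0, 1, 400)],
            np.r_[np.zeros(400, int), np.ones(400, int)],
        )
        ui = tt.find_uncertain_interval(d)
        assert ui.found
        assert ui.n_inside > 0.6 * d.n
        assert ui.ui_se <= 0.55 + 1e-9 and ui.ui_sp <= 0.55 + 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        d = random_two_class(rng, n=30, ties=(seed % 2 == 0))
        inter = float(np.median(d.scores))
        ui = tt.find_uncertain_interval(d, select=0.55, intersection=inter)
        oracle = search_ui_brute(
            d.scores.tolist(), d.labels.tolist(), inter, select=0.55
        )
        if oracle is None:
            assert not ui.found
        else:
            lo, up, cells = oracle
            assert ui.found
            assert (ui.lower, ui.upper) == (lo, up)
            assert (ui.ui_counts.tn, ui.ui_counts.fn,
                    ui.ui_counts.fp, ui.ui_counts.tp) == cells

    @pytest.mark.parametrize("select", [0.55, 0.6, 0.75])
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_constraints_always_hold(self, select, seed):
        rng = np.random.default_rng(seed)
        d = random_two_class(rng, n=80)
        ui = tt.find_uncertain_interval(d, select=select)
        if ui.found:
            assert ui.ui_se <= select + 1e-9
            assert ui.ui_sp <= select + 1e-9
            assert ui.lower <= ui.intersection <= ui.upper
            assert min(ui.ui_counts.tn, ui.ui_counts.fn,
                       ui.ui_counts.fp, ui.ui_counts.tp) >= 1

    def test_select_out_of_range_rejected(self):
        d = tt.LabeledScores([1, 2, 3, 4], [0, 0, 1, 1])
        with pytest.raises(ValueError, match="select"):
            tt.find_uncertain_interval(d, select=0.4)


class TestQualityThreshold:
    def test_clinical_decision_table(self, clinical):
        tri = tt.quality_threshold(clinical.data, clinical.lower, clinical.upper)
        assert tri.decision_table[0].tolist() == [124, 86, 17]
        assert tri.decision_table[1].tolist() == [13, 57, 83]
        assert round(tri.mci_ccr, 3) == 0.873
        assert round(tri.mci_se, 3) == 0.865
        assert round(tri.mci_sp, 3) == 0.879

    def test_margins_conserve_class_sizes(self):
        rng = np.random.default_rng(21)
        d = random_two_class(rng, n=37)
        lo, hi = np.quantile(d.scores, [0.3, 0.7])
        tri = tt.quality_threshold(d, lo, hi)
        assert tri.decision_table[0].sum() == d.n0
        assert tri.decision_table[1].sum() == d.n1
        assert tri.n_inside + tri.n_outside == d.n

    def test_degenerate_zone_reduces_to_dichotomy(self):
        rng = np.random.default_rng(22)
        d = random_two_class(rng, n=25)
        t = float(np.median(np.unique(d.scores))) + 1e-9  # between scores
        tri = tt.quality_threshold(d, t, t)
        c = tt.confusion_at(d, t)
        assert tri.n_inside == 0
        assert tri.mci_ccr == pytest.approx(c.ccr)
        assert tri.mci_se == pytest.approx(c.se)
        assert tri.mci_sp == pytest.approx(c.sp)

    def test_all_inside_flags_undefined(self):
        d = tt.LabeledScores([1, 2, 3, 4], [0, 0, 1, 1])
        tri = tt.quality_threshold(d, 0, 5)
        assert not tri.mci_defined


class TestQualityThresholdUncertain:
    def test_clinical_report(self, clinical):
        ui = tt.UncertainIntervalResult(
            found=True, lower=clinical.lower, upper=clinical.upper,
            intersection=clinical.intersection,
        )
        rep = tt.quality_threshold_uncertain(clinical.data, ui)
        assert rep.tests_defined
        assert round(rep.chi2, 3) == 0.788
        assert rep.chi2_df == 1
        assert round(rep.chi2_p, 3) == 0.375
        assert round(rep.ui_ccr, 3) == 0.545

    def test_requires_found_interval(self, clinical):
        with pytest.raises(ValueError, match="found"):
            tt.quality_threshold_uncertain(
                clinical.data, tt.UncertainIntervalResult(found=False)
            )


class TestMonotoneTransformInvariance:
    def test_count_outputs_invariant(self):
        rng = np.random.default_rng(30)
        d = random_two_class(rng, n=45)
        f = lambda x: np.exp(x / 2) + x**3 / 50  # strictly increasing
        d2 = tt.LabeledScores(f(d.scores), d.labels)
        lo, mid, hi = np.quantile(d.scores, [0.25, 0.5, 0.75])

        c1 = tt.ui_counts(d, lo, hi, mid)
        c2 = tt.ui_counts(d2, f(lo), f(hi), f(mid))
        assert (c1.tn, c1.fn, c1.fp, c1.tp) == (c2.tn, c2.fn, c2.fp, c2.tp)

        t1 = tt.quality_threshold(d, lo, hi)
        t2 = tt.quality_threshold(d2, f(lo), f(hi))
        assert t1.decision_table.equals(t2.decision_table)

        for method in ("youden", "maxSe", "maxSp", "roc01", "spEqualSe"):
            r1 = tt.optimal_threshold(d, method)
            r2 = tt.optimal_threshold(d2, method)
            assert r2.threshold == pytest.approx(f(np.array([r1.threshold]))[0])
            assert (r1.se, r1.sp) == (r2.se, r2.sp)
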