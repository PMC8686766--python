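"""Clinical statistics: t tests from summaries, Fisher exact, classical
group comparisons, Kaplan-Meier / log-rank and annual-change slopes."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import proteotype as pt
from proteotype.data import ClinicalTable, DataError

from conftest import make_clinical


class TestTwoSampleT:
    def test_summary_matches_raw(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1.3, 20)
        for variant in ("pooled", "welch"):
            raw = pt.two_sample_t(a, b, variant=variant)
            summ = pt.two_sample_t(
                (len(a), a.mean(), a.std(ddof=1)),
                (len(b), b.mean(), b.std(ddof=1)),
                variant=variant,
            )
            assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
            assert raw.p == pytest.approx(summ.p, abs=1e-12)

    def test_identical_summaries(self):
        res = pt.two_sample_t((10, 5.0, 1.0), (10, 5.0, 1.0))
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_pooled_equals_welch_for_equal_groups(self):
        pooled = pt.two_sample_t((20, 3.0, 1.5), (20, 4.0, 1.5), variant="pooled")
        welch = pt.two_sample_t((20, 3.0, 1.5), (20, 4.0, 1.5), variant="welch")
        assert pooled.statistic == pytest.approx(welch.statistic, abs=1e-12)
        assert pooled.p == pytest.approx(welch.p, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(DataError):
            pt.two_sample_t((1, 5.0, 1.0), (10, 5.0, 1.0))


def exhaustive_fisher_two_sided(table):
    """Two-sided Fisher p: sum of probabilities of all fixed-margin tables
    no more probable than the observed one (independent enumeration)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1) if prob(x) <= p_obs * (1 + 1e-12))


class TestFisherExact:
    def test_balanced_table(self):
        assert pt.fisher_exact([[5, 5], [5, 5]]).p == pytest.approx(1.0)

    def test_enumeration_oracle(self):
        for table in ([[1, 9], [9, 1]], [[2, 8], [6, 4]], [[0, 5], [5, 0]]):
            res = pt.fisher_exact(table)
            assert res.p == pytest.approx(exhaustive_fisher_two_sided(table), rel=1e-12)

    def test_zero_margin_degenerate(self):
        res = pt.fisher_exact([[0, 0], [3, 4]])
        assert res.degenerate and res.p == 1.0

    def test_non_integer_rejected(self):
        with pytest.raises(DataError):
            pt.fisher_exact([[1.5, 2], [3, 4]])

    def test_cohort_sex_and_smoking_tables(self):
        # female sex 2/34 vs 21/51 is strongly imbalanced ...
        assert pt.fisher_exact([[2, 32], [21, 30]]).p < 0.001
        # ... while current smokers 8/34 vs 7/51 is not (p rounds to 0.26)
        assert pt.fisher_exact([[8, 26], [7, 44]]).p == pytest.approx(0.26, abs=0.005)


class TestGroupCompare:
    def test_identical_groups_anova(self):
        values = [1.0, 2.0, 3.0] * 3
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = pt.group_compare(values, groups, "anova")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_mann_whitney_exact_small_case(self):
        # complete separation of {1,2,3} and {4,5,6}: two-sided exact
        # p = 2 / C(6,3) = 0.1
        res = pt.group_compare([1, 2, 3, 4, 5, 6], list("aaabbb"), "mann_whitney")
        assert res.p == pytest.approx(0.1)

    def test_kruskal_equals_mann_whitney_asymptotically(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 21), rng.normal(0.5, 1, 21)])
        groups = ["a"] * 21 + ["b"] * 21
        kw = pt.group_compare(values, groups, "kruskal_wallis")
        mw = pt.group_compare(values, groups, "mann_whitney")
        assert kw.p == pytest.approx(mw.p, abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(DataError):
            pt.group_compare([1, 2, 3], ["a"] * 3, "anova")

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            pt.group_compare([1, 2, 3, 4], ["a", "a", "b", "b"], "median_test")


def hand_logrank(times, events, groups):
    """Observed-minus-expected log-rank chi-squared, aggregated at event
    times (independent textbook computation)."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    ga = groups == np.unique(groups)[0]
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & ga).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & ga).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKMLogrank:
    def test_identical_groups(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [True] * 6
        res = pt.km_logrank(times, events, ["a"] * 3 + ["b"] * 3)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_worked_example(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [True] * 6
        groups = ["a", "a", "a", "b", "b", "b"]
        res = pt.km_logrank(times, events, groups)
        assert res.chi2 == pytest.approx(hand_logrank(times, events, groups), rel=1e-9)
        assert res.df == 1

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(2.0, 40)
        res = pt.km_logrank(
            np.concatenate([times, [1.0]]),
            [True] * 41,
            ["a"] * 40 + ["b"],
        )
        curve = res.curves["a"]
        for t, s in zip(curve["time"], curve["survival"]):
            assert s == pytest.approx((times > t).mean() + 1e-15, abs=1e-12)

    def test_null_permutation_p_uniform(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(3.0, 40)
        events = times <= 5.0
        times = np.minimum(times, 5.0)
        ps = []
        for _ in range(300):
            groups = rng.permutation(["a"] * 20 + ["b"] * 20)
            ps.append(pt.km_logrank(times, events, groups).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            pt.km_logrank([1.0, 2.0], [True, True], ["a", "a"])


class TestAnnualChange:
    def _clinical_with_visits(self, slopes, noise_sd=0.0, seed=0, n_visits=6):
        rng = np.random.default_rng(seed)
        n = len(slopes)
        clin = make_clinical(n, diseases=["COPD"] * n)
        rows = []
        for i, sid in enumerate(clin.subject_ids):
            for t in range(n_visits):
                rows.append(
                    {
                        "subject_id": sid,
                        "time_years": float(t),
                        "kco": 1.2 + slopes[i] * t + rng.normal(0, noise_sd),
                        "fev1": 2.0,
                    }
                )
        return ClinicalTable(clin.subjects, pd.DataFrame(rows))

    def test_noiseless_slope_exact(self):
        clin = self._clinical_with_visits([-0.08, 0.02])
        res = pt.annual_change(clin, "kco")
        assert res.per_subject["slope"].iloc[0] == pytest.approx(-0.08, abs=1e-12)
        assert res.per_subject["slope"].iloc[1] == pytest.approx(0.02, abs=1e-12)

    def test_bias_small_under_noise(self):
        true = -0.08
        clin = self._clinical_with_visits([true] * 1000, noise_sd=0.05, seed=1)
        res = pt.annual_change(clin, "kco")
        bias = res.per_subject["slope"].mean() - true
        assert abs(bias) <= 0.005

    def test_single_visit_subject_excluded_and_named(self):
        clin = self._clinical_with_visits([-0.05, -0.05])
        visits = clin.visits[
            ~((clin.visits["subject_id"] == "S001") & (clin.visits["time_years"] > 0))
        ]
        clin = ClinicalTable(clin.subjects, visits)
        res = pt.annual_change(clin, "kco")
        assert res.excluded == ["S001"]
        assert "S001" not in res.per_subject.index

    def test_group_statistics(self):
        clin = self._clinical_with_visits([-0.08, -0.08, -0.005, -0.005])
        groups = pd.Series([1, 1, 2, 2], index=clin.subject_ids)
        res = pt.annual_change(clin, "kco", groups=groups)
        assert res.group_stats.loc[1, "mean_slope"] == pytest.approx(-0.08)
        assert res.group_stats.loc[2, "mean_slope"] == pytest.approx(-0.005)

    def test_no_usable_subject_rejected(self):
        clin = make_clinical(3, diseases=["COPD"] * 3)
        with pytest.raises(DataError):
            pt.annual_change(clin, "kco")
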