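"""From-scratch survival estimators and tests against independent oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lifespankit.errors import (
    NotComputableError,
    UndefinedMedianError,
    ValidationError,
)
from lifespankit.simulate import SimulationConfig, gompertz_median_days, sample_gompertz
from lifespankit.survival import (
    TieWarning,
    daily_chisquare_scan,
    fisher_exact_2x2,
    kaplan_meier,
    logrank_test,
    max_lifespan_test,
    median_survival,
    pearson_chi2_2x2,
    percent_change,
    ttest_unpaired,
)

from conftest import fisher_two_sided_oracle, make_cohort


class TestKaplanMeier:
    def test_uniform_all_events(self):
        curve = kaplan_meier(make_cohort([1, 2, 3, 4, 5]))
        assert np.allclose(curve.survival_prob, [0.8, 0.6, 0.4, 0.2, 0.0])
        assert list(curve.n_at_risk) == [5, 4, 3, 2, 1]

    def test_single_mouse(self):
        curve = kaplan_meier(make_cohort([100]))
        assert curve.survival_at(100) == 0.0
        assert curve.survival_at(99) == 1.0

    def test_censoring_hand_oracle(self):
        # deaths at 1,3,4,5,6; censored at 2: S = 5/6, then x3/4, x2/3, x1/2, x0
        curve = kaplan_meier(
            make_cohort([1, 2, 3, 4, 5, 6],
                        events=[1, 0, 1, 1, 1, 1])
        )
        expected = [5 / 6, 5 / 6 * 3 / 4, 5 / 6 * 3 / 4 * 2 / 3,
                    5 / 6 * 3 / 4 * 2 / 3 / 2, 0.0]
        assert np.allclose(curve.survival_prob, expected)

    def test_no_censoring_matches_empirical_survival(self, rng):
        days = rng.integers(1, 1000, size=80)
        curve = kaplan_meier(make_cohort(days))
        for t in np.unique(days):
            assert curve.survival_at(t) == pytest.approx(np.mean(days > t))

    def test_matches_lifelines_with_censoring(self, rng):
        lifelines = pytest.importorskip("lifelines")
        days = rng.integers(1, 400, size=60)
        events = rng.uniform(size=60) < 0.7
        curve = kaplan_meier(make_cohort(days, events=events))
        kmf = lifelines.KaplanMeierFitter().fit(days, events)
        for t, s in zip(curve.event_times, curve.survival_prob):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_empty_cohort_errors(self):
        with pytest.raises(ValidationError):
            kaplan_meier(make_cohort([]))


class TestMedianSurvival:
    def test_all_events_odd(self):
        assert median_survival(kaplan_meier(make_cohort([1, 2, 3, 4, 5]))) == 3

    def test_plateau_midpoint_convention(self):
        # S = 0.75, 0.50, 0.25, 0 -> plateau at exactly 0.5 from t=2 to t=3
        assert median_survival(kaplan_meier(make_cohort([1, 2, 3, 4]))) == 2.5

    def test_undefined_median_signalled(self):
        curve = kaplan_meier(
            make_cohort([10, 20, 30, 40], events=[1, 0, 0, 0])
        )
        with pytest.raises(UndefinedMedianError):
            median_survival(curve)

    def test_gompertz_median_recovery(self, rng):
        config = SimulationConfig()
        days = sample_gompertz(config, 10_000, rng=rng)
        med = median_survival(kaplan_meier(make_cohort(days)))
        closed = gompertz_median_days(config.gompertz_a, config.gompertz_b)
        assert med == pytest.approx(closed, rel=0.01)


class TestPercentChange:
    def test_study_female_medians(self):
        # +20.6% over the wt median of 623 days puts the mutant at 751.5
        assert percent_change(623, 751.5) == pytest.approx(20.6, abs=0.05)

    def test_no_change(self):
        assert percent_change(100, 100) == 0.0

    def test_ud_free_female_medians(self):
        assert percent_change(740, 860.5) == pytest.approx(16.3, abs=0.05)

    def test_zero_baseline_errors(self):
        with pytest.raises(ValidationError):
            percent_change(0, 10)


class TestLogrank:
    def test_identical_cohorts(self):
        a = make_cohort([100, 200, 300], prefix="a")
        b = make_cohort([100, 200, 300], prefix="b")
        res = logrank_test(a, b)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_table_oracle(self):
        # A={1,2}, B={3,4}: O_A=2, E_A=1/2+1/3, V=1/4+2/9 -> stat=49/17
        res = logrank_test(make_cohort([1, 2], prefix="a"),
                           make_cohort([3, 4], prefix="b"))
        assert res.statistic == pytest.approx(49 / 17)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(49 / 17, 1)))

    def test_symmetry_under_group_swap(self, rng):
        a = make_cohort(rng.integers(1, 500, size=30), prefix="a")
        b = make_cohort(rng.integers(1, 700, size=25), prefix="b")
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for _ in range(5):
            ta = rng.integers(1, 600, size=40)
            tb = rng.integers(1, 600, size=35)
            ea = rng.uniform(size=40) < 0.8
            eb = rng.uniform(size=35) < 0.8
            mine = logrank_test(make_cohort(ta, events=ea, prefix="a"),
                                make_cohort(tb, events=eb, prefix="b"))
            ref = lifelines.statistics.logrank_test(ta, tb, ea, eb)
            assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
            assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_errors(self):
        a = make_cohort([1, 2], events=[0, 0], prefix="a")
        b = make_cohort([3, 4], events=[0, 0], prefix="b")
        with pytest.raises(NotComputableError):
            logrank_test(a, b)


class TestFisherExact:
    def test_decile_membership_table(self):
        # 1 of 50 wt vs 9 of 50 mutant mice in the pooled top decile
        assert fisher_exact_2x2([[1, 49], [9, 41]]).p_value == pytest.approx(
            0.0157, abs=5e-5
        )

    def test_identical_rows(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == 1.0

    def test_enumeration_oracle_all_small_margins(self):
        # every table with both row sums <= 12 against exact-rational enumeration
        for r1 in range(1, 13):
            for r2 in range(1, 13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        table = [[a, r1 - a], [c, r2 - c]]
                        if a + c == 0 or (r1 - a) + (r2 - c) == 0:
                            continue
                        mine = fisher_exact_2x2(table).p_value
                        oracle = fisher_two_sided_oracle(a, r1 - a, c, r2 - c)
                        assert mine == pytest.approx(oracle, rel=1e-9), table

    @settings(max_examples=60, derandomize=True)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_invariance_under_swaps_and_transpose(self, cells):
        a, b, c, d = cells
        if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
            return
        p = fisher_exact_2x2([[a, b], [c, d]]).p_value
        assert fisher_exact_2x2([[c, d], [a, b]]).p_value == pytest.approx(p)
        assert fisher_exact_2x2([[b, a], [d, c]]).p_value == pytest.approx(p)
        assert fisher_exact_2x2([[a, c], [b, d]]).p_value == pytest.approx(p)

    def test_negative_cell_errors(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


class TestTTest:
    def test_identical_samples(self):
        res = ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_pooled_formula(self):
        # means 2 and 3, pooled variance 1 -> t = -1/sqrt(2/3), df = 4
        res = ttest_unpaired([1, 2, 3], [2, 3, 4])
        t_expected = -1 / math.sqrt(2 / 3)
        assert res.statistic == pytest.approx(t_expected)
        assert res.df == 4
        assert res.p_value == pytest.approx(
            2 * float(stats.t.sf(abs(t_expected), 4))
        )

    def test_matches_scipy(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(0.5, 2.0, size=9)
        mine = ttest_unpaired(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue)
        mine_w = ttest_unpaired(x, y, welch=True)
        ref_w = stats.ttest_ind(x, y, equal_var=False)
        assert mine_w.statistic == pytest.approx(ref_w.statistic)
        assert mine_w.p_value == pytest.approx(ref_w.pvalue)

    def test_zero_variance_conventions(self):
        assert ttest_unpaired([2, 2, 2], [2, 2]).p_value == 1.0
        res = ttest_unpaired([2, 2, 2], [3, 3])
        assert res.p_value == 0.0 and math.isinf(res.statistic)


class TestMaxLifespan:
    def test_nine_of_ten_mutant(self, rng):
        # two 50-mouse cohorts arranged so 9 of the pooled top 10 are mutant
        wt = make_cohort(np.arange(500, 550), prefix="w")
        mu = make_cohort(np.concatenate([np.arange(460, 501), np.arange(551, 560)]),
                         prefix="u", genotype="mutant")
        res = max_lifespan_test(wt, mu)
        assert res.top_set_size == 10
        assert res.count_in_top == (1, 9)
        assert res.fisher.p_value == pytest.approx(0.0157, abs=5e-5)

    def test_identical_cohorts_split_evenly(self):
        a = make_cohort(np.arange(100, 150), prefix="m")
        b = make_cohort(np.arange(100, 150), prefix="m", genotype="mutant")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", TieWarning)
            res = max_lifespan_test(a, b)
        assert res.count_in_top == (5, 5)
        assert res.fisher.p_value == 1.0

    def test_q_one_uses_whole_cohorts(self):
        a = make_cohort([1, 2, 3], prefix="a")
        b = make_cohort([4, 5, 6], prefix="b")
        res = max_lifespan_test(a, b, q=1.0)
        assert res.count_in_top == (3, 3)
        assert res.fisher.p_value == 1.0

    def test_censored_record_rejected(self):
        a = make_cohort([1, 2, 3], events=[1, 1, 0], prefix="a")
        b = make_cohort([4, 5, 6], prefix="b")
        with pytest.raises(ValidationError):
            max_lifespan_test(a, b)

    def test_shifted_cohort_dominates_membership(self):
        # +15% uniform shift: the shifted arm holds >= half the top decile in
        # at least 99% of 1000 seeded replicates
        rng = np.random.default_rng(11)
        config = SimulationConfig()
        wins = 0
        n_reps = 1000
        for _ in range(n_reps):
            base = sample_gompertz(config, 50, rng=rng)
            shifted = np.maximum(1, np.rint(base[::-1] * 1.15).astype(int))
            a = make_cohort(base, prefix="a")
            b = make_cohort(shifted, prefix="b", genotype="mutant")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", TieWarning)
                res = max_lifespan_test(a, b)
            if res.count_in_top[1] >= res.count_in_top[0]:
                wins += 1
        assert wins / n_reps >= 0.99

    def test_top_mean_percent_diff_sign(self):
        a = make_cohort(np.arange(100, 150), prefix="a")
        b = make_cohort(np.arange(200, 250), prefix="b", genotype="mutant")
        res = max_lifespan_test(a, b)
        assert res.top_mean_percent_diff > 0
        assert res.top_mean[0][0] < res.top_mean[1][0]


class TestDailyChiSquare:
    def test_identical_groups_no_windows(self):
        a = make_cohort([100, 200, 300, 400], prefix="a")
        b = make_cohort([100, 200, 300, 400], prefix="b")
        assert daily_chisquare_scan(a, b).windows == []

    def test_closed_form_five_vs_zero(self):
        # 5/5 dead-alive vs 0/10 on a day: chi2 = 20*(50)^2/(10*10*5*15) = 20/3
        stat, p = pearson_chi2_2x2(5, 5, 0, 10)
        assert stat == pytest.approx(20 / 3)
        assert p == pytest.approx(float(stats.chi2.sf(20 / 3, 1)))
        a = make_cohort([10] * 5 + [100] * 5, prefix="a")
        b = make_cohort([100] * 10, prefix="b")
        scan = daily_chisquare_scan(a, b)
        day_idx = np.where(scan.days == 50)[0][0]
        assert scan.p_per_day[day_idx] == pytest.approx(p)

    def test_window_bookkeeping(self):
        a = make_cohort([10] * 5 + [100] * 5, prefix="a")
        b = make_cohort([100] * 10, prefix="b")
        scan = daily_chisquare_scan(a, b)
        assert len(scan.windows) == 1
        start, end, n_deaths = scan.windows[0]
        assert start == 10 and end == 99
        assert n_deaths == 5  # the five early deaths fall inside the run

    def test_degenerate_margins_flagged(self):
        a = make_cohort([5, 6], prefix="a")
        b = make_cohort([5, 7], prefix="b")
        scan = daily_chisquare_scan(a, b)
        # final day: everyone dead -> alive margin zero -> p = 1 by convention
        assert scan.p_per_day[-1] == 1.0
        assert scan.degenerate_days >= 1

    def test_early_excess_hazard_detected(self):
        # arm b has 3x hazard before day 600, equal after: the significant
        # window overlaps the excess period in >= 95% of seeded replicates
        config = SimulationConfig()
        rng = np.random.default_rng(5)
        hits = 0
        n_reps = 100
        for _ in range(n_reps):
            t_a = sample_gompertz(config, 50, rng=rng)
            t_b0 = sample_gompertz(config, 50, rng=rng, hazard_scale=3.0)
            # keep the excess only below day 600; redraw survivors from the
            # conditional baseline law by inverse CDF beyond day 600
            t_b = t_b0.copy()
            survivors = t_b0 > 600
            n_s = int(survivors.sum())
            if n_s:
                a, bb = config.gompertz_a, config.gompertz_b
                u = rng.uniform(size=n_s)
                h0 = (a / bb) * (math.exp(bb * 600) - 1.0)
                t_new = (1.0 / bb) * np.log1p(
                    (bb / a) * (h0 - np.log(u))
                )
                t_b[survivors] = np.rint(t_new).astype(int)
            scan = daily_chisquare_scan(
                make_cohort(t_a, prefix="a"), make_cohort(t_b, prefix="b")
            )
            if any(s <= 600 for s, e, _ in scan.windows):
                hits += 1
        assert hits / n_reps >= 0.95

    def test_censoring_rejected(self):
        a = make_cohort([1, 2], events=[1, 0], prefix="a")
        b = make_cohort([3, 4], prefix="b")
        with pytest.raises(ValidationError):
            daily_chisquare_scan(a, b)
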