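import numpy as np
import pandas as pd
import pytest

import mrsurv
from conftest import make_survival_frame
from _oracles import maximize_partial_loglik
from mrsurv.survival import EffectEstimate, supremum_linearity_test

Z975 = 1.959963984540054


class TestFitCox:
    def test_matches_brute_force_partial_likelihood(self, small_cox_data):
        fit = mrsurv.fit_cox(small_cox_data, "x")
        oracle = maximize_partial_loglik(small_cox_data["follow_up"],
                                         small_cox_data["event"],
                                         small_cox_data["x"])
        assert fit.params["x"] == pytest.approx(oracle, abs=1e-4)

    def test_two_group_exponential_recovery(self):
        # groups with true rate ratio 2: log-HR CI covers ln 2 ~95% of runs
        rng = np.random.default_rng(21)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            grp = rng.integers(0, 2, 500)
            t = rng.exponential(1.0 / (0.2 * 2.0**grp))
            c = rng.uniform(1, 4, 500)
            df = pd.DataFrame({"follow_up": np.minimum(t, c),
                               "event": (t <= c).astype(int),
                               "g": grp.astype(float)})
            e = mrsurv.fit_cox(df, "g").estimate("g")
            hits += e.ci_lower <= 2.0 <= e.ci_upper
        assert hits >= 32

    def test_permuted_exposure_is_null(self):
        rng = np.random.default_rng(5)
        rej = 0
        n_rep = 40
        for _ in range(n_rep):
            df = make_survival_frame(rng, n=250, beta=0.5)
            df["z"] = rng.permutation(df["z"].to_numpy())
            rej += mrsurv.fit_cox(df, "z").estimate("z").p < 0.05
        assert rej <= 8

    def test_zero_events_error(self):
        df = pd.DataFrame({"follow_up": [1.0, 2.0], "event": [0, 0],
                           "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="events"):
            mrsurv.fit_cox(df, "x")

    def test_nonfinite_followup_error(self):
        df = pd.DataFrame({"follow_up": [1.0, np.inf], "event": [1, 1],
                           "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="follow-up"):
            mrsurv.fit_cox(df, "x")

    def test_robust_and_model_se_agree_asymptotically(self):
        rng = np.random.default_rng(2)
        df = make_survival_frame(rng, n=4000, beta=0.3)
        plain = mrsurv.fit_cox(df, "z")
        robust = mrsurv.fit_cox(df, "z", robust=True)
        assert robust.se("z") / plain.se("z") == pytest.approx(1.0, abs=0.1)


class TestMetaAnalysis:
    def test_identical_estimates_q_zero(self):
        e = EffectEstimate.from_log(0.3, 0.1)
        q, df, p = mrsurv.heterogeneity_q([e, e, e])
        assert q == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_exact_critical_difference_gives_p_05(self):
        se1, se2 = 0.10, 0.15
        delta = Z975 * np.sqrt(se1**2 + se2**2)
        q, df, p = mrsurv.heterogeneity_q(
            [EffectEstimate.from_log(0.0, se1),
             EffectEstimate.from_log(delta, se2)])
        assert p == pytest.approx(0.05, abs=1e-10)

    def test_published_cohort_hrs_heterogeneity_in_range(self):
        # unadjusted cohort HRs 1.55 (1.27-1.90), 1.38 (1.21-1.57),
        # 1.31 (1.11-1.56): printed between-study p is 0.42
        ests = [self._from_ci(*x) for x in
                [(1.55, 1.27, 1.90), (1.38, 1.21, 1.57), (1.31, 1.11, 1.56)]]
        _, _, p = mrsurv.heterogeneity_q(ests)
        assert 0.40 <= p <= 0.48

    @staticmethod
    def _from_ci(hr, lo, hi):
        return EffectEstimate.from_log(np.log(hr),
                                       mrsurv.se_from_ci(hr, lo, hi))

    def test_pooling_reproduces_published_combined_hr(self):
        ests = [self._from_ci(*x) for x in
                [(1.55, 1.27, 1.90), (1.38, 1.21, 1.57), (1.31, 1.11, 1.56)]]
        pooled = mrsurv.pool_fixed_effect(ests)
        assert round(pooled.hr, 2) == 1.39
        assert round(pooled.ci_lower, 2) == 1.27
        assert round(pooled.ci_upper, 2) == 1.53

    def test_single_estimate_returned_unchanged(self):
        e = EffectEstimate.from_log(0.2, 0.05)
        pooled = mrsurv.pool_fixed_effect([e])
        assert pooled.estimate == pytest.approx(e.estimate)
        assert pooled.se == pytest.approx(e.se)

    def test_two_identical_estimates_halve_variance(self):
        e = EffectEstimate.from_log(0.2, 0.06)
        pooled = mrsurv.pool_fixed_effect([e, e])
        assert pooled.se == pytest.approx(0.06 / np.sqrt(2))

    def test_zero_se_with_differing_estimates_errors(self):
        with pytest.raises(ValueError):
            mrsurv.heterogeneity_q([EffectEstimate.from_log(0.1, 0.0),
                                    EffectEstimate.from_log(0.2, 0.1)])


class TestIncidenceRate:
    @pytest.mark.parametrize("events, py, expected", [
        (78, 1890, 4.1), (206, 7504, 2.7), (119, 3060, 3.9), (0, 100, 0.0),
    ])
    def test_published_rates(self, events, py, expected):
        assert round(mrsurv.incidence_rate(events, py), 1) == expected

    def test_nonpositive_person_years_error(self):
        with pytest.raises(ValueError):
            mrsurv.incidence_rate(5, 0)


class TestModelSuite:
    def test_reference_category_hr_is_one(self, default_table, default_grs):
        suite = mrsurv.model_suite(default_table, default_grs, models=(1,))
        est = suite["estimates"]
        ref = est[(est.exposure == "grs_cat") & (est.term == "grs_cat[0]")]
        assert (ref.hr == 1.0).all() and (ref.se == 0.0).all()

    def test_missing_covariate_errors(self, default_table):
        bad = default_table.drop(columns=["bmi"])
        with pytest.raises(ValueError, match="bmi"):
            mrsurv.model_suite(bad, models=(2,))

    def test_adjustment_attenuates_confounded_hr(self):
        # confounders raise both resistin and hazard: model 3 < model 1
        diffs = []
        for s in range(8):
            t = mrsurv.simulate_multi_cohort(mrsurv.default_config(seed=s))
            suite = mrsurv.model_suite(t, models=(1, 3))
            est = suite["estimates"]
            comb = est[(est.exposure == "resistin")
                       & (est.cohort == "combined")]
            m1 = comb[comb.model == 1].estimate.iloc[0]
            m3 = comb[comb.model == 3].estimate.iloc[0]
            diffs.append(m1 - m3)
        assert np.mean(diffs) > 0

    def test_robust_flag_follows_heterogeneity_rule(self, default_table,
                                                    default_grs):
        suite = mrsurv.model_suite(default_table, default_grs, models=(1,))
        est, het = suite["estimates"], suite["heterogeneity"]
        for exp_name in est.exposure.unique():
            trig = (het[het.exposure == exp_name].p < 0.10).any()
            comb = est[(est.exposure == exp_name) & (est.cohort == "combined")]
            assert (comb.robust == trig).all()


class TestSupremumTest:
    def test_log_linear_truth_not_rejected_on_default_data(self,
                                                           default_table):
        tab = default_table.copy()
        z, _ = mrsurv.standardize_resistin(tab["resistin"])
        tab["z_log_resistin"] = z
        dummies = pd.get_dummies(tab["cohort"], prefix="cohort",
                                 drop_first=True).astype(float)
        tab = pd.concat([tab, dummies], axis=1)
        fit = mrsurv.fit_cox(tab, "z_log_resistin", list(dummies.columns))
        _, p = supremum_linearity_test(fit, "z_log_resistin", n_sim=2000,
                                       seed=9)
        assert p > 0.05

    def test_quadratic_effect_rejected(self):
        rng = np.random.default_rng(31)
        rej = 0
        for _ in range(10):
            df = make_survival_frame(rng, n=400, beta=0.0, quadratic=0.6)
            fit = mrsurv.fit_cox(df, "z")
            _, p = supremum_linearity_test(fit, "z", n_sim=1000,
                                           seed=rng.integers(2**31))
            rej += p < 0.05
        assert rej >= 8

    def test_statistic_invariant_to_monotone_relabeling(self):
        rng = np.random.default_rng(13)
        df = make_survival_frame(rng, n=200, beta=0.4)
        fit = mrsurv.fit_cox(df, "z")
        obs1, p1 = supremum_linearity_test(fit, "z", n_sim=500, seed=4)
        # any monotone transform of the cumulating axis preserves ordering,
        # hence the statistic and the resampled p exactly
        obs2, p2 = supremum_linearity_test(
            fit, "z", n_sim=500, seed=4,
            axis_values=np.exp(df["z"].to_numpy()))
        assert obs1 == obs2 and p1 == p2

    def test_constant_covariate_errors(self):
        df = pd.DataFrame({"follow_up": [1, 2, 3.0], "event": [1, 1, 0],
                           "x": [1.0, 0.0, 1.0], "c": [1.0, 1.0, 1.0]})
        fit = mrsurv.fit_cox(df, "x")
        with pytest.raises(ValueError):
            supremum_linearity_test(fit, "c", n_sim=500)

    def test_small_n_sim_errors(self, small_cox_data):
        fit = mrsurv.fit_cox(small_cox_data, "x")
        with pytest.raises(ValueError):
            supremum_linearity_test(fit, "x", n_sim=50)
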