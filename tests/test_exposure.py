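import numpy as np
import pandas as pd
import pytest

import mrsurv
from mrsurv.exposure import ExposureFit, percent_change_means
from mrsurv.genetics import build_grs
from mrsurv.simulate import default_config


def _toy_table(scores, y, cohort="A"):
    """Minimal cohort table with log-resistin exp(y) and GRS parts."""
    g1 = np.minimum(scores, 2)
    return pd.DataFrame({"cohort": cohort, "sex": "male",
                         "resistin": np.exp(y),
                         "g1": g1, "g2": scores - g1})


class TestStandardize:
    def test_hand_computed_example(self):
        z, sd = mrsurv.standardize_resistin([np.e, np.e**2, np.e**3])
        assert sd == pytest.approx(1.0)
        assert z == pytest.approx([1.0, 2.0, 3.0])

    def test_unit_sample_sd(self):
        rng = np.random.default_rng(0)
        z, _ = mrsurv.standardize_resistin(rng.lognormal(2, 0.7, 500))
        assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_nonpositive_value_errors(self):
        with pytest.raises(ValueError, match="rows"):
            mrsurv.standardize_resistin([1.0, 0.0, 2.0])


class TestFitExposureModel:
    def test_recovers_per_allele_effect_with_coverage(self):
        # continuous-coding slope covers the generating per-allele effect
        hits = 0
        n_rep = 50
        for s in range(n_rep):
            cfg = default_config(seed=1500 + s)
            t = mrsurv.simulate_cohort(cfg, "GMS")
            grs = build_grs(t)
            fit = mrsurv.fit_exposure_model(t, grs, "continuous")
            # true effect in standardized units: a / sd(log resistin)
            z, sd = mrsurv.standardize_resistin(t["resistin"])
            truth = cfg.allele_effects[0] / sd
            lo, hi = fit.conf_int("grs")
            hits += lo <= truth <= hi
        assert 0.86 <= hits / n_rep <= 1.0

    def test_null_genetic_effect_p_uniform(self):
        rej = 0
        n_rep = 40
        for s in range(n_rep):
            cfg = default_config(seed=2500 + s, allele_effects=(0.0, 0.0))
            t = mrsurv.simulate_cohort(cfg, "GHS")
            fit = mrsurv.fit_exposure_model(t, build_grs(t), "categorical")
            rej += fit.overall_p < 0.05
        assert rej <= 8

    def test_single_category_errors(self):
        t = _toy_table(np.zeros(30, dtype=int),
                       np.random.default_rng(1).normal(2, 0.5, 30))
        with pytest.raises(ValueError):
            mrsurv.fit_exposure_model(t, build_grs(t), "continuous")

    def test_collinear_design_names_columns(self, default_table, default_grs):
        t = default_table.copy()
        t["bmi2"] = t["bmi"]
        with pytest.raises(ValueError, match="collinear"):
            mrsurv.fit_exposure_model(t, default_grs, "continuous",
                                      covariates=("bmi", "bmi2"))

    def test_aic_matches_likelihood_ratio_identity(self, default_table,
                                                   default_grs):
        cat = mrsurv.fit_exposure_model(default_table, default_grs,
                                        "categorical")
        cont = mrsurv.fit_exposure_model(default_table, default_grs,
                                         "continuous")
        # nested codings: AIC difference = LR statistic - 2 * extra params
        df_extra = len(cat.params) - len(cont.params)
        lr = (cat.aic - 2 * (len(cat.params) + 1)) \
            - (cont.aic - 2 * (len(cont.params) + 1))
        assert cat.aic - cont.aic == pytest.approx(lr + 2 * df_extra)

    def test_sd_scaling_identity(self, default_table, default_grs):
        # slope in SD units equals raw-log-scale slope divided by the SD
        fit = mrsurv.fit_exposure_model(default_table, default_grs,
                                        "continuous")
        keep = default_grs.score.notna()
        logs = np.log(default_table.loc[keep, "resistin"])
        import statsmodels.api as sm
        X = pd.DataFrame({"const": 1.0,
                          "grs": default_grs.score[keep].astype(float)})
        dummies = pd.get_dummies(default_table.loc[keep, "cohort"],
                                 drop_first=True).astype(float)
        X = pd.concat([X, dummies - dummies.mean()], axis=1)
        raw_slope = sm.OLS(logs, X).fit().params["grs"]
        assert fit.params["grs"] == pytest.approx(
            raw_slope / fit.log_resistin_sd, rel=1e-8)


class TestCompareCodings:
    def test_tie_breaks_to_continuous(self):
        a = ExposureFit("categorical", pd.Series(dtype=float),
                        pd.DataFrame(), 1.0, 100.0, 50, 0.5)
        b = ExposureFit("continuous", pd.Series(dtype=float),
                        pd.DataFrame(), 1.0, 100.0, 50, 0.5)
        assert mrsurv.compare_codings(a, b) == "continuous"

    def test_mismatched_n_errors(self):
        a = ExposureFit("categorical", pd.Series(dtype=float),
                        pd.DataFrame(), 1.0, 100.0, 50, 0.5)
        b = ExposureFit("continuous", pd.Series(dtype=float),
                        pd.DataFrame(), 1.0, 100.0, 49, 0.5)
        with pytest.raises(ValueError):
            mrsurv.compare_codings(a, b)

    def test_linear_truth_prefers_continuous(self):
        rng = np.random.default_rng(3)
        wins = 0
        for _ in range(20):
            scores = rng.integers(0, 5, 600)
            y = 2.0 + 0.1 * scores + rng.normal(0, 0.5, 600)
            t = _toy_table(scores, y)
            grs = build_grs(t)
            cat = mrsurv.fit_exposure_model(t, grs, "categorical")
            cont = mrsurv.fit_exposure_model(t, grs, "continuous")
            wins += mrsurv.compare_codings(cat, cont) == "continuous"
        assert wins >= 15

    def test_step_truth_prefers_categorical(self):
        # modest effect for scores 1-2, a jump at 3+: the printed pattern
        rng = np.random.default_rng(4)
        wins = 0
        for _ in range(20):
            scores = rng.integers(0, 5, 600)
            y = 2.0 + 0.05 * np.minimum(scores, 2) \
                + 0.6 * (scores >= 3) + rng.normal(0, 0.5, 600)
            t = _toy_table(scores, y)
            grs = build_grs(t)
            cat = mrsurv.fit_exposure_model(t, grs, "categorical")
            cont = mrsurv.fit_exposure_model(t, grs, "continuous")
            wins += mrsurv.compare_codings(cat, cont) == "categorical"
        assert wins >= 15


class TestPercentChange:
    def _fit_with(self, params, cov, terms):
        idx = list(params.keys())
        return ExposureFit("categorical", pd.Series(params),
                           pd.DataFrame(cov, index=idx, columns=idx),
                           1.0, 0.0, 10, 0.5, grs_terms=terms)

    def test_zero_beta_is_zero_percent(self):
        fit = self._fit_with({"const": 2.0, "grs[1]": 0.0},
                             np.zeros((2, 2)), ["grs[1]"])
        pcs = percent_change_means(fit)
        assert pcs[1].percent == 0.0

    def test_exact_arithmetic_with_zero_covariance(self):
        fit = self._fit_with({"const": 2.0, "grs[1]": 0.5},
                             np.zeros((2, 2)), ["grs[1]"])
        pcs = percent_change_means(fit)
        assert pcs[1].percent == pytest.approx(25.0)
        assert pcs[1].se == 0.0

    def test_reference_row_exact(self, default_table, default_grs):
        fit = mrsurv.fit_exposure_model(default_table, default_grs,
                                        "categorical")
        pcs = percent_change_means(fit)
        assert pcs[0].category == "0" and pcs[0].percent == 0.0 \
            and pcs[0].se == 0.0

    def test_near_zero_reference_mean_errors(self):
        fit = self._fit_with({"const": 1e-9, "grs[1]": 0.5},
                             np.zeros((2, 2)), ["grs[1]"])
        with pytest.raises(ValueError, match="ill-defined"):
            percent_change_means(fit)

    def test_invariant_to_category_relabeling(self, default_table,
                                              default_grs):
        fit = mrsurv.fit_exposure_model(default_table, default_grs,
                                        "categorical")
        pcs = {pc.category: (pc.percent, pc.se)
               for pc in percent_change_means(fit)}
        # permuting the non-reference term order changes nothing
        fit2 = ExposureFit(fit.coding, fit.params, fit.cov_params,
                           fit.resid_sd, fit.aic, fit.n, fit.overall_p,
                           grs_terms=list(reversed(fit.grs_terms)),
                           log_resistin_sd=fit.log_resistin_sd)
        pcs2 = {pc.category: (pc.percent, pc.se)
                for pc in percent_change_means(fit2)}
        assert pcs == pcs2
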