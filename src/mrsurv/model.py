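"""Model/Results facade for the full instrumental-variable mortality analysis.

:class:`MRSurvival` is built from a per-subject cohort table (or a simulation
config) and its :meth:`~MRSurvival.fit` runs the complete sequence —
descriptives, genotype QC, risk-score construction, exposure-stage models with
AIC coding selection, the observational Cox ladder with heterogeneity and
robust-CI rule, the log-linearity supremum check, the causal IV estimate with
its Cochran-Q contrast, and analytic power — returning a
:class:`MRSurvivalResults` whose ``summary()`` is the report.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import causal as causal_mod
from . import exposure as exposure_mod
from . import genetics, survival
from .power import detectable_hr, detectable_slope
from .simulate import SimulationConfig, simulate_multi_cohort

__all__ = ["MRSurvival", "MRSurvivalResults"]

_CONT_DESC = [("age", "Age at recruitment (yrs)"),
              ("diabetes_duration", "Diabetes duration (yrs)"),
              ("bmi", "BMI (kg/m2)"), ("hba1c", "HbA1c (%)"),
              ("resistin", "Resistin (ng/ml)"), ("follow_up", "Follow-up (yrs)")]
_BIN_DESC = [("male", "Males (%)"), ("smoker", "Smokers (%)"),
             ("insulin_therapy", "Insulin therapy (%)"),
             ("antihypertensive", "Anti-hypertension therapy (%)"),
             ("antidyslipidemia", "Anti-dyslipidemia therapy (%)")]


class MRSurvival:
    """One-sample Mendelian-randomization survival analysis on a cohort table.

    Parameters
    ----------
    data : DataFrame with the documented cohort-table schema.
    covariates : full-adjustment covariate set (the model-3 list by default).
    grs_pool_threshold : risk scores at/above this pool into one category.
    het_alpha : between-study heterogeneity level triggering robust CIs.
    supremum_sims : residual patterns simulated for the log-linearity check.
    seed : drives every stochastic step (the supremum resampling).
    """

    def __init__(self, data: pd.DataFrame, covariates=None,
                 grs_pool_threshold: int = 3, het_alpha: float = 0.10,
                 supremum_sims: int = 10000, seed: int = 0):
        self.data = data.reset_index(drop=True)
        self.covariates = tuple(covariates) if covariates is not None \
            else survival.MODEL_COVARIATES[3]
        self.grs_pool_threshold = grs_pool_threshold
        self.het_alpha = het_alpha
        self.supremum_sims = supremum_sims
        self.seed = seed

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MRSurvival":
        from .io import read_cohort_csv
        table, report = read_cohort_csv(path)
        model = cls(table, **kwargs)
        model.validation_report = report
        return model

    @classmethod
    def from_config(cls, config: SimulationConfig, **kwargs) -> "MRSurvival":
        kwargs.setdefault("seed", config.seed)
        return cls(simulate_multi_cohort(config), **kwargs)

    # ------------------------------------------------------------------

    def _descriptives(self) -> pd.DataFrame:
        rows = []
        tab = self.data.copy()
        tab["male"] = (tab["sex"].astype(str) == "male").astype(float)
        for label, grp in [("combined", tab)] + [
                (c, tab[tab["cohort"] == c]) for c in tab["cohort"].unique()]:
            py = survival.person_years(grp)
            ev = int(grp["event"].sum())
            row: dict[str, Any] = {"cohort": label, "n": len(grp),
                                   "events": ev, "person_years": py,
                                   "incidence_rate": survival.incidence_rate(ev, py)}
            for col, name in _CONT_DESC:
                row[f"{col}_mean"] = float(grp[col].mean())
                row[f"{col}_sd"] = float(grp[col].std(ddof=1))
            for col, name in _BIN_DESC:
                row[f"{col}_pct"] = float(100 * grp[col].mean())
            rows.append(row)
        return pd.DataFrame(rows)

    def fit(self) -> "MRSurvivalResults":
        data = self.data
        has_genotypes = ("g1" in data.columns and "g2" in data.columns
                         and data["g1"].notna().any()
                         and data["g2"].notna().any())
        descriptives = self._descriptives()

        hwe = {}
        grs = balance = None
        exposure_fits: dict[str, Any] = {}
        chosen_coding = None
        percent_changes = None
        if has_genotypes:
            for snp in ("g1", "g2"):
                for cohort in list(data["cohort"].unique()) + ["combined"]:
                    sub = data if cohort == "combined" else \
                        data[data["cohort"] == cohort]
                    counts = genetics.genotype_counts(sub[snp])
                    chi2, p = genetics.hwe_test(counts)
                    hwe[(snp, cohort)] = {"chi2": chi2, "p": p,
                                          "maf": counts.allele_freq}
            grs = genetics.build_grs(data, self.grs_pool_threshold)
            balance = genetics.confounder_balance(
                data, grs, list(self.covariates))
            exposure_fits["categorical"] = exposure_mod.fit_exposure_model(
                data, grs, "categorical", self.covariates)
            exposure_fits["continuous"] = exposure_mod.fit_exposure_model(
                data, grs, "continuous", self.covariates)
            chosen_coding = exposure_mod.compare_codings(
                exposure_fits["categorical"], exposure_fits["continuous"])
            percent_changes = exposure_mod.percent_change_means(
                exposure_fits["categorical"])

        suite = survival.model_suite(data, grs, het_alpha=self.het_alpha)

        # log-linearity of the resistin effect, fully adjusted combined model
        tab = survival._with_z_resistin(data)
        covs = list(self.covariates)
        if tab["cohort"].nunique() > 1:
            dummies = pd.get_dummies(tab["cohort"], prefix="cohort",
                                     drop_first=True)
            for c in dummies.columns:
                tab[c] = dummies[c].astype(float)
            covs += list(dummies.columns)
        cox3 = survival.fit_cox(tab, "z_log_resistin", covs)
        sup_obs, sup_p = survival.supremum_linearity_test(
            cox3, "z_log_resistin", n_sim=self.supremum_sims, seed=self.seed)

        causal_res = {}
        if has_genotypes and grs is not None and grs.score.notna().sum() > 0:
            try:
                causal_res["two_stage"] = causal_mod.two_stage_cox(
                    data, grs, self.covariates)
                causal_res["wald_ratio"] = causal_mod.wald_ratio_from_data(
                    data, grs, self.covariates)
                obs = next(e for e in self._iter_estimates(suite)
                           if e[:4] == ("resistin", 3, "combined",
                                        "z_log_resistin"))
                observed = survival.EffectEstimate.from_log(
                    obs[4], obs[5], n=obs[10], label="observed model3")
                q, p = causal_mod.causal_vs_observed_q(
                    causal_res["two_stage"].as_effect(), observed)
                causal_res["q_vs_observed"] = {"Q": q, "p": p,
                                               "observed": observed}
            except ZeroDivisionError as err:
                causal_res["error"] = str(err)

        events = int(data["event"].sum())
        power = {"detectable_hr_per_sd": detectable_hr(events, var_x=1.0)}
        if grs is not None:
            var_g = float(grs.score.dropna().var(ddof=0))
            if var_g > 0:
                power["detectable_hr_per_grs"] = detectable_hr(events,
                                                               var_x=var_g)
                power["detectable_slope_per_allele"] = detectable_slope(
                    int(grs.score.notna().sum()), var_x=var_g)

        prov = {
            "seed": self.seed,
            "n": int(len(data)),
            "data_sha1": hashlib.sha1(
                pd.util.hash_pandas_object(
                    data.astype(str)).values.tobytes()).hexdigest(),
        }
        return MRSurvivalResults(
            model=self, descriptives=descriptives, hwe=hwe, grs=grs,
            confounder_balance=balance, exposure_fits=exposure_fits,
            chosen_coding=chosen_coding, percent_changes=percent_changes,
            survival_suite=suite, supremum=(sup_obs, sup_p),
            causal=causal_res, power=power, provenance=prov)

    @staticmethod
    def _iter_estimates(suite):
        for row in suite["estimates"].itertuples(index=False):
            yield tuple(row)


@dataclass
class MRSurvivalResults:
    """Fitted results: every stage's estimates, diagnostics, and provenance."""

    model: MRSurvival
    descriptives: pd.DataFrame
    hwe: dict
    grs: Any
    confounder_balance: pd.DataFrame | None
    exposure_fits: dict
    chosen_coding: str | None
    percent_changes: list | None
    survival_suite: dict
    supremum: tuple[float, float]
    causal: dict
    power: dict
    provenance: dict = field(default_factory=dict)

    # -- views ----------------------------------------------------------

    @property
    def estimates(self) -> pd.DataFrame:
        return self.survival_suite["estimates"]

    @property
    def heterogeneity(self) -> pd.DataFrame:
        return self.survival_suite["heterogeneity"]

    def grs_effects_table(self) -> pd.DataFrame:
        """Per-category percent change of log-resistin mean and mortality HR.

        One row per risk-score category, each referenced to category 0
        (exactly 0% and HR 1), mirroring the parallel-ladders figure.
        """
        if self.percent_changes is None:
            raise ValueError("no genotype data: categorical effects unavailable")
        est = self.estimates
        cox = est[(est.exposure == "grs_cat") & (est.model == 3)
                  & (est.cohort == "combined")].set_index("term")
        rows = []
        for pc in self.percent_changes:
            term = f"grs_cat[{pc.category}]"
            hr_row = cox.loc[term]
            rows.append({
                "grs_category": pc.category,
                "pct_change": pc.percent, "pct_se": pc.se,
                "pct_ci_lower": pc.ci_lower, "pct_ci_upper": pc.ci_upper,
                "hr": float(hr_row.hr),
                "hr_ci_lower": float(hr_row.ci_lower),
                "hr_ci_upper": float(hr_row.ci_upper),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Multi-section plain-text report of the whole analysis."""
        lines = ["One-sample Mendelian randomization: resistin and mortality",
                 "=" * 60, ""]
        d = self.descriptives
        lines.append("Cohorts (n / events / person-years / IR per 100 py):")
        for row in d.itertuples(index=False):
            lines.append(f"  {row.cohort:>9}: {row.n:5d} / {row.events:4d} / "
                         f"{row.person_years:9.1f} / {row.incidence_rate:4.1f}")
        lines.append("")
        if self.hwe:
            lines.append("Hardy-Weinberg (combined sample):")
            for (snp, cohort), h in self.hwe.items():
                if cohort == "combined":
                    lines.append(f"  {snp}: chi2={h['chi2']:.3f} p={h['p']:.3f}"
                                 f" (risk-allele freq {h['maf']:.3f})")
            lines.append("")
        if self.grs is not None:
            cc = self.grs.category_counts
            lines.append("Risk-score categories: "
                         + ", ".join(f"{k}: {v}" for k, v in cc.items())
                         + f"  (excluded, missing genotype: "
                           f"{self.grs.n_excluded})")
            lines.append(f"Exposure coding by AIC: {self.chosen_coding} "
                         f"(categorical {self.exposure_fits['categorical'].aic:.1f}"
                         f" vs continuous "
                         f"{self.exposure_fits['continuous'].aic:.1f}); "
                         f"overall GRS-resistin p = "
                         f"{self.exposure_fits['categorical'].overall_p:.2e}")
            lines.append("")
        est = self.estimates
        lines.append("Resistin-mortality HR per SD of log-resistin (combined):")
        for m in (1, 2, 3):
            r = est[(est.exposure == "resistin") & (est.model == m)
                    & (est.cohort == "combined")].iloc[0]
            flag = " (robust)" if r.robust else ""
            lines.append(f"  Model {m}: {r.hr:.2f} "
                         f"({r.ci_lower:.2f}-{r.ci_upper:.2f}), p={r.p:.2e}"
                         f"{flag}")
        lines.append(f"Log-linearity supremum test: sup|W| = "
                     f"{self.supremum[0]:.3f}, p = {self.supremum[1]:.3f}")
        lines.append("")
        if "two_stage" in self.causal:
            ce = self.causal["two_stage"]
            lines.append(f"Causal HR per SD of log-resistin (two-stage): "
                         f"{ce.hr:.2f} ({ce.ci_lower:.2f}-{ce.ci_upper:.2f})")
            w = self.causal["wald_ratio"]
            lines.append(f"  Wald ratio: {w.hr:.2f} "
                         f"({w.ci_lower:.2f}-{w.ci_upper:.2f})")
            qv = self.causal["q_vs_observed"]
            lines.append(f"  Cochran Q vs observational estimate: "
                         f"Q={qv['Q']:.2f}, p={qv['p']:.3f}")
        elif "error" in self.causal:
            lines.append(f"Causal section not computed: {self.causal['error']}")
        else:
            lines.append("Causal section not computed: no genotype data")
        lines.append("")
        lines.append("Power (80%, alpha 0.05, observed events): "
                     + ", ".join(f"{k}={v:.3f}" for k, v in self.power.items()))
        lines.append("")
        lines.append(f"[seed {self.provenance.get('seed')}, n "
                     f"{self.provenance.get('n')}, data sha1 "
                     f"{str(self.provenance.get('data_sha1'))[:12]}]")
        return "\n".join(lines)

    def to_yaml(self) -> str:
        """Lossless-enough structured-text serialization of the key numbers."""
        def eff(e):
            return {"estimate": float(e.estimate), "se": float(e.se),
                    "hr": float(np.exp(e.estimate)),
                    "ci": [float(e.ci_lower), float(e.ci_upper)]}

        doc = {
            "descriptives": self.descriptives.to_dict("records"),
            "supremum": {"statistic": self.supremum[0], "p": self.supremum[1]},
            "power": self.power,
            "provenance": self.provenance,
        }
        if "two_stage" in self.causal:
            ce = self.causal["two_stage"]
            doc["causal"] = {"method": ce.method, "hr": ce.hr,
                             "ci": [ce.ci_lower, ce.ci_upper],
                             "Q_vs_observed": self.causal["q_vs_observed"]["Q"],
                             "p_vs_observed": self.causal["q_vs_observed"]["p"]}
        return yaml.safe_dump(doc, sort_keys=False)
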