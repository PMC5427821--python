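# mrsurv

One-sample Mendelian randomization with survival outcomes: does serum
resistin *causally* raise the risk of all-cause death in patients with type 2
diabetes, or is the repeatedly observed resistin–mortality association
confounded?

Circulating resistin is firmly associated with mortality, but association is
not causation. Two SNPs (rs3931020, rs13144478) raise serum resistin in
Europeans and — being fixed at conception — cannot be confounded by lifestyle
or disease severity. `mrsurv` implements the full genetic
instrumental-variable pipeline around that idea, for a three-cohort
prospective design (the Italian GHS, GMS and FMS cohorts of patients with
type 2 diabetes; 1,479 subjects, 403 deaths over 12,454 person-years):

- **Genotype risk score (GRS).** Per-subject count of resistin-increasing
  alleles across the two SNPs (0–4; 3 and 4 pooled as "3+"), with
  Hardy–Weinberg QC and a complete-case missingness policy.
- **Exposure stage.** OLS of standardized log-resistin
  (`z = ln(resistin)/SD(ln resistin)`) on the GRS, categorical vs continuous
  coding chosen by AIC, and delta-method percent changes of the category
  means versus GRS = 0.
- **Survival stage.** Cox proportional-hazards models of death on
  standardized log-resistin and on the GRS, unadjusted (Model 1), adjusted
  for sex/age/smoking/BMI (Model 2) and fully adjusted (Model 3), per cohort
  and combined, with inverse-variance pooling, Cochran-Q between-study
  heterogeneity (robust sandwich CIs when p < 0.10), and a
  Kolmogorov-type supremum test of log-linearity built on cumulative
  martingale residuals (Lin–Wei–Ying resampling).
- **Causal estimate.** The hazard ratio per *genetic-equivalent* SD of
  log-resistin, by the Wald ratio
  `log HR_causal = (per-allele log-HR) / (per-allele effect on z)` and by
  two-stage predictor substitution (Cox on the stage-1 fitted exposure),
  with a Cochran-Q contrast against the observational estimate.
- **Power.** The Schoenfeld relation
  `D = (z_{1-α/2} + z_pow)² / (β² σ²_x)` and its inversions, plus a
  Monte-Carlo verification that fits a Cox model per replicate.
- **Synthetic cohorts.** No subject-level data were ever deposited for the
  motivating study, so the package ships a calibrated generator
  (SNPs → log-resistin → exponential survival, shared confounders) that
  reproduces the published cohort sizes, incidence rates (4.1/2.7/3.9 per
  100 person-years), resistin distributions and follow-up; every stage is
  exercised end-to-end on it.

## Worked example

```python
import mrsurv

model = mrsurv.MRSurvival.from_config(mrsurv.default_config(seed=42))
results = model.fit()
print(results.summary())
```

```
One-sample Mendelian randomization: resistin and mortality
============================================================

Cohorts (n / events / person-years / IR per 100 py):
   combined:  1479 /  388 /   12577.4 /  3.1
        GHS:   350 /   75 /    1885.4 /  4.0
        GMS:   698 /  192 /    7625.1 /  2.5
        FMS:   431 /  121 /    3067.0 /  3.9

Hardy-Weinberg (combined sample):
  g1: chi2=0.018 p=0.893 (risk-allele freq 0.314)
  g2: chi2=0.229 p=0.632 (risk-allele freq 0.362)

Risk-score categories: 0: 290, 1: 579, 2: 429, 3+: 181  (excluded, missing genotype: 0)
Exposure coding by AIC: continuous (categorical 4136.9 vs continuous 4133.8); overall GRS-resistin p = 2.81e-05

Resistin-mortality HR per SD of log-resistin (combined):
  Model 1: 1.55 (1.40-1.71), p=1.46e-17 (robust)
  Model 2: 1.47 (1.32-1.63), p=2.98e-13 (robust)
  Model 3: 1.46 (1.32-1.62), p=5.44e-13 (robust)
Log-linearity supremum test: sup|W| = 14.093, p = 0.304

Causal HR per SD of log-resistin (two-stage): 2.36 (1.05-5.32)
  Wald ratio: 2.36 (0.97-5.72)
  Cochran Q vs observational estimate: Q=1.32, p=0.251

Power (80%, alpha 0.05, observed events): detectable_hr_per_sd=1.153, detectable_hr_per_grs=1.160, detectable_slope_per_allele=0.076
```

Reading it: the three synthetic cohorts land on the published sizes and
death rates; both SNPs sit in Hardy–Weinberg equilibrium; the risk score
predicts resistin (p ≈ 3 × 10⁻⁵) but none of the confounders; each SD of
log-resistin carries a ~1.5-fold observational mortality hazard, log-linear
by the supremum test; and the instrument-based causal hazard ratio (2.36
per SD here) is larger than — but statistically compatible with — the
observational one, exactly the qualitative configuration the design is
meant to probe. (This run's generating truth is HR 1.4 per SD; the wide
causal CI reflects the modest instrument strength, first-stage F ≈ 15.)

Because the published subject-level data are unavailable, the package also
has a *summary-statistics mode* that reruns every meta-analytic step from
the published per-cohort numbers, with no randomness:

```bash
$ mrsurv replicate-summary
IR GHS: 4.1 per 100 py
IR GMS: 2.7 per 100 py
IR FMS: 3.9 per 100 py
total person-years: 12454 (403 events)
Model 1 pooled HR 1.39 (1.27-1.53); heterogeneity p 0.45
Model 2 pooled HR 1.32 (1.19-1.45); heterogeneity p 0.07
Model 3 pooled HR 1.28 (1.16-1.42); heterogeneity p 0.06
causal vs observed: Q=3.20, p=0.074
detectable: HR/SD 1.15, HR/GRS 1.19, slope 0.092
```

The CLI also exposes `simulate`, `qc`, `exposure`, `survival`, `causal`,
`power` and `run-all`; see `mrsurv --help`.

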