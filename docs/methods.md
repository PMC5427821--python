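# Methods

## The estimand and the identification strategy

The package estimates the causal effect of serum resistin on all-cause
mortality in a prospective cohort setting, expressed as a hazard ratio per
one standard deviation of log-resistin. The instrument is a genotype risk
score (GRS): the per-subject count of resistin-increasing alleles at two
SNPs, 0–4, with the sparse 3- and 4-allele carriers pooled into "3+".
Identification rests on the usual instrumental-variable conditions —
relevance (the GRS predicts resistin), exchangeability (genotypes are
independent of the confounders of the resistin–mortality association), and
exclusion (the SNPs affect mortality only through resistin). The package
tests relevance directly (stage-1 F and overall p) and probes
exchangeability empirically (`confounder_balance`); exclusion is an
assumption and is discussed as a limitation below.

Two estimators are provided:

- **Wald ratio.** `log HR_causal = b / a`, with `a` the per-allele effect on
  standardized log-resistin (OLS) and `b` the per-allele log hazard ratio
  (Cox). First-order delta-method variance
  `var(b)/a² + b²·var(a)/a⁴`, treating the stage-1/stage-2 covariance as
  zero. Both stages come from the same sample, so this covariance is not
  exactly zero; ignoring it is a documented approximation and the
  bootstrap option on the two-stage estimator quantifies it.
- **Two-stage predictor substitution (default).** Stage 1 regresses
  standardized log-resistin on the integer GRS plus covariates and cohort
  indicators; stage 2 fits a Cox model on the stage-1 fitted values with
  the same covariates, robust (sandwich) covariance by default. With
  identical rows and covariate sets the two estimators coincide exactly —
  the stage-2 Cox model on an affine function of the GRS is a
  reparameterization of the Cox model on the GRS itself — which the test
  suite exploits as an internal consistency check. The two-stage form is
  the default because it generalizes to multi-instrument and
  covariate-adjusted settings without extra derivation.

The causal and observational estimates are contrasted with a Cochran Q on
1 df, `Q = (θ_c − θ_o)²/(SE_c² + SE_o²)`, again treating the two as
independent (they share the sample; the approximation is conservative in
neither direction in general and is stated in the output).

A first-stage F below 10 flags the instrument as weak in the results
object. The flag is report-only: estimation proceeds, because a hard
threshold would be arbitrary and the delta-method CI already widens
appropriately. Division by a stage-1 effect indistinguishable from zero
(|a| < 1e-10) raises an error instead.

## Exposure standardization and stage-1 modelling

Resistin (ng/ml) is log-transformed and divided by the sample SD of the
logs, **without centering** — coefficients are then per-SD of log-resistin
while the mean of the standardized variable stays positive. Centering is
available (`center_covariates` controls covariates; the outcome is never
centred) and would leave hazard ratios untouched while changing the
percent-change scale, which is why the uncentred convention is the
default: the percent change of the category mean, `100·β_g/μ0`, needs a
meaningful reference mean `μ0`. Covariates and cohort indicators are
mean-centred inside the exposure fit so the intercept *is* the adjusted
reference-category mean. The delta-method SE of the percent change uses
the gradient `(100/μ0, −100·β_g/μ0²)` on the `(β_g, μ0)` covariance block;
a reference mean within 1e-6 of zero raises an error (the quantity is
ill-defined there).

GRS coding (categorical {0,1,2,3+} vs continuous 0–4) is chosen by AIC.
The AIC convention counts the residual-variance parameter,
`AIC = 2(k_mean + 1) − 2 lnL`; only AIC *differences* matter for the
choice, so the convention is stated rather than consequential. Ties break
toward the leaner continuous coding. The overall categorical association
p-value is a joint F-test across the category dummies.

## Survival modelling

Cox fits are delegated to lifelines (partial likelihood, Efron tie
handling, Newton convergence tightened to 1e-9 so small flat-likelihood
problems agree with a brute-force grid search to 1e-4). Follow-up is
continuous, so ties arise only from rounding and the Efron/Breslow
distinction is immaterial here; only Efron is exposed. "Adjusted for study
sample" is implemented as fixed cohort-indicator covariates rather than a
stratified baseline — the three cohorts differ in baseline rate by at most
~1.5-fold and the indicator form keeps one shared coefficient vector.

Between-study heterogeneity uses fixed-effect Cochran Q over the
per-cohort estimates; the combined fit switches to the robust sandwich
covariance when the heterogeneity p falls below 0.10. Pooling is
inverse-variance on the log scale.

### The log-linearity supremum test

Martingale residuals `M_i = δ_i − Λ̂0(T_i)·exp(x_iᵀβ̂)` (Breslow baseline)
are cumulated over the sorted covariate axis,
`W(x) = Σ_{z_i ≤ x} M_i`, and the observed statistic is `sup_x |W(x)|`.
The null distribution is simulated by multiplying residual contributions
by independent standard-normal draws. Two schemes are implemented:

- `scheme="score"` (default): the Lin–Wei–Ying resampling, which adds the
  terms that account for the estimation of β̂ and of the baseline hazard
  (the compensator part of each perturbed martingale increment plus the
  score-influence correction `η̂(x)ᵀ Î⁻¹ Σ G_i Û_i`).
- `scheme="simple"`: the raw multiplier `Σ 1(z_i≤x) M̂_i G_i`.

The simple scheme ignores that the fitted residuals are constrained by the
score equations (the observed process is tied down at the right end while
the resampled ones are not), and in calibration runs it is severely
conservative — near-zero rejection at the nominal 5% level with null
p-values piling up near 1 — whereas the score scheme is calibrated. The
score scheme is therefore the default; the simple multiplier is retained
as an explicit option for comparison. The statistic depends on the
covariate axis only through its ordering (monotone-relabeling invariant),
and the p-value is the fraction of simulated suprema at or above the
observed one.

## Power

The Schoenfeld relation links the number of events D, the log hazard
ratio β, and the predictor variance σ²ₓ:
`D = (z_{1−α/2} + z_pow)²/(β²σ²ₓ)`, with z-quantiles at full double
precision and two-sided α throughout. `detectable_hr` and
`schoenfeld_events` are exact inverses up to the integer ceiling (the
ceiling is guarded against float noise). The linear-stage analogue gives
the minimal detectable stage-1 slope. With the published inputs
(n = 1,479, GRS variance 0.624 from the printed category counts) the
formula yields a detectable slope of **0.092**, not the published 0.10;
the discrepancy is reported as-is rather than reconciled — no combination
of the printed inputs reproduces 0.10 under the standard formula.

`simulate_power` verifies the analytic numbers by simulation: exponential
event times with `log λ_i = log λ0 + β x_i`, administrative censoring at a
unit horizon, λ0 solved by Gauss–Hermite quadrature plus Brent root
finding so the expected event count hits its target, one univariate Cox
fit per replicate, two-sided Wald test at α.

## The synthetic-data generator

The generator emulates the structure the analysis assumes:

1. genotypes Binomial(2, maf) at two independent loci
   (defaults 0.30 and 0.37);
2. `ln resistin = intercept_c + a1·g1 + a2·g2 + Σ b_k z_k + ε`,
   `ε ~ N(0, σ_c)`, with per-cohort intercepts and residual SDs calibrated
   so the arithmetic resistin mean/SD of each cohort matches the published
   values under log-normality (a single global σ can be forced via
   `resistin_sigma`);
3. exponential event times with
   `log hazard = log λ_c + θ·z_resistin + Σ γ_k z_k`, where `z_resistin`
   is log-resistin standardized within the generator and θ
   (`causal_loghr_per_sd`, default ln 1.4) is the true causal effect;
4. administrative censoring uniform on (horizon ± jitter).

λ_c and the censoring horizon are solved jointly by quadrature so the
*realized* incidence rate and mean follow-up match the published
per-cohort values (4.1/2.7/3.9 deaths per 100 person-years; 5.4/10.8/7.1
years) — events shorten follow-up and hazard heterogeneity down-weights
high-risk person-time, so naive plug-in targets would undershoot by
~10–15%. Confounders (age, sex, BMI, HbA1c, smoking) feed both
log-resistin and the hazard with small coefficients, so adjustment
matters (Model 3 attenuates Model 1) while the instrument remains valid.

The default θ = ln 1.4 makes the *observational* per-SD hazard ratio land
near the published combined estimate; the published causal point estimate
(2.17, CI 1.22–3.87) and observational estimate (1.27) cannot both hold in
a pleiotropy-free simulation, and the generator prioritizes the
observational scale while letting the IV machinery recover its own
generating truth. Features of real data the generator does **not**
emulate: linkage disequilibrium between loci, non-European allele
architectures, measurement error and within-subject variability of
resistin, non-proportional hazards, informative censoring, and the
published GRS category distribution itself (231/587/599/62), which is
over-dispersed relative to any two independent Hardy–Weinberg loci and is
therefore used directly as a data input where needed (e.g. the GRS
variance in power calculations) rather than being force-fit by the
generator. Passing tests on synthetic data show the estimators are
consistent and calibrated *under the generator's assumptions*, not that
the substantive causal claim is true.

Determinism: a fixed config and seed reproduce tables byte-for-byte;
cohorts draw from label-keyed substreams (CRC32 of the label) so a single
cohort simulated alone equals its slice of the multi-cohort table.

## Problem sizes used in validation

Coverage of the causal CI is checked over 500 replicates of the full
default configuration (n = 1,479 each); the supremum test's type-I error
over 500 replicates at n = 300 with 1,000 resampled patterns per test;
empirical Cox power over 1,000 replicates at n = 1,479; delta-method
percent-change SEs against a 2,000-replicate bootstrap at n = 698. These
sizes keep each check's Monte-Carlo error well inside the asserted bands
while the whole suite runs in minutes on one core.

## Known limitations

- Exclusion restriction and pleiotropy are untestable with two loci at one
  locus pair; the package reports, it cannot verify.
- The Wald/two-stage SEs ignore the stage-1/stage-2 sampling covariance;
  with modest instrument strength (first-stage F ≈ 10–20) the delta-method
  CI of the ratio over-covers slightly (the Wald-ratio CI empirically
  ~98% at the default configuration, the two-stage sandwich CI ~96%).
- The missingness policy is complete-case exclusion for GRS analyses; no
  imputation is offered.
- Robust-vs-model-based covariance choice is driven by a hard p < 0.10
  rule, inherited from the reporting convention it mirrors, not by any
  optimality argument.
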