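"""Stage-1 exposure models: GRS -> standardized log-resistin.

Serum resistin is log-transformed and divided by the sample SD of the logs
(no centering), so regression coefficients read as SD-of-log-resistin units.
The risk score enters either as an integer dose (continuous coding) or as
dummy-coded categories {0, 1, 2, 3+} with 0 as reference; the two codings are
compared by AIC.  Percent changes of the category means relative to the
reference, with first-order delta-method standard errors, provide the
figure-style summary that parallels the hazard-ratio ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genetics import GRSProfile

__all__ = [
    "ExposureFit",
    "PercentChange",
    "standardize_resistin",
    "fit_exposure_model",
    "compare_codings",
    "percent_change_means",
]

Z975 = 1.959963984540054

_BOOL_COLS = ("smoker", "insulin_therapy", "antihypertensive", "antidyslipidemia")


def _numeric_covariate(table: pd.DataFrame, name: str) -> pd.Series:
    """Numeric coding for a model covariate (``male`` derives from ``sex``)."""
    if name in ("male", "sex"):
        return (table["sex"].astype(str).str.lower() == "male").astype(float)
    col = table[name]
    if col.dtype == bool or name in _BOOL_COLS:
        return col.astype(float)
    return pd.to_numeric(col)


def standardize_resistin(values) -> tuple[np.ndarray, float]:
    """log-transform and divide by the sample SD of the logs (ddof=1).

    Returns the standardized vector (unit sample SD, not centred) and the SD
    of log-resistin used as the divisor.
    """
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(f"resistin must be > 0; offending rows: {bad[:20].tolist()}")
    logs = np.log(arr)
    sd = float(np.std(logs, ddof=1))
    if sd == 0:
        raise ValueError("log-resistin has zero variance; cannot standardize")
    return logs / sd, sd


@dataclass
class ExposureFit:
    """OLS fit of standardized log-resistin on the risk score."""

    coding: str  # "continuous" | "categorical"
    params: pd.Series
    cov_params: pd.DataFrame
    resid_sd: float
    aic: float  # 2k - 2 lnL with k counting the residual variance
    n: int
    overall_p: float  # joint F-test (categorical) or slope t-test (continuous)
    grs_terms: list[str] = field(default_factory=list)
    log_resistin_sd: float = float("nan")

    def conf_int(self, term: str) -> tuple[float, float]:
        b = self.params[term]
        se = float(np.sqrt(self.cov_params.loc[term, term]))
        return b - Z975 * se, b + Z975 * se


def _rank_check(X: pd.DataFrame) -> None:
    mat = X.to_numpy(float)
    rank = np.linalg.matrix_rank(mat)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(mat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _design(table: pd.DataFrame, grs: GRSProfile, coding: str,
            covariates, cohort_indicators: bool,
            center_covariates: bool) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    keep = grs.score.notna() & table["resistin"].notna()
    tab = table.loc[keep]
    z, sd = standardize_resistin(tab["resistin"])
    y = pd.Series(z, index=tab.index, name="z_log_resistin")

    cols = {"const": pd.Series(1.0, index=tab.index)}
    if coding == "continuous":
        if grs.score[keep].nunique() < 2:
            raise ValueError("risk score is constant on the analysis rows")
        cols["grs"] = grs.score[keep].astype(float)
        grs_terms = ["grs"]
    elif coding == "categorical":
        cats = grs.category[keep]
        levels = [lab for lab in ["0", "1", "2", f"{grs.pool_threshold}+"]
                  if (cats == lab).any()]
        if len(levels) < 2:
            raise ValueError("fewer than two risk-score categories present")
        grs_terms = []
        for lab in levels[1:]:  # reference = lowest category
            name = f"grs[{lab}]"
            cols[name] = (cats == lab).astype(float)
            grs_terms.append(name)
    else:
        raise ValueError(f"unknown coding {coding!r}")

    for cov in covariates:
        x = _numeric_covariate(tab, cov)
        if center_covariates:
            x = x - x.mean()
        cols[cov] = x
    if cohort_indicators and tab["cohort"].nunique() > 1:
        dummies = pd.get_dummies(tab["cohort"], prefix="cohort", drop_first=True)
        for c in dummies.columns:
            d = dummies[c].astype(float)
            cols[c] = d - d.mean() if center_covariates else d
    X = pd.DataFrame(cols)
    _rank_check(X)
    return X, y, grs_terms, sd


def fit_exposure_model(table: pd.DataFrame, grs: GRSProfile,
                       coding: str = "categorical",
                       covariates: tuple[str, ...] = (),
                       cohort_indicators: bool = True,
                       center_covariates: bool = True) -> ExposureFit:
    """OLS of standardized log-resistin on the risk score plus covariates.

    Covariates (and cohort indicators) are mean-centred by default so the
    intercept is the model-estimated mean of the reference category, which is
    what :func:`percent_change_means` divides by.  The AIC convention counts
    the residual-variance parameter: AIC = 2(k_mean + 1) - 2 lnL.
    """
    X, y, grs_terms, sd = _design(table, grs, coding, covariates,
                                  cohort_indicators, center_covariates)
    res = sm.OLS(y, X).fit()
    aic = 2.0 * (X.shape[1] + 1) - 2.0 * res.llf
    if coding == "categorical":
        contrast = np.zeros((len(grs_terms), X.shape[1]))
        for i, term in enumerate(grs_terms):
            contrast[i, X.columns.get_loc(term)] = 1.0
        overall_p = float(res.f_test(contrast).pvalue)
    else:
        overall_p = float(res.pvalues["grs"])
    return ExposureFit(
        coding=coding,
        params=res.params,
        cov_params=res.cov_params(),
        resid_sd=float(np.sqrt(res.scale)),
        aic=float(aic),
        n=int(res.nobs),
        overall_p=overall_p,
        grs_terms=grs_terms,
        log_resistin_sd=sd,
    )


def compare_codings(fit_cat: ExposureFit, fit_cont: ExposureFit) -> str:
    """Pick the coding with the smaller AIC; ties go to the leaner continuous."""
    if fit_cat.n != fit_cont.n:
        raise ValueError(f"fits use different rows (n={fit_cat.n} vs {fit_cont.n})")
    return "categorical" if fit_cat.aic < fit_cont.aic else "continuous"


@dataclass
class PercentChange:
    """Percent change of a category mean versus the reference category."""

    category: str
    percent: float
    se: float
    ci_lower: float
    ci_upper: float


def percent_change_means(fit: ExposureFit, mu_tol: float = 1e-6
                         ) -> list[PercentChange]:
    """Per-category percent change of the modelled log-resistin mean vs GRS=0.

    For category g the estimate is 100 * beta_g / mu0 with mu0 the reference
    (intercept) mean; the SE comes from the first-order delta method with
    gradient (100/mu0, -100 beta_g / mu0^2) applied to the (beta_g, mu0)
    covariance block.  The reference row is exactly (0, SE 0).
    """
    if fit.coding != "categorical":
        raise ValueError("percent changes need the categorical coding")
    mu0 = float(fit.params["const"])
    if abs(mu0) < mu_tol:
        raise ValueError(f"reference mean {mu0:g} within tolerance of zero; "
                         "percent change is ill-defined")
    out = [PercentChange("0", 0.0, 0.0, 0.0, 0.0)]
    for term in fit.grs_terms:
        beta = float(fit.params[term])
        pc = 100.0 * beta / mu0
        grad = np.array([100.0 / mu0, -100.0 * beta / mu0**2])
        block = fit.cov_params.loc[[term, "const"], [term, "const"]].to_numpy()
        se = float(np.sqrt(grad @ block @ grad))
        cat = term[term.index("[") + 1: -1]
        out.append(PercentChange(cat, pc, se, pc - Z975 * se, pc + Z975 * se))
    return out
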