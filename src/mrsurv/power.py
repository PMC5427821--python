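"""Analytic (Schoenfeld) and simulation-based power for Cox and linear stages.

The Schoenfeld relation ties the number of events D, the log hazard ratio
beta, and the predictor variance sigma_x^2:

    D = (z_{1-alpha/2} + z_power)^2 / (beta^2 sigma_x^2)

Its inversions give the minimal detectable hazard ratio at a fixed event
count and the analytic event requirement at a fixed effect.  The companion
linear-stage formula gives the minimal detectable regression slope, and a
Monte-Carlo routine verifies the analytic numbers by simulating exponential
survival with administrative censoring and fitting a Cox model per replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from lifelines import CoxPHFitter

__all__ = [
    "PowerSpec",
    "schoenfeld_events",
    "detectable_hr",
    "detectable_slope",
    "calibrate_censoring_rate",
    "simulate_power",
]


@dataclass
class PowerSpec:
    """Parameters of an analytic or simulated power run."""

    alpha: float = 0.05
    power: float = 0.80
    n: int = 1479
    target_events: int = 403
    log_hr: float = math.log(1.15)
    var_x: float = 1.0
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.var_x <= 0:
            raise ValueError("var_x must be > 0")
        if self.n < 2 or self.target_events < 1:
            raise ValueError("need n >= 2 and target_events >= 1")


def _zsum(alpha: float, power: float) -> float:
    return stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)


def schoenfeld_events(alpha: float, power: float, log_hr: float,
                      var_x: float = 1.0) -> int:
    """Smallest event count D with D >= (z_a + z_p)^2 / (log_hr^2 var_x)."""
    if log_hr == 0:
        raise ValueError("log_hr must be nonzero")
    if var_x <= 0:
        raise ValueError("var_x must be > 0")
    d = _zsum(alpha, power) ** 2 / (log_hr**2 * var_x)
    # guard the ceiling against float noise so detectable_hr round-trips
    return int(math.ceil(d - 1e-9 * max(d, 1.0)))


def detectable_hr(events: int, alpha: float = 0.05, power: float = 0.80,
                  var_x: float = 1.0) -> float:
    """Minimal detectable hazard ratio at the given event count."""
    if events < 1:
        raise ValueError("events must be >= 1")
    if var_x <= 0:
        raise ValueError("var_x must be > 0")
    return float(np.exp(math.sqrt(_zsum(alpha, power) ** 2 / (events * var_x))))


def detectable_slope(n: float, alpha: float = 0.05, power: float = 0.80,
                     var_x: float = 1.0, residual_sd: float = 1.0) -> float:
    """Minimal detectable slope in OLS of a unit-residual-SD outcome."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if var_x <= 0:
        raise ValueError("var_x must be > 0")
    return float(_zsum(alpha, power) * residual_sd / math.sqrt(n * var_x))


def calibrate_censoring_rate(target_event_frac: float, log_hr: float,
                             horizon: float = 1.0) -> float:
    """Baseline exponential rate hitting a target event fraction.

    Solves E_Z[1 - exp(-lambda e^{log_hr Z} horizon)] = target_event_frac for
    lambda, with Z standard normal (Gauss–Hermite quadrature), under
    administrative censoring at ``horizon``.
    """
    if not 0 < target_event_frac < 1:
        raise ValueError("target_event_frac must be in (0, 1)")
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    w = weights / weights.sum()

    def frac(lam):
        return float(np.sum(w * (1 - np.exp(-lam * np.exp(log_hr * nodes)
                                            * horizon))))

    return float(optimize.brentq(lambda l: frac(l) - target_event_frac,
                                 1e-8, 1e4, xtol=1e-12))


def simulate_power(spec: PowerSpec, progress: bool = False) -> dict:
    """Empirical power of the univariate Cox test by Monte-Carlo simulation.

    Each replicate draws a standard-normal exposure for ``spec.n`` subjects
    (scaled to ``var_x``), exponential event times with log-hazard
    ``log(rate) + log_hr * x``, administrative censoring at a unit horizon
    with the baseline rate calibrated so the expected event count matches
    ``spec.target_events``, fits a Cox model, and tests the coefficient at
    ``spec.alpha`` (two-sided Wald).

    Returns a dict with the empirical power, its binomial Monte-Carlo SE, the
    mean realized event count, and the replicate count.
    """
    if spec.replicates < 100:
        raise ValueError("replicates must be >= 100")
    sd_x = math.sqrt(spec.var_x)
    beta = spec.log_hr / 1.0  # per unit of x
    rate = calibrate_censoring_rate(spec.target_events / spec.n,
                                    spec.log_hr * sd_x) / 1.0
    rng = np.random.default_rng(spec.seed)
    rejections = 0
    events_seen = []
    cph = CoxPHFitter()
    for _ in range(spec.replicates):
        z = rng.standard_normal(spec.n)
        x = z * sd_x
        lam = rate * np.exp(beta * x)
        t = rng.exponential(1.0 / lam)
        fu = np.minimum(t, 1.0)
        ev = (t <= 1.0).astype(int)
        events_seen.append(int(ev.sum()))
        df = pd.DataFrame({"fu": fu, "ev": ev, "x": x})
        cph.fit(df, duration_col="fu", event_col="ev")
        if float(cph.summary.loc["x", "p"]) < spec.alpha:
            rejections += 1
    power = rejections / spec.replicates
    mc_se = math.sqrt(power * (1 - power) / spec.replicates)
    return {
        "power": power,
        "mc_se": mc_se,
        "mean_events": float(np.mean(events_seen)),
        "replicates": spec.replicates,
    }
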