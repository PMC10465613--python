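"""Lifespan simulation and Kaplan--Meier estimation.

Mortality follows a Gompertz hazard h(t) = m * A * exp(G * t); intervention
profiles apply a proportional (frailty-style) multiplier m to the baseline
rate A, calibrated by root finding so that the continuous expected lifespan
changes by a stated percentage over control.  The packaged targets mirror
the printed effect sizes of the study the generator emulates: single-TE
RNAi +10%, double knockdown +20% (additive), somatic Piwi expression +30%
at the 20 C profile and +20% at the 25 C profile, daf-2 doubling lifespan;
the demethylase/methyltransferase mutants carry placeholder targets.

Cohorts are drawn by inverse-transform sampling from the Gompertz survival
function and rounded up to whole days (daily scoring).  Estimation uses the
product-limit (Kaplan--Meier) estimator, restricted means under censoring,
and the Mantel--Cox log-rank test, all via lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import integrate, optimize

from .errors import CalibrationError, ConfigurationError

BASE_G = 0.25                 # Gompertz shape, per day
BASE_MEAN_20C = 17.0          # expected wild-type lifespan, 20 C profile (days)
BASE_MEAN_25C = 13.0          # 25 C profile: shorter-lived baseline


@dataclass(frozen=True)
class HazardProfile:
    A: float                  # baseline Gompertz rate (per day)
    G: float                  # Gompertz shape (per day)
    multiplier: float = 1.0   # proportional factor on A
    label: str = ""

    def __post_init__(self):
        if self.A <= 0 or self.G <= 0 or self.multiplier <= 0:
            raise ValueError("A, G and multiplier must be positive")

    def hazard(self, t):
        return self.multiplier * self.A * np.exp(self.G * np.asarray(t))

    def survival(self, t):
        rate = self.multiplier * self.A / self.G
        with np.errstate(over="ignore"):  # exp overflow at large t -> S = 0
            return np.exp(-rate * (np.exp(self.G * np.asarray(t)) - 1.0))


def expected_lifespan(profile: HazardProfile) -> float:
    """Continuous expected lifespan by quadrature of the survival function."""
    value, _err = integrate.quad(profile.survival, 0, np.inf)
    return value


@lru_cache(maxsize=None)
def _solve_baseline_A(G: float, target_mean: float) -> float:
    def gap(log_a):
        return expected_lifespan(HazardProfile(math.exp(log_a), G)) - target_mean
    log_a = optimize.brentq(gap, -30.0, 5.0, xtol=1e-12)
    return math.exp(log_a)


def base_profile(temperature: str = "20C") -> HazardProfile:
    mean = {"20C": BASE_MEAN_20C, "25C": BASE_MEAN_25C}.get(temperature)
    if mean is None:
        raise ConfigurationError(f"unknown temperature profile {temperature!r}")
    return HazardProfile(_solve_baseline_A(BASE_G, mean), BASE_G,
                         label=f"control_{temperature}")


def calibrate_multiplier(base: HazardProfile,
                         target_extension_percent: float) -> float:
    """Multiplier m on A such that the expected lifespan under (m*A, G) is
    (1 + target/100) times the control expectation, to within 0.1
    percentage points."""
    if target_extension_percent <= -100:
        raise CalibrationError("target extension must exceed -100%")
    if target_extension_percent == 0:
        return 1.0
    control = expected_lifespan(replace(base, multiplier=1.0))
    goal = (1.0 + target_extension_percent / 100.0) * control

    def gap(log_m):
        return expected_lifespan(replace(base, multiplier=math.exp(log_m))) - goal

    try:
        log_m = optimize.brentq(gap, -25.0, 25.0, xtol=1e-12)
    except ValueError as exc:
        raise CalibrationError(f"multiplier search failed to bracket: {exc}") from None
    m = math.exp(log_m)
    achieved = 100.0 * (expected_lifespan(replace(base, multiplier=m)) / control - 1.0)
    if abs(achieved - target_extension_percent) > 0.1:
        raise CalibrationError(
            f"achieved {achieved:.3f}% vs target {target_extension_percent}%")
    return m


#: Intervention profiles: (target extension percent, temperature profile).
#: The demethylase (nmad-1) and methyltransferase (damt-1) entries are
#: directional placeholders -- the study reports shortening/lengthening
#: without a printed percentage.
INTERVENTION_TARGETS: dict[str, tuple[float, str]] = {
    "control": (0.0, "20C"),
    "te_rnai_single": (10.0, "20C"),
    "tc1_tc3_rnai": (20.0, "20C"),
    "piwi_soma": (30.0, "20C"),
    "piwi_soma_nogfp": (20.0, "25C"),
    "daf2": (100.0, "20C"),
    "nmad1": (-15.0, "20C"),
    "damt1": (10.0, "20C"),
}


def intervention_profile(name: str) -> HazardProfile:
    if name not in INTERVENTION_TARGETS:
        raise ConfigurationError(f"unknown intervention profile {name!r}")
    target, temp = INTERVENTION_TARGETS[name]
    base = base_profile(temp)
    return replace(base, multiplier=calibrate_multiplier(base, target), label=name)


# ---------------------------------------------------------------------------
# cohorts and estimation
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Per-animal event/censor day (whole days) and censoring flags."""

    days: np.ndarray
    censored: np.ndarray

    def __post_init__(self):
        self.days = np.asarray(self.days)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.days.shape != self.censored.shape:
            raise ValueError("days and censored must have equal shapes")
        if np.any(self.days <= 0):
            raise ValueError("days must be positive")

    @property
    def n(self) -> int:
        return self.days.size

    @property
    def n_events(self) -> int:
        return int((~self.censored).sum())


def simulate_cohort(profile: HazardProfile, n: int, seed: int) -> Cohort:
    """Inverse-transform Gompertz lifespans, scored in whole days."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    rate = profile.multiplier * profile.A / profile.G
    t = np.log1p(-np.log(u) / rate) / profile.G
    days = np.maximum(np.ceil(t).astype(int), 1)
    return Cohort(days, np.zeros(n, dtype=bool))


@dataclass(frozen=True)
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _fit_km(cohort: Cohort) -> KaplanMeierFitter:
    if cohort.n_events == 0:
        raise ValueError("no events in cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.days, event_observed=~cohort.censored)
    return kmf


def km_estimate(cohort: Cohort) -> KMEstimate:
    """Product-limit estimator; censored animals leave the risk set at their
    censor day (deaths precede censorings at ties, the standard convention)."""
    kmf = _fit_km(cohort)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 \
        else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, kmf.survival_function_.columns[0]]
    return KMEstimate(times, surv.to_numpy(dtype=float),
                      table["at_risk"].to_numpy(dtype=int))


def mean_lifespan(cohort: Cohort) -> tuple[float, float]:
    """Mean +/- SEM.  Censor-free cohorts use the arithmetic mean with
    sd/sqrt(n); censored cohorts use the restricted mean from the KM curve
    with a Greenwood-based variance of the area."""
    if cohort.n_events < 2:
        raise ValueError("need >= 2 events to estimate a mean lifespan")
    if not cohort.censored.any():
        days = cohort.days.astype(float)
        return float(days.mean()), float(days.std(ddof=1) / math.sqrt(days.size))
    kmf = _fit_km(cohort)
    horizon = float(cohort.days.max())
    rmst, var = restricted_mean_survival_time(kmf, t=horizon, return_variance=True)
    return float(rmst), float(math.sqrt(max(var, 0.0)))


def logrank(cohort_a: Cohort, cohort_b: Cohort) -> tuple[float, float]:
    """Mantel--Cox log-rank chi-square (1 df) and two-sided p."""
    if cohort_a.n_events == 0 or cohort_b.n_events == 0:
        raise ValueError("both cohorts need events")
    res = logrank_test(cohort_a.days, cohort_b.days,
                       event_observed_A=~cohort_a.censored,
                       event_observed_B=~cohort_b.censored)
    return float(res.test_statistic), float(res.p_value)


def percent_extension(treated: Cohort, control: Cohort) -> float:
    """100 * (mean_treated - mean_control) / mean_control."""
    mean_t, _ = mean_lifespan(treated)
    mean_c, _ = mean_lifespan(control)
    if mean_c <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (mean_t - mean_c) / mean_c
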