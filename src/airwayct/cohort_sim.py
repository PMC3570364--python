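"""Synthetic heavy-smoker screening cohort.

Generates a cohort of elderly male heavy smokers with the marginal
distributions and structural associations of a lung-cancer-screening
population: log-normal airway wall thickness (AWT at 3.5 mm lumen
diameter), normal Perc15 correlated with log-AWT, airflow limitation
(FEV1 %predicted) generated as a linear function of log-AWT and Perc15
plus residual noise, and respiratory symptoms as logistic functions of
log-AWT.  The defaults are calibrated so that, at n = 492:

* FEV1 %predicted has mean ~98.2 and SD ~19.7;
* AWT_3.5 has median ~0.57 mm with quartiles ~(0.44, 0.74);
* Perc15 has median ~-920 HU with quartiles ~(-930, -907);
* the multivariable coefficients of FEV1%pred on (log-AWT, Perc15) are
  -31.28 %pred per log-mm and 0.342 %pred per HU.

Where a printed summary gives a median and interquartile range, the
log-scale (or plain) SD is recovered with the normal identity
``IQR = 2 * z(0.75) * SD`` (z(0.75) = 0.6745).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Z75 = 0.674489750196082  # standard normal upper quartile

SYMPTOMS = ("cmh", "cough", "dyspnea", "wheezing")

#: symptom prevalences of the target population (proportions)
DEFAULT_PREVALENCE = {"cmh": 0.297, "cough": 0.327, "dyspnea": 0.284,
                      "wheezing": 0.253}


@dataclass
class CohortParams:
    n: int = 492
    age_mean: float = 59.4
    age_sd: float = 5.2
    packyears_log_mu: float = math.log(34.0)
    packyears_log_sd: float = (math.log(45.6) - math.log(28.0)) / (2 * Z75)
    current_smoking_prob: float = 0.591
    awt_log_mu: float = math.log(0.57)
    awt_log_sd: float = (math.log(0.74) - math.log(0.44)) / (2 * Z75)
    perc15_mu: float = -920.0
    perc15_sd: float = (-907.0 - (-930.0)) / (2 * Z75)
    # correlation between log-AWT and Perc15; not printed anywhere, derived
    # from the univariate slope of log-AWT on Perc15 (0.003 per HU):
    # rho = b * sd(perc15) / sd(logAWT)
    rho_awt_perc15: float = 0.003 * ((-907.0 + 930.0) / (2 * Z75)) / (
        (math.log(0.74) - math.log(0.44)) / (2 * Z75)
    )
    beta_logawt: float = -31.28
    beta_perc15: float = 0.342
    beta0: float = float("nan")  # solved in default_params / __post_init__
    resid_sd: float = float("nan")
    fev1pp_mean: float = 98.2
    fev1pp_sd: float = 19.7
    laa_log_mu: float = math.log(2.5)
    laa_log_sd: float = (math.log(4.3) - math.log(1.3)) / (2 * Z75)
    lung_volume_mean_l: float = 6.5
    lung_volume_sd_l: float = 1.4
    fev1_mean_l: float = 3.45
    fev1_fvc_mean: float = 70.0
    symptom_slopes: dict = field(
        default_factory=lambda: {s: 1.3 for s in SYMPTOMS}
    )
    symptom_intercepts: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.current_smoking_prob <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        for sd in (self.age_sd, self.awt_log_sd, self.perc15_sd,
                   self.packyears_log_sd):
            if sd <= 0:
                raise ValueError("standard deviations must be positive")
        if not abs(self.rho_awt_perc15) < 1:
            raise ValueError("|rho| must be < 1")
        if math.isnan(self.beta0):
            # solve the intercept so E[fev1pp] hits the target at the means
            self.beta0 = (
                self.fev1pp_mean
                - self.beta_logawt * self.awt_log_mu
                - self.beta_perc15 * self.perc15_mu
            )
        if math.isnan(self.resid_sd):
            cov = self.rho_awt_perc15 * self.awt_log_sd * self.perc15_sd
            explained = (
                self.beta_logawt**2 * self.awt_log_sd**2
                + self.beta_perc15**2 * self.perc15_sd**2
                + 2 * self.beta_logawt * self.beta_perc15 * cov
            )
            resid_var = self.fev1pp_sd**2 - explained
            if resid_var <= 0:
                raise ValueError(
                    "target FEV1%pred SD is smaller than the variance implied "
                    "by the structural coefficients"
                )
            self.resid_sd = math.sqrt(resid_var)
        if not self.symptom_intercepts:
            self.symptom_intercepts = {
                s: _solve_logistic_intercept(
                    DEFAULT_PREVALENCE[s],
                    self.symptom_slopes[s],
                    self.awt_log_mu,
                    self.awt_log_sd,
                )
                for s in SYMPTOMS
            }


def _solve_logistic_intercept(
    prevalence: float, slope: float, mu: float, sd: float
) -> float:
    """Intercept a such that E[logistic(a + slope * X)] = prevalence for
    X ~ Normal(mu, sd), by bisection over a Gauss-Hermite expectation."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(61)
    x = mu + sd * nodes
    w = weights / weights.sum()

    def mean_prob(a: float) -> float:
        return float(np.sum(w / (1.0 + np.exp(-(a + slope * x)))))

    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_prob(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def default_params(n: int = 492, seed: int = 0) -> CohortParams:
    """Cohort parameters calibrated to the target population summaries."""
    return CohortParams(n=n, seed=seed)


def simulate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Draw a cohort table, one row per subject.

    Structure: (log-AWT, Perc15) bivariate normal with correlation
    ``rho_awt_perc15``; FEV1 %predicted linear in both plus Gaussian
    residual; symptoms Bernoulli with logistic probability in log-AWT;
    %LAA-950 a fixed monotone (log-linear) transform of Perc15 so its
    marginal is log-normal; FEV1 (L) and FEV1/FVC are descriptive
    transforms of FEV1 %predicted.  Deterministic under ``params.seed``.
    """
    p = params or default_params()
    if p.n < 10:
        raise ValueError("cohort size must be at least 10")
    rng = np.random.default_rng(p.seed)

    age = rng.normal(p.age_mean, p.age_sd, p.n)
    pack_years = np.exp(rng.normal(p.packyears_log_mu, p.packyears_log_sd, p.n))
    current = rng.random(p.n) < p.current_smoking_prob

    cov = p.rho_awt_perc15 * p.awt_log_sd * p.perc15_sd
    mean = [p.awt_log_mu, p.perc15_mu]
    cov_m = [[p.awt_log_sd**2, cov], [cov, p.perc15_sd**2]]
    log_awt, perc15 = rng.multivariate_normal(mean, cov_m, p.n).T
    awt = np.exp(log_awt)

    fev1pp = (
        p.beta0
        + p.beta_logawt * log_awt
        + p.beta_perc15 * perc15
        + rng.normal(0.0, p.resid_sd, p.n)
    )
    fev1pp = np.maximum(fev1pp, 10.0)

    # %LAA-950: fixed monotone map of Perc15 (lower Perc15 -> more LAA),
    # giving a log-normal marginal with the target median and IQR
    z = -(perc15 - p.perc15_mu) / p.perc15_sd
    laa = np.exp(p.laa_log_mu + p.laa_log_sd * z)
    laa = np.clip(laa, 0.0, 100.0)

    lung_volume = rng.normal(p.lung_volume_mean_l, p.lung_volume_sd_l, p.n)
    lung_volume = np.maximum(lung_volume, 2.0)

    # descriptive-only spirometry companions of FEV1 %predicted
    fev1_l = p.fev1_mean_l * fev1pp / p.fev1pp_mean + rng.normal(0, 0.15, p.n)
    fev1_l = np.maximum(fev1_l, 0.5)
    fev1_fvc = (
        p.fev1_fvc_mean
        + 0.35 * (fev1pp - p.fev1pp_mean)
        + rng.normal(0, 4.0, p.n)
    )
    fev1_fvc = np.clip(fev1_fvc, 20.0, 95.0)

    table = pd.DataFrame(
        {
            "subject_id": np.arange(1, p.n + 1),
            "age": age,
            "pack_years": pack_years,
            "current_smoking": current,
            "awt35_mm": awt,
            "log_awt35": log_awt,
            "perc15_hu": perc15,
            "laa950_pct": laa,
            "lung_volume_l": lung_volume,
            "fev1_l": fev1_l,
            "fev1_pct_pred": fev1pp,
            "fev1_fvc_pct": fev1_fvc,
        }
    )
    for s in SYMPTOMS:
        prob = 1.0 / (
            1.0 + np.exp(-(p.symptom_intercepts[s] + p.symptom_slopes[s] * log_awt))
        )
        table[s] = rng.random(p.n) < prob
    return table
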