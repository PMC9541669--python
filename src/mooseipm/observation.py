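"""The two observation channels linking latent abundance to data.

1. Aerial surveys (winter): the survey estimate anchors the latent log
   abundance.  In a surveyed year the state density is
   Normal(log N_hat, (se / N_hat)^2) — the survey SE mapped to the log scale
   by the delta method — and *no* process error is applied; in unsurveyed
   years the state follows the Gompertz prediction with process SD
   sigma_proj.

2. Hunter questionnaires (fall): moose seen per unit-year follow an
   overdispersed Poisson whose rate is proportional to the preharvest
   population (next winter's postharvest plus that fall's harvest):

       y ~ Poisson(lambda),
       log lambda = alpha + theta . z + log(exp(mu_next) + E) + eta,
       eta ~ Normal(0, sigma_obs^2)

   alpha is the log of the average observable proportion of preharvest
   moose, z holds observation covariates (days hunted, fall snow index),
   and eta absorbs overdispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    InvalidCountError,
    InvalidParameterError,
    InvalidSurveyError,
)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class AerialSurvey:
    """One winter survey: abundance estimate, its SE, and a conducted flag."""

    estimate: float = float("nan")
    se: float = float("nan")
    conducted: int = 0

    def __post_init__(self) -> None:
        if self.conducted not in (0, 1):
            raise InvalidSurveyError("conducted flag must be 0 or 1")
        if self.conducted == 1:
            if not (self.estimate > 0):
                raise InvalidSurveyError("conducted survey needs estimate > 0")
            if not (self.se >= 0):
                raise InvalidSurveyError("conducted survey needs se >= 0")


@dataclass
class ObservationParams:
    """Hierarchical parameters of the hunter-count channel."""

    alpha: np.ndarray            # per-unit log detection intercepts
    theta: np.ndarray            # per-unit (J, n_cov) covariate effects
    sigma_obs: float             # SD of the observation-level overdispersion
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    mu_theta: np.ndarray | None = None
    sigma_theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, float))
        self.theta = np.atleast_2d(np.asarray(self.theta, float))
        if self.sigma_obs < 0 or self.sigma_alpha < 0:
            raise InvalidParameterError("observation SDs must be >= 0")
        if self.mu_theta is None:
            self.mu_theta = np.zeros(self.theta.shape[1])
        if self.sigma_theta is None:
            self.sigma_theta = np.zeros(self.theta.shape[1])


@dataclass(frozen=True)
class HunterObservation:
    """Moose seen by hunters in one unit-year, with observation covariates."""

    moose_seen: int
    days_hunted: float
    snow_index: float = 0.0

    def __post_init__(self) -> None:
        if self.moose_seen < 0 or self.moose_seen != int(self.moose_seen):
            raise InvalidCountError("moose_seen must be a non-negative integer")
        if not self.days_hunted > 0:
            raise InvalidParameterError("days_hunted must be > 0")


def delta_log_se(estimate: float, se: float) -> float:
    """First-order (delta-method) SD of log(N_hat): se / N_hat."""
    est = np.asarray(estimate, float)
    if np.any(est <= 0):
        raise InvalidSurveyError("survey estimate must be > 0")
    if np.any(np.asarray(se, float) < 0):
        raise InvalidSurveyError("survey se must be >= 0")
    out = np.asarray(se, float) / est
    return float(out) if out.ndim == 0 else out


def _normal_logpdf(x, mean, sd):
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI


def state_logdensity(mu: float, predicted_n: float, sigma_proj: float,
                     survey: AerialSurvey) -> float:
    """Log density of the latent winter state mu.

    Surveyed year (w=1): Normal(log N_hat, (se/N_hat)^2) — the survey
    replaces the process-error term entirely.  Unsurveyed year (w=0):
    Normal(log predicted_n, sigma_proj^2) from the growth map.
    """
    if survey.conducted == 1:
        sd = delta_log_se(survey.estimate, survey.se)
        mean = math.log(survey.estimate)
    else:
        if not predicted_n > 0:
            raise InvalidParameterError("predicted abundance must be > 0")
        sd = sigma_proj
        mean = math.log(predicted_n)
    if sd == 0.0:
        return 0.0 if mu == mean else -math.inf
    return float(_normal_logpdf(mu, mean, sd))


def hunter_count_rate(alpha: float, theta, z, mu_next: float, harvest: float,
                      eta: float = 0.0) -> float:
    """Poisson mean for moose seen: detection times preharvest population.

    The preharvest population exp(mu_next) + E is an offset; alpha, the
    covariate term theta.z and the overdispersion draw eta act
    multiplicatively on it.
    """
    pre = math.exp(mu_next) + harvest
    if not pre > 0:
        raise InvalidParameterError("preharvest population must be > 0")
    lin = alpha + float(np.dot(np.atleast_1d(theta), np.atleast_1d(z))) + eta
    if not math.isfinite(lin):
        raise InvalidParameterError("non-finite linear predictor")
    return math.exp(lin) * pre


def hunter_count_loglik(y: int, lam: float) -> float:
    """Poisson log pmf of the observed hunter count."""
    if y < 0 or y != int(y):
        raise InvalidCountError("count must be a non-negative integer")
    if not lam > 0:
        raise InvalidParameterError("Poisson rate must be > 0")
    return float(stats.poisson.logpmf(int(y), lam))


def simulate_hunter_counts(alpha, cov_term, mu_next, harvest, sigma_obs,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw overdispersed counts: eta ~ N(0, sigma_obs^2), y ~ Poisson.

    ``cov_term`` is the already-assembled theta . z contribution (array
    broadcastable against alpha and mu_next).
    """
    alpha = np.asarray(alpha, float)
    eta = rng.normal(0.0, sigma_obs,
                     size=np.broadcast(alpha, np.asarray(mu_next)).shape)
    pre = np.exp(mu_next) + harvest
    lam = np.exp(alpha + cov_term + eta) * pre
    return rng.poisson(lam)
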