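"""Deterministic skeleton of the moose population process.

The process model is a discrete-time Gompertz growth model on the log scale
with harvest subtracted on the natural scale.  Writing ``mu_t`` for the log
of postharvest abundance in winter ``t``, the expected postharvest abundance
one year later is

    N_{t+1} = exp(mu_t + r_max + b * mu_t + beta_pred * c_t
                  + beta_cN * c_t * mu_t + beta_deer * d_t) - E_t

where ``c_t`` and ``d_t`` are standardized canid and deer sighting rates from
the fall hunt, ``E_t`` is the number of moose harvested that fall, and the
composite predator coefficient is

    beta_pred = beta_canids + beta_bears * bear_density.

``r_max`` is the intrinsic growth rate from minimal abundance (N = 1), shared
across management units; ``b`` is the (negative) density-dependence
coefficient; the canid-by-log-abundance interaction ``beta_cN`` lets the
predation effect weaken or strengthen with moose abundance.

This module holds the parameter containers, the one-step growth map, the
closed-form equilibrium under proportional harvest, and deterministic or
stochastic forward projection.  It knows nothing about observation error or
inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateStateError,
    InvalidHarvestError,
    InvalidParameterError,
    NoStableEquilibriumError,
)

__all__ = [
    "CovariateVector",
    "LatentState",
    "UnitParams",
    "ProcessParams",
    "HarvestRule",
    "predator_coefficient",
    "log_growth_increment",
    "growth_step",
    "equilibrium_log_abundance",
    "equilibrium_abundance",
    "Trajectory",
    "project_trajectory",
]


@dataclass(frozen=True)
class CovariateVector:
    """Standardized covariates entering the growth model for one unit-year.

    bear_density is static within a unit; canid_rate and deer_rate are
    per-hunter-day sighting rates from the fall of the source year.
    """

    canid_rate: float = 0.0
    deer_rate: float = 0.0
    bear_density: float = 0.0

    def __post_init__(self) -> None:
        for name in ("canid_rate", "deer_rate", "bear_density"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"non-finite covariate {name!r}")


@dataclass(frozen=True)
class LatentState:
    """Log postharvest abundance and realized harvest for one unit-year."""

    mu: float
    harvest_total: float = 0.0

    def __post_init__(self) -> None:
        if self.harvest_total < 0:
            raise InvalidParameterError("harvest_total must be >= 0")
        if not math.isfinite(self.mu):
            raise InvalidParameterError("mu must be finite")

    @property
    def postharvest(self) -> float:
        return math.exp(self.mu)

    @property
    def preharvest(self) -> float:
        return math.exp(self.mu) + self.harvest_total


@dataclass(frozen=True)
class UnitParams:
    """Process parameters for a single management unit."""

    r_max: float
    b: float
    beta_canids: float = 0.0
    beta_cN: float = 0.0
    beta_deer: float = 0.0
    beta_bears: float = 0.0
    sigma_proj: float = 0.0

    def __post_init__(self) -> None:
        vals = [self.r_max, self.b, self.beta_canids, self.beta_cN,
                self.beta_deer, self.beta_bears, self.sigma_proj]
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError("non-finite process parameter")
        if self.sigma_proj < 0:
            raise InvalidParameterError("sigma_proj must be >= 0")
        if not -2.0 <= self.b <= 2.0:
            raise InvalidParameterError("b outside the truncation bounds [-2, 2]")


@dataclass
class ProcessParams:
    """Hierarchical process parameters across J management units.

    Unit-level coefficients are length-J arrays; population-level means and
    between-unit SDs describe the normal distributions they arise from.
    """

    r_max: float
    b: np.ndarray
    beta_canids: np.ndarray
    beta_cN: np.ndarray
    beta_deer: np.ndarray
    beta_bears: float
    sigma_proj: float
    mu_b: float = 0.0
    sigma_b: float = 0.0
    mu_beta_canids: float = 0.0
    sigma_beta_canids: float = 0.0
    mu_beta_cN: float = 0.0
    sigma_beta_cN: float = 0.0
    mu_beta_deer: float = 0.0
    sigma_beta_deer: float = 0.0

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.beta_canids = np.asarray(self.beta_canids, dtype=float)
        self.beta_cN = np.asarray(self.beta_cN, dtype=float)
        self.beta_deer = np.asarray(self.beta_deer, dtype=float)
        for name in ("sigma_b", "sigma_beta_canids", "sigma_beta_cN",
                     "sigma_beta_deer", "sigma_proj"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if np.any(np.abs(self.b) > 2.0):
            raise InvalidParameterError("b outside the truncation bounds [-2, 2]")

    @property
    def n_units(self) -> int:
        return self.b.size

    def unit(self, j: int) -> UnitParams:
        """Scalar parameter slice for management unit ``j``."""
        return UnitParams(
            r_max=self.r_max,
            b=float(self.b[j]),
            beta_canids=float(self.beta_canids[j]),
            beta_cN=float(self.beta_cN[j]),
            beta_deer=float(self.beta_deer[j]),
            beta_bears=self.beta_bears,
            sigma_proj=self.sigma_proj,
        )

    @classmethod
    def from_population(cls, n_units: int, r_max: float, mu_b: float,
                        mu_beta_canids: float = 0.0, mu_beta_cN: float = 0.0,
                        mu_beta_deer: float = 0.0, beta_bears: float = 0.0,
                        sigma_proj: float = 0.0) -> "ProcessParams":
        """All unit-level coefficients pinned at their population means."""
        ones = np.ones(n_units)
        return cls(
            r_max=r_max, b=mu_b * ones, beta_canids=mu_beta_canids * ones,
            beta_cN=mu_beta_cN * ones, beta_deer=mu_beta_deer * ones,
            beta_bears=beta_bears, sigma_proj=sigma_proj,
            mu_b=mu_b, mu_beta_canids=mu_beta_canids,
            mu_beta_cN=mu_beta_cN, mu_beta_deer=mu_beta_deer,
        )


def predator_coefficient(beta_canids: float, beta_bears: float,
                         bear_density: float) -> float:
    """Composite predator effect: canid coefficient modulated by bear density.

    Bear density is static within a unit, so the bear term shifts the unit's
    canid effect additively rather than entering the model on its own.
    """
    out = np.asarray(beta_canids) + np.asarray(beta_bears) * np.asarray(bear_density)
    if not np.all(np.isfinite(out)) or not (
        np.all(np.isfinite(beta_canids))
        and np.all(np.isfinite(beta_bears))
        and np.all(np.isfinite(bear_density))
    ):
        raise InvalidParameterError("non-finite input to predator_coefficient")
    return float(out) if out.ndim == 0 else out


def log_growth_increment(mu_prev: float, params: UnitParams,
                         x_prev: CovariateVector) -> float:
    """Linear predictor increment: log(preharvest_t) - mu_{t-1}."""
    beta_pred = predator_coefficient(params.beta_canids, params.beta_bears,
                                     x_prev.bear_density)
    return (params.r_max
            + params.b * mu_prev
            + beta_pred * x_prev.canid_rate
            + params.beta_cN * x_prev.canid_rate * mu_prev
            + params.beta_deer * x_prev.deer_rate)


def growth_step(mu_prev: float, params: UnitParams, x_prev: CovariateVector,
                harvest: float) -> float:
    """One step of the growth map: expected postharvest abundance.

    Returns ``exp(mu_prev + increment) - harvest``; raises
    DegenerateStateError when harvest meets or exceeds production rather than
    silently returning a non-positive abundance.
    """
    if harvest < 0:
        raise InvalidParameterError("harvest must be >= 0")
    pre = math.exp(mu_prev + log_growth_increment(mu_prev, params, x_prev))
    post = pre - harvest
    if post <= 0:
        raise DegenerateStateError(
            f"harvest {harvest:.1f} >= production {pre:.1f}")
    return post


def _b_effective(params: UnitParams, x_bar: CovariateVector) -> float:
    return params.b + params.beta_cN * x_bar.canid_rate


def equilibrium_log_abundance(params: UnitParams, x_bar: CovariateVector,
                              h: float = 0.0) -> float:
    """Fixed point mu* of the growth map under proportional harvest.

    With harvest E = h * preharvest the log-scale map is affine,
    mu' = mu + r_max + b_eff * mu + beta.x + log(1 - h), giving

        mu* = -(r_max + beta_pred c + beta_deer d + log(1 - h)) / b_eff

    which is stable exactly when b_eff = b + beta_cN * c < 0.
    """
    if not 0.0 <= h < 1.0:
        raise InvalidHarvestError(f"harvest rate {h} outside [0, 1)")
    b_eff = _b_effective(params, x_bar)
    if b_eff >= 0:
        raise NoStableEquilibriumError(
            f"effective density dependence {b_eff:.4f} >= 0")
    beta_pred = predator_coefficient(params.beta_canids, params.beta_bears,
                                     x_bar.bear_density)
    numer = (params.r_max + beta_pred * x_bar.canid_rate
             + params.beta_deer * x_bar.deer_rate + math.log1p(-h))
    return -numer / b_eff


def equilibrium_abundance(params: UnitParams, x_bar: CovariateVector,
                          h: float = 0.0) -> float:
    """Equilibrium postharvest abundance N* = exp(mu*)."""
    return math.exp(equilibrium_log_abundance(params, x_bar, h))


@dataclass(frozen=True)
class HarvestRule:
    """Per-year harvest rule for projection.

    kind="proportion": E_t = value_t * preharvest_t (value scalar or vector).
    kind="absolute":   E_t = value_t moose removed (vector or scalar).
    """

    kind: str
    value: float | Sequence[float] | np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("proportion", "absolute"):
            raise InvalidParameterError(f"unknown harvest rule kind {self.kind!r}")

    @classmethod
    def proportion(cls, value) -> "HarvestRule":
        return cls("proportion", value)

    @classmethod
    def absolute(cls, value) -> "HarvestRule":
        return cls("absolute", value)

    def amounts(self, n_years: int, preharvest: np.ndarray | None = None):
        v = np.broadcast_to(np.asarray(self.value, dtype=float), (n_years,))
        return v

    def harvest_at(self, t: int, preharvest: float, n_years: int) -> float:
        v = np.broadcast_to(np.asarray(self.value, dtype=float), (n_years,))[t]
        if self.kind == "proportion":
            if not 0.0 <= v < 1.0:
                raise InvalidHarvestError(f"proportional harvest {v} outside [0, 1)")
            return v * preharvest
        if v < 0:
            raise InvalidHarvestError(f"absolute harvest {v} < 0")
        return float(v)


@dataclass
class Trajectory:
    """Projected abundance path for one unit.

    mu has length n_years + 1 (winter states, mu[0] = initial); preharvest,
    harvest and postharvest have length n_years (falls).  If the population
    hits the degenerate state (postharvest <= floor), `extinct` is set and
    the path is truncated at `extinction_year` (arrays are NaN afterwards).
    """

    mu: np.ndarray
    preharvest: np.ndarray
    harvest: np.ndarray
    postharvest: np.ndarray
    extinct: bool = False
    extinction_year: int | None = None

    @property
    def n_years(self) -> int:
        return self.preharvest.size


def project_trajectory(params: UnitParams, mu_init: float,
                       harvest_schedule: HarvestRule | float,
                       x_series: Sequence[CovariateVector] | CovariateVector,
                       n_years: int, process_noise: bool = False,
                       seed: int | np.random.Generator | None = None,
                       floor: float = 1.0) -> Trajectory:
    """Project the population forward n_years from log abundance mu_init.

    With process_noise on, each winter state receives a Normal(0, sigma_proj)
    innovation on the log scale; with it off the projection is deterministic
    and the seed is irrelevant.  When harvest drives postharvest abundance to
    or below `floor` (default 1 moose, so the log state stays defined) the
    trajectory is truncated and flagged extinct.
    """
    if n_years < 1:
        raise InvalidParameterError("n_years must be >= 1")
    if isinstance(harvest_schedule, (int, float)):
        harvest_schedule = HarvestRule.proportion(float(harvest_schedule))
    if isinstance(x_series, CovariateVector):
        x_series = [x_series] * n_years
    if len(x_series) != n_years:
        raise InvalidParameterError("x_series length must equal n_years")
    rng = np.random.default_rng(seed)

    mu = np.full(n_years + 1, np.nan)
    pre = np.full(n_years, np.nan)
    har = np.full(n_years, np.nan)
    post = np.full(n_years, np.nan)
    mu[0] = mu_init
    extinct = False
    extinction_year = None
    for t in range(n_years):
        p = math.exp(mu[t] + log_growth_increment(mu[t], params, x_series[t]))
        e = harvest_schedule.harvest_at(t, p, n_years)
        n_post = p - e
        pre[t], har[t] = p, e
        if n_post <= floor:
            post[t] = max(n_post, 0.0)
            extinct = True
            extinction_year = t
            break
        mu[t + 1] = math.log(n_post)
        if process_noise and params.sigma_proj > 0:
            mu[t + 1] += rng.normal(0.0, params.sigma_proj)
        # realized postharvest (includes the process innovation)
        post[t] = math.exp(mu[t + 1])
    return Trajectory(mu=mu, preharvest=pre, harvest=har, postharvest=post,
                      extinct=extinct, extinction_year=extinction_year)
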