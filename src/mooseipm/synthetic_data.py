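"""Synthetic monitoring data with the structure the integrated model assumes.

The generator mirrors the full generative chain: hierarchical unit-level
parameters drawn around population means, latent Gompertz dynamics with
process noise and harvest subtraction, class-structured harvest through
tags x success with partial questionnaire return, sparse aerial surveys with
lognormal error, and overdispersed Poisson hunter counts with observation
covariates.  A truth ledger (all latent states, realized harvests and drawn
parameters) accompanies the observed tables so parameter- and state-recovery
can be scored.

Default design values emulate the Ontario moose monitoring program:
55 units followed for 20 years, aerial surveys in a sparse subset of winters
(2-7 per unit, median 5, always including the first winter, which anchors
the initial-abundance prior), annual questionnaire response averaging 74.1%
(year-to-year range roughly 0.51-0.80), and harvest removing 3.5-11.3% of
the preharvest population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import covariates as cov
from .exceptions import InvalidParameterError

__all__ = ["TrueParams", "SyntheticDesign", "SyntheticDataset", "generate",
           "scenario_bank", "DensityScenario", "CounterfactualScenario"]


@dataclass(frozen=True)
class TrueParams:
    """Population-level generative parameters (hyper-level truth).

    Defaults are the fitted population-level posterior means for the Ontario
    moose system; between-unit SDs and the process/observation SDs are not
    printed at that level and are set to values typical of northern ungulate
    monitoring (see docs/methods.md).
    """

    r_max: float = 0.487
    mu_b: float = -0.058
    sigma_b: float = 0.015
    mu_beta_canids: float = -0.195
    sigma_beta_canids: float = 0.06
    mu_beta_cN: float = 0.023
    sigma_beta_cN: float = 0.008
    mu_beta_deer: float = -0.022
    sigma_beta_deer: float = 0.012
    beta_bears: float = -0.013
    sigma_proj: float = 0.08
    mu_alpha: float = -0.445
    sigma_alpha: float = 0.15
    theta_days: float = 0.734
    theta_snow: float = 0.028
    sigma_theta_days: float = 0.08
    sigma_theta_snow: float = 0.01
    sigma_obs: float = 0.15


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design for one synthetic province."""

    n_units: int = 55
    n_years: int = 20
    first_year: int = 1999
    # per-unit survey counts are drawn on {2..7} with median 5
    survey_count_probs: tuple = (0.10, 0.12, 0.18, 0.30, 0.20, 0.10)
    survey_cv: float = 0.2
    response_rate_mean: float = 0.741
    response_rate_range: tuple = (0.508, 0.803)
    # harvest pressure: per-unit target proportion of initial preharvest
    harvest_rate_range: tuple = (0.035, 0.113)
    tag_class_split: tuple = (0.5, 0.3, 0.2)          # bull, cow, calf
    class_success: tuple = (0.45, 0.40, 0.25)
    # initial log postharvest abundance, uniform across units; the bounds
    # are the low/high reference unit sizes (100 and 6,000 moose)
    log_n0_range: tuple = (4.6, 8.7)
    mean_area_km2: float = 9409.0
    days_per_hunter: float = 6.0
    # AR(1) sighting-rate processes (on the log scale)
    canid_ar: tuple = (0.5, 0.25)                      # (phi, innovation SD)
    deer_ar: tuple = (0.5, 0.35)
    params: TrueParams = field(default_factory=TrueParams)
    poisson_counts: bool = True
    floor: float = 1.0
    seed: int | None = None
    # optional per-year multiplier on the tag allocation (harvest scenarios)
    harvest_multipliers: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_years < 2:
            raise InvalidParameterError("need n_units >= 1 and n_years >= 2")
        if not 0 <= self.response_rate_range[0] <= self.response_rate_range[1] <= 1:
            raise InvalidParameterError("response-rate range outside [0, 1]")


@dataclass
class SyntheticDataset:
    """Observed tables plus the ground-truth ledger."""

    observations: pd.DataFrame
    truth: pd.DataFrame
    unit_params: pd.DataFrame
    params: TrueParams
    design: SyntheticDesign


def _response_rate(rng: np.random.Generator, design: SyntheticDesign,
                   n: int) -> np.ndarray:
    lo, hi = design.response_rate_range
    if hi == lo:
        return np.full(n, float(lo))
    mean_pos = (design.response_rate_mean - lo) / (hi - lo)
    conc = 10.0
    return lo + (hi - lo) * rng.beta(mean_pos * conc, (1 - mean_pos) * conc, n)


def generate(design: SyntheticDesign,
             seed: int | np.random.Generator | None = None) -> SyntheticDataset:
    """Simulate one synthetic province under the given design."""
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    p = design.params
    J, T = design.n_units, design.n_years
    years = design.first_year + np.arange(T)

    # ---- unit-level parameters drawn around population means -------------
    b = np.clip(rng.normal(p.mu_b, p.sigma_b, J), -2.0, 2.0)
    beta_c = rng.normal(p.mu_beta_canids, p.sigma_beta_canids, J)
    beta_cN = rng.normal(p.mu_beta_cN, p.sigma_beta_cN, J)
    beta_d = rng.normal(p.mu_beta_deer, p.sigma_beta_deer, J)
    alpha = rng.normal(p.mu_alpha, p.sigma_alpha, J)
    th_days = rng.normal(p.theta_days, p.sigma_theta_days, J)
    th_snow = rng.normal(p.theta_snow, p.sigma_theta_snow, J)

    # ---- raw covariates --------------------------------------------------
    def ar1_field(mean_log_loc, mean_log_sd, phi, tau):
        base = rng.normal(mean_log_loc, mean_log_sd, J)
        x = np.empty((J, T))
        x[:, 0] = base + rng.normal(0, tau / np.sqrt(1 - phi**2), J)
        for t in range(1, T):
            x[:, t] = base + phi * (x[:, t - 1] - base) + rng.normal(0, tau, J)
        return np.exp(x)

    canid_raw = ar1_field(np.log(0.05), 0.5, *design.canid_ar)
    deer_raw = ar1_field(np.log(0.30), 0.7, *design.deer_ar)
    snow_raw = (rng.normal(300.0, 50.0, J)[:, None]
                + rng.normal(0.0, 60.0, T)[None, :]
                + rng.normal(0.0, 30.0, (J, T)))
    bear_raw = np.exp(rng.normal(np.log(20.0), 0.4, J))
    area = np.exp(rng.normal(np.log(design.mean_area_km2), 0.3, J))

    canid_x, _ = cov.standardize(canid_raw.ravel())
    deer_x, _ = cov.standardize(deer_raw.ravel())
    snow_z, _ = cov.standardize(snow_raw.ravel())
    canid_x = canid_x.reshape(J, T)
    deer_x = deer_x.reshape(J, T)
    snow_z = snow_z.reshape(J, T)
    bear_x, _ = cov.standardize(bear_raw) if J > 1 else (np.zeros(J), None)

    beta_pred = beta_c + p.beta_bears * bear_x

    # ---- harvest pressure and effort ------------------------------------
    # tag allocations track the current population (managers adjust tags
    # yearly), holding each unit's target harvest proportion roughly
    # constant through time
    mu0 = rng.uniform(*design.log_n0_range, J)
    h_target = rng.uniform(*design.harvest_rate_range, J)
    mean_succ = float(np.dot(design.tag_class_split, design.class_success))
    split = np.asarray(design.tag_class_split)
    hmult = (np.ones(T) if design.harvest_multipliers is None
             else np.broadcast_to(np.asarray(design.harvest_multipliers, float), (T,)))
    resp_rate = _response_rate(rng, design, T)

    succ = np.asarray(design.class_success)

    # ---- latent dynamics + harvest + observations ------------------------
    mu = np.empty((J, T + 1))
    mu[:, 0] = mu0
    harvest_tot = np.empty((J, T))
    pre_expected = np.empty((J, T))
    eo_all = np.empty((J, T, 3))
    resp_all = np.empty((J, T, 3))
    tags_all = np.empty((J, T, 3))
    succ_hat = np.empty((J, T, 3))
    degenerate = np.zeros((J, T), dtype=bool)

    for t in range(T):
        incr = (p.r_max + b * mu[:, t] + beta_pred * canid_x[:, t]
                + beta_cN * canid_x[:, t] * mu[:, t] + beta_d * deer_x[:, t])
        pre = np.exp(mu[:, t] + incr)
        pre_expected[:, t] = pre
        tags_total_t = np.maximum(
            np.round(h_target * pre / mean_succ * hmult[t]), 3)
        tags_t = np.maximum(
            np.round(tags_total_t[:, None] * split[None, :]), 1).astype(int)
        reporters = rng.binomial(tags_t, resp_rate[t])
        eo = rng.binomial(reporters, succ[None, :])
        unknown = rng.binomial(tags_t - reporters, succ[None, :])
        h_tot = (eo + unknown).sum(axis=1).astype(float)
        # cap harvest where it would drive the unit below the floor
        cap = np.maximum(pre - design.floor, 0.0)
        over = h_tot > cap
        if np.any(over):
            degenerate[over, t] = True
            scale = np.where(h_tot > 0, cap / np.maximum(h_tot, 1e-12), 0.0)
            eo = np.where(over[:, None], np.floor(eo * scale[:, None]), eo)
            unknown = np.where(over[:, None],
                               np.floor(unknown * scale[:, None]), unknown)
            h_tot = (eo + unknown).sum(axis=1).astype(float)
        post = np.maximum(pre - h_tot, design.floor)
        mu[:, t + 1] = np.log(post)
        if p.sigma_proj > 0:
            mu[:, t + 1] += rng.normal(0.0, p.sigma_proj, J)
        harvest_tot[:, t] = h_tot
        eo_all[:, t] = eo
        resp_all[:, t] = reporters
        tags_all[:, t] = tags_t
        with np.errstate(invalid="ignore", divide="ignore"):
            succ_hat[:, t] = np.where(reporters > 0, eo / np.maximum(reporters, 1), 0.0)

    if degenerate.any(axis=1).sum() > 0.5 * J:
        warnings.warn(
            f"design drove {int(degenerate.any(axis=1).sum())} of {J} units "
            "to the degenerate floor", RuntimeWarning, stacklevel=2)

    # realized preharvest seen by hunters in fall t
    pre_realized = np.exp(mu[:, 1:]) + harvest_tot

    # effort follows the tag allocation (one hunter per tag)
    days_raw = (tags_all.sum(axis=2)
                * rng.normal(design.days_per_hunter, 1.0, (J, T)).clip(min=1.0))
    days_z, _ = cov.standardize(days_raw.ravel())
    days_z = days_z.reshape(J, T)

    cov_term = th_days[:, None] * days_z + th_snow[:, None] * snow_z
    lam = np.exp(alpha[:, None] + cov_term
                 + (rng.normal(0.0, p.sigma_obs, (J, T)) if p.sigma_obs > 0
                    else 0.0)) * pre_realized
    y = rng.poisson(lam) if design.poisson_counts else np.round(lam)

    # ---- aerial surveys --------------------------------------------------
    counts = 2 + rng.choice(6, size=J, p=design.survey_count_probs)
    counts = np.minimum(counts, T)
    conducted = np.zeros((J, T), dtype=int)
    conducted[:, 0] = 1  # first winter anchors the initial-abundance prior
    for j in range(J):
        extra = rng.choice(np.arange(1, T), size=counts[j] - 1, replace=False)
        conducted[j, extra] = 1
    sigma_log = design.survey_cv
    est = np.where(
        conducted == 1,
        np.exp(mu[:, :T] + (rng.normal(0.0, sigma_log, (J, T)) if sigma_log > 0
                            else 0.0)),
        np.nan)
    se = design.survey_cv * est

    # ---- assemble tables -------------------------------------------------
    unit_ids = np.array([f"WMU{j + 1:02d}" for j in range(J)])
    jj, tt = np.meshgrid(np.arange(J), np.arange(T), indexing="ij")
    obs = pd.DataFrame({
        "unit_id": unit_ids[jj.ravel()],
        "year": years[tt.ravel()],
        "area_km2": np.round(area[jj.ravel()], 1),
        "aerial_estimate": np.round(est.ravel(), 1),
        "aerial_se": np.round(se.ravel(), 1),
        "survey_conducted": conducted.ravel(),
        "hunter_moose_seen": y.ravel().astype(int),
        "days_hunted": np.round(days_raw.ravel(), 1),
        "canids_per_day": np.round(canid_raw.ravel(), 4),
        "deer_per_day": np.round(deer_raw.ravel(), 4),
        "snow_index": np.round(snow_raw.ravel(), 1),
        "bear_density": np.round(bear_raw[jj.ravel()], 3),
    })
    for k, cls in enumerate(("bull", "cow", "calf")):
        obs[f"tags_issued_{cls}"] = tags_all[:, :, k].ravel().astype(int)
        obs[f"reported_harvest_{cls}"] = eo_all[:, :, k].ravel().astype(int)
        obs[f"respondents_{cls}"] = resp_all[:, :, k].ravel().astype(int)
        obs[f"reported_success_{cls}"] = np.round(succ_hat[:, :, k].ravel(), 4)

    jj2, tt2 = np.meshgrid(np.arange(J), np.arange(T + 1), indexing="ij")
    fall = tt2 < T  # the final winter state has no fall data
    truth = pd.DataFrame({
        "unit_id": unit_ids[jj2.ravel()],
        "year": (design.first_year + tt2).ravel(),
        "mu_true": mu.ravel(),
        "postharvest_true": np.exp(mu.ravel()),
        "harvest_true": np.where(fall.ravel(), np.pad(
            harvest_tot, ((0, 0), (0, 1)), constant_values=np.nan).ravel(), np.nan),
        "preharvest_true": np.where(fall.ravel(), np.pad(
            pre_realized, ((0, 0), (0, 1)), constant_values=np.nan).ravel(), np.nan),
        "degenerate": np.pad(degenerate, ((0, 0), (0, 1)),
                             constant_values=False).ravel(),
    })

    unit_params = pd.DataFrame({
        "unit_id": unit_ids, "b": b, "beta_canids": beta_c, "beta_cN": beta_cN,
        "beta_deer": beta_d, "alpha": alpha, "theta_days": th_days,
        "theta_snow": th_snow, "bear_x": bear_x, "mu0": mu0,
        "h_target": h_target,
    })
    return SyntheticDataset(observations=obs, truth=truth,
                            unit_params=unit_params, params=p, design=design)


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DensityScenario:
    """A reference management unit at a named moose density."""

    name: str
    n_moose: float
    area_km2: float = 9409.0

    @property
    def density_per_100km2(self) -> float:
        return self.n_moose / self.area_km2 * 100.0


@dataclass(frozen=True)
class CounterfactualScenario:
    """Per-year harvest multipliers for a retrospective scenario."""

    name: str
    multipliers: tuple

    def design(self, base: SyntheticDesign | None = None) -> SyntheticDesign:
        base = base or SyntheticDesign()
        return replace(base, harvest_multipliers=self.multipliers,
                       n_years=len(self.multipliers))


def scenario_bank() -> dict:
    """Named presets: density levels, harvest regimes, and counterfactuals.

    Densities are 100 / 1600 / 6000 moose in an average-sized 9,409 km^2
    unit (1.1 / 17.0 / 63.8 per 100 km^2).  Harvest regimes span the range
    of realized provincial harvest proportions (none, low 3.5%, average
    7.4%, high 11.3%).  "fig6b" reduces harvest by 35% over the first eight
    years (1999-2006) and leaves it unchanged afterwards.
    """
    n_years = 20
    early = 8  # 1999-2006 inclusive
    bank = {
        "low": DensityScenario("low", 100.0),
        "average": DensityScenario("average", 1600.0),
        "high": DensityScenario("high", 6000.0),
        "harvest_regimes": (0.0, 0.035, 0.074, 0.113),
        "fig6b": CounterfactualScenario(
            "fig6b", tuple([0.65] * early + [1.0] * (n_years - early))),
    }
    return bank


def get_scenario(name: str):
    bank = scenario_bank()
    if name not in bank:
        raise KeyError(f"unknown scenario preset {name!r}; "
                       f"choose from {sorted(bank)}")
    return bank[name]
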