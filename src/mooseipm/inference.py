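"""Joint posterior assembly and MCMC sampling for the integrated model.

The joint density couples three layers over J management units and T years:

* process: latent log postharvest abundance ``mu[j, t]`` follows the
  Gompertz map with harvest subtraction; process error sigma_proj applies
  only in winters without an aerial survey, where the survey SE (delta
  method, log scale) replaces it;
* harvest: the unreported harvest component is a sum of class-level
  binomials, handled by its matching normal approximation and sampled as a
  continuous latent ``E[j, t]``;
* observation: hunter counts are Poisson with the realized preharvest
  population as offset, unit-level detection intercepts and covariate
  effects, and a per-observation overdispersion latent ``eta[j, t]``.

Unit-level coefficients arise from normal population-level distributions
(hyper-mean + between-unit SD); priors follow the published analysis where
stated (informative r_max prior, density dependence truncated at +/-2,
survey-based initial abundance priors) and are vague otherwise.

Sampling is adaptive Metropolis-within-Gibbs: latent states by single-site
random-walk updates with an even/odd-year schedule, unit-level coefficients
by vectorized per-unit updates, hyper-means by conjugate Gibbs draws,
scale parameters and the remaining scalars by slice sampling, plus one
joint "ridge" move along the r_max / density-dependence tradeoff.  Step
sizes adapt during burn-in only.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import harvest as harvest_mod
from . import covariates as cov
from .exceptions import (
    DegenerateCovariateError,
    InsufficientChainsError,
    InvalidParameterError,
    MooseIPMError,
)
from .observation import delta_log_se

logger = logging.getLogger("mooseipm")

_LOG_2PI = math.log(2.0 * math.pi)

SCALAR_PARAMS = (
    "r_max", "beta_bears",
    "mu_b", "sigma_b",
    "mu_beta_canids", "sigma_beta_canids",
    "mu_beta_cN", "sigma_beta_cN",
    "mu_beta_deer", "sigma_beta_deer",
    "mu_alpha", "sigma_alpha",
    "mu_theta_days", "sigma_theta_days",
    "mu_theta_snow", "sigma_theta_snow",
    "sigma_proj", "sigma_obs",
)
UNIT_PARAMS = ("b", "beta_canids", "beta_cN", "beta_deer",
               "alpha", "theta_days", "theta_snow")
_HYPER = {  # unit param -> (hyper mean name, hyper sd name)
    "b": ("mu_b", "sigma_b"),
    "beta_canids": ("mu_beta_canids", "sigma_beta_canids"),
    "beta_cN": ("mu_beta_cN", "sigma_beta_cN"),
    "beta_deer": ("mu_beta_deer", "sigma_beta_deer"),
    "alpha": ("mu_alpha", "sigma_alpha"),
    "theta_days": ("mu_theta_days", "sigma_theta_days"),
    "theta_snow": ("mu_theta_snow", "sigma_theta_snow"),
}


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorConfig:
    """Prior settings; defaults follow the published analysis where stated."""

    r_max_mean: float = 0.304
    r_max_sd: float = 0.08
    b_bounds: tuple = (-2.0, 2.0)
    hyper_mean_sd: float = 10.0        # vague Normal(0, .) on hyper-means
    hyper_sd_scale: float = 5.0        # half-Normal(0, .) on between-unit SDs
    sigma_proj_scale: float = 5.0
    sigma_obs_scale: float = 5.0
    init_se_floor: float = 1e-3        # numerical floor on log-scale survey SE
    init_fallback_sd: float = 0.5      # initial prior SD when year 0 unsurveyed

    def __post_init__(self) -> None:
        if self.b_bounds[0] >= self.b_bounds[1]:
            raise InvalidParameterError("b truncation bounds must be ordered")
        for name in ("r_max_sd", "hyper_mean_sd", "hyper_sd_scale",
                     "sigma_proj_scale", "sigma_obs_scale"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class FitConfig:
    """Sampler settings.

    Desk-scale defaults (3 chains, 16,000 adaptive burn-in sweeps, 40,000
    sampling sweeps thinned to every 20th) replace the published
    three-chain, two-million-iteration run; the long settings remain
    reachable through these fields.
    """

    chains: int = 3
    iterations: int = 40_000
    burn_in: int = 16_000
    thinning: int = 20
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.burn_in < 0:
            raise InvalidParameterError("iterations > 0 and burn_in >= 0 required")
        if self.thinning < 1:
            raise InvalidParameterError("thinning must be >= 1")
        if self.chains < 1:
            raise InvalidParameterError("chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return self.iterations // self.thinning


# --------------------------------------------------------------------------
# model assembly
# --------------------------------------------------------------------------

@dataclass
class ModelData:
    """Aligned arrays for the fitted units (J x T)."""

    unit_ids: np.ndarray
    years: np.ndarray
    canid: np.ndarray
    deer: np.ndarray
    z_days: np.ndarray
    z_snow: np.ndarray
    bear_x: np.ndarray
    y: np.ndarray
    y_mask: np.ndarray
    surveyed: np.ndarray
    log_nhat: np.ndarray
    se_log: np.ndarray
    e_known: np.ndarray
    e_mean: np.ndarray
    e_sd: np.ndarray
    e_span: np.ndarray
    mu0_mean: np.ndarray
    mu0_sd: np.ndarray
    excluded_units: list

    @property
    def J(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]


class Model:
    """Joint log-posterior evaluator over parameters and latent states."""

    def __init__(self, data: ModelData, priors: PriorConfig,
                 harvest_mode: str = "latent"):
        if harvest_mode not in ("latent", "fixed"):
            raise InvalidParameterError(f"unknown harvest_mode {harvest_mode!r}")
        self.data = data
        self.priors = priors
        self.harvest_mode = harvest_mode
        # destination-year process mask: column t covers transition t -> t+1;
        # the process density applies when the destination winter is
        # unsurveyed (the terminal state T always is)
        md = data
        proc = np.ones((md.J, md.T), dtype=bool)
        proc[:, : md.T - 1] = ~md.surveyed[:, 1:]
        self.proc_mask = proc
        self._dest_lognhat = np.concatenate(
            [md.log_nhat[:, 1:], np.zeros((md.J, 1))], axis=1)
        self._dest_se = np.concatenate(
            [md.se_log[:, 1:], np.ones((md.J, 1))], axis=1)
        self.e_mask = (md.e_sd > 0) if harvest_mode == "latent" else np.zeros(
            (md.J, md.T), dtype=bool)

    # -- density pieces ---------------------------------------------------

    def process_terms(self, st: dict) -> np.ndarray:
        """Per-transition process log density (J x T); -inf if degenerate."""
        md = self.data
        mu_src = st["mu"][:, : md.T]
        bpred = st["beta_canids"] + st["beta_bears"] * md.bear_x
        logpre = (mu_src * (1.0 + st["b"][:, None]) + st["r_max"]
                  + bpred[:, None] * md.canid
                  + st["beta_cN"][:, None] * md.canid * mu_src
                  + st["beta_deer"][:, None] * md.deer)
        with np.errstate(over="ignore", invalid="ignore"):
            post = np.exp(logpre) - st["E"]
            ok = np.isfinite(post) & (post > 0)
            sd = max(st["sigma_proj"], 1e-300)
            z = (st["mu"][:, 1:] - np.log(np.where(ok, post, 1.0))) / sd
            lp = -0.5 * z * z - math.log(sd) - 0.5 * _LOG_2PI
            out = np.where(self.proc_mask, np.where(ok, lp, -np.inf), 0.0)
        return out

    def in_terms(self, st: dict) -> np.ndarray:
        """Per-state incoming log density (J x (T+1)).

        Column 0 is the initial-abundance prior; column s >= 1 is the
        process term for transition s-1 -> s in unsurveyed winters and the
        survey anchor in surveyed winters.
        """
        md = self.data
        out = np.empty((md.J, md.T + 1))
        z0 = (st["mu"][:, 0] - md.mu0_mean) / md.mu0_sd
        out[:, 0] = -0.5 * z0 * z0 - np.log(md.mu0_sd) - 0.5 * _LOG_2PI
        proc = self.process_terms(st)
        # destination-aligned survey anchors: state s pairs with the survey
        # of winter s (the terminal state T has none)
        zs = (st["mu"][:, 1:] - self._dest_lognhat) / self._dest_se
        surv = -0.5 * zs * zs - np.log(self._dest_se) - 0.5 * _LOG_2PI
        out[:, 1:] = np.where(self.proc_mask, proc, surv)
        return out

    def obs_terms(self, st: dict) -> np.ndarray:
        """Poisson hunter-count log likelihood (J x T), constants dropped."""
        md = self.data
        with np.errstate(over="ignore", invalid="ignore"):
            loglam = (st["alpha"][:, None]
                      + st["theta_days"][:, None] * md.z_days
                      + st["theta_snow"][:, None] * md.z_snow
                      + st["eta"]
                      + np.log(np.exp(st["mu"][:, 1:]) + st["E"]))
            raw = md.y * loglam - np.exp(loglam)
            out = np.where(md.y_mask, np.where(np.isfinite(raw), raw, -np.inf),
                           0.0)
        return out

    def prior_logp(self, st: dict) -> float:
        pr = self.priors
        md = self.data
        lp = _norm_lp(st["r_max"], pr.r_max_mean, pr.r_max_sd)
        lp += _norm_lp(st["beta_bears"], 0.0, pr.hyper_mean_sd)
        lo, hi = pr.b_bounds
        if not lo <= st["mu_b"] <= hi or np.any(st["b"] < lo) or np.any(st["b"] > hi):
            return -np.inf
        for name in ("mu_b", "mu_beta_canids", "mu_beta_cN", "mu_beta_deer",
                     "mu_alpha", "mu_theta_days", "mu_theta_snow"):
            lp += _norm_lp(st[name], 0.0, pr.hyper_mean_sd)
        for name in ("sigma_b", "sigma_beta_canids", "sigma_beta_cN",
                     "sigma_beta_deer", "sigma_alpha", "sigma_theta_days",
                     "sigma_theta_snow"):
            lp += _half_norm_lp(st[name], pr.hyper_sd_scale)
        lp += _half_norm_lp(st["sigma_proj"], pr.sigma_proj_scale)
        lp += _half_norm_lp(st["sigma_obs"], pr.sigma_obs_scale)
        if not np.isfinite(lp):
            return -np.inf
        for uname, (m, s) in _HYPER.items():
            sd = max(st[s], 1e-300)
            lp += float(np.sum(_norm_lp(st[uname], st[m], sd)))
        if self.e_mask.any():
            e, m, s = st["E"][self.e_mask], md.e_mean[self.e_mask], md.e_sd[self.e_mask]
            lo_e = md.e_known[self.e_mask]
            hi_e = lo_e + md.e_span[self.e_mask]
            if np.any(e < lo_e) or np.any(e > hi_e):
                return -np.inf
            lp += float(np.sum(_norm_lp(e, m, s)))
        sd_obs = max(st["sigma_obs"], 1e-300)
        lp += float(np.sum(_norm_lp(st["eta"][md.y_mask], 0.0, sd_obs)))
        return lp

    def logp(self, st: dict) -> float:
        """Full joint log posterior (unnormalized)."""
        lp = self.prior_logp(st)
        if not np.isfinite(lp):
            return -np.inf
        lp += float(np.sum(self.in_terms(st))) + float(np.sum(self.obs_terms(st)))
        return lp

    # -- initialization ---------------------------------------------------

    def initial_state(self, rng: np.random.Generator) -> dict:
        md = self.data
        J, T = md.J, md.T
        mu = np.empty((J, T + 1))
        ts = np.arange(T)
        for j in range(J):
            s = np.flatnonzero(md.surveyed[j])
            mu[j, :T] = np.interp(ts, s, md.log_nhat[j, s])
            mu[j, T] = mu[j, T - 1]
        mu += rng.normal(0.0, 0.01, mu.shape)
        e0 = md.e_mean.copy()
        pre = np.exp(mu[:, 1:]) + e0
        # start the observation layer at a per-unit least-squares fit of
        # log(count / offset) on the observation covariates; a zero start
        # dumps the effort effect into the overdispersion terms and can
        # strand the chain in an inflated-variance region
        alpha0 = np.full(J, -0.5)
        th1_0 = np.zeros(J)
        th2_0 = np.zeros(J)
        resid = np.zeros((J, T))
        with np.errstate(divide="ignore"):
            r_jt = np.where(md.y_mask, np.log((md.y + 1.0) / pre), 0.0)
        for j in range(J):
            idx = np.flatnonzero(md.y_mask[j])
            if idx.size >= 4:
                x = np.column_stack([np.ones(idx.size), md.z_days[j, idx],
                                     md.z_snow[j, idx]])
                coef, *_ = np.linalg.lstsq(x, r_jt[j, idx], rcond=None)
                alpha0[j], th1_0[j], th2_0[j] = coef
                resid[j, idx] = r_jt[j, idx] - x @ coef
            elif idx.size > 0:
                alpha0[j] = r_jt[j, idx].mean()
                resid[j, idx] = r_jt[j, idx] - alpha0[j]
        sig_obs0 = float(np.clip(np.std(resid[md.y_mask]) if md.y_mask.any()
                                 else 0.2, 0.05, 1.0))
        st = {
            "r_max": self.priors.r_max_mean + 0.01 * rng.standard_normal(),
            "beta_bears": 0.0,
            "mu_b": -0.05, "sigma_b": 0.05,
            "mu_beta_canids": 0.0, "sigma_beta_canids": 0.05,
            "mu_beta_cN": 0.0, "sigma_beta_cN": 0.02,
            "mu_beta_deer": 0.0, "sigma_beta_deer": 0.02,
            "mu_alpha": float(np.mean(alpha0)),
            "sigma_alpha": float(np.clip(np.std(alpha0), 0.05, 1.0)),
            "mu_theta_days": float(np.mean(th1_0)),
            "sigma_theta_days": float(np.clip(np.std(th1_0), 0.02, 1.0)),
            "mu_theta_snow": float(np.mean(th2_0)),
            "sigma_theta_snow": float(np.clip(np.std(th2_0), 0.01, 1.0)),
            "sigma_proj": 0.1, "sigma_obs": sig_obs0,
            "b": -0.05 + 0.01 * rng.standard_normal(J),
            "beta_canids": 0.01 * rng.standard_normal(J),
            "beta_cN": 0.005 * rng.standard_normal(J),
            "beta_deer": 0.005 * rng.standard_normal(J),
            "alpha": alpha0 + 0.01 * rng.standard_normal(J),
            "theta_days": th1_0 + 0.01 * rng.standard_normal(J),
            "theta_snow": th2_0 + 0.01 * rng.standard_normal(J),
            "mu": mu,
            "E": e0,
            "eta": np.clip(resid, -1.0, 1.0) * md.y_mask,
        }
        self._repair_feasibility(st)
        return st

    def _repair_feasibility(self, st: dict) -> None:
        """Raise interpolated states where harvest would exceed production.

        The interpolated start can imply postharvest <= 0 in declining
        units; lift the source log abundance until production comfortably
        exceeds the initial harvest so the chain starts at finite density.
        """
        md = self.data
        for _ in range(10):
            mu_src = st["mu"][:, : md.T]
            bpred = st["beta_canids"] + st["beta_bears"] * md.bear_x
            logpre = (mu_src * (1.0 + st["b"][:, None]) + st["r_max"]
                      + bpred[:, None] * md.canid
                      + st["beta_cN"][:, None] * md.canid * mu_src
                      + st["beta_deer"][:, None] * md.deer)
            post = np.exp(logpre) - st["E"]
            bad = (post <= 1.0) & self.proc_mask
            if not bad.any():
                return
            slope = np.maximum(
                1.0 + st["b"][:, None] + st["beta_cN"][:, None] * md.canid, 0.5)
            target = np.log(2.0 * st["E"] + 10.0)
            adj = np.where(bad, np.maximum(target - logpre, 0.0) / slope, 0.0)
            st["mu"][:, : md.T] += adj


def _norm_lp(x, mean, sd):
    z = (np.asarray(x, float) - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _half_norm_lp(x, scale):
    if x <= 0:
        return -np.inf
    return -0.5 * (x / scale) ** 2 - math.log(scale)


def build_model(observations: pd.DataFrame, priors: PriorConfig | None = None,
                harvest_mode: str = "latent",
                min_surveys: int = 2) -> Model:
    """Assemble the joint model from a unit-year observation table.

    Units with fewer than ``min_surveys`` aerial surveys are excluded with a
    logged warning (their dynamics cannot be anchored).  Growth and
    observation covariates are standardized (center + scale) across all
    fitted unit-years.
    """
    priors = priors or PriorConfig()
    df = observations.sort_values(["unit_id", "year"]).reset_index(drop=True)
    required = {"unit_id", "year", "aerial_estimate", "aerial_se",
                "survey_conducted", "hunter_moose_seen", "days_hunted",
                "canids_per_day", "deer_per_day", "snow_index", "bear_density"}
    missing = required - set(df.columns)
    if missing:
        raise MooseIPMError(f"observation table missing columns {sorted(missing)}")

    n_surv = df.groupby("unit_id")["survey_conducted"].sum()
    excluded = sorted(n_surv[n_surv < min_surveys].index)
    if excluded:
        logger.warning("excluding %d unit(s) with < %d aerial surveys: %s",
                       len(excluded), min_surveys, ", ".join(map(str, excluded)))
        df = df[~df["unit_id"].isin(excluded)]
    if df.empty:
        raise MooseIPMError("no units with enough aerial surveys to fit")

    units = np.asarray(sorted(df["unit_id"].unique()))
    years = np.asarray(sorted(df["year"].unique()))
    J, T = len(units), len(years)
    uidx = {u: j for j, u in enumerate(units)}
    yidx = {y: t for t, y in enumerate(years)}

    def grid(col, fill=np.nan):
        out = np.full((J, T), fill)
        out[df["unit_id"].map(uidx), df["year"].map(yidx)] = df[col].to_numpy(float)
        return out

    surveyed = grid("survey_conducted", 0.0).astype(bool)
    est = grid("aerial_estimate")
    se = grid("aerial_se")
    log_nhat = np.where(surveyed, np.log(np.where(surveyed, est, 1.0)), 0.0)
    se_log = np.where(surveyed,
                      np.maximum(delta_log_se(np.where(surveyed, est, 1.0),
                                              np.nan_to_num(se)),
                                 priors.init_se_floor),
                      1.0)

    y_raw = grid("hunter_moose_seen")
    days = grid("days_hunted")
    y_mask = np.isfinite(y_raw) & np.isfinite(days) & (days > 0)
    y = np.where(y_mask, np.nan_to_num(y_raw), 0.0)

    def std_grid(values):
        try:
            z, _ = cov.standardize(values.ravel())
        except DegenerateCovariateError:
            z = np.zeros(values.size)  # missing/constant covariate is inert
        return np.nan_to_num(z.reshape(J, T))

    canid = std_grid(grid("canids_per_day"))
    deer = std_grid(grid("deer_per_day"))
    z_days = std_grid(days)
    z_snow = std_grid(grid("snow_index"))
    bear_by_unit = df.groupby("unit_id")["bear_density"].first().reindex(units)
    if J > 1 and bear_by_unit.nunique() > 1:
        bear_x, _ = cov.standardize(bear_by_unit.to_numpy())
    else:
        bear_x = np.zeros(J)

    e_known = np.zeros((J, T))
    e_mean = np.zeros((J, T))
    e_var = np.zeros((J, T))
    e_span = np.zeros((J, T))
    has_report = all(f"reported_harvest_{c}" in df.columns
                     for c in harvest_mod.CLASSES)
    if has_report:
        for c in harvest_mod.CLASSES:
            eo = grid(f"reported_harvest_{c}", 0.0)
            tags = grid(f"tags_issued_{c}", 0.0)
            resp = grid(f"respondents_{c}", 0.0)
            s = np.nan_to_num(grid(f"reported_success_{c}", 0.0))
            # zero-respondent fallback: unit-level pooled multi-year success
            with np.errstate(invalid="ignore", divide="ignore"):
                pooled = np.nansum(eo, axis=1) / np.maximum(
                    np.nansum(resp, axis=1), 1.0)
            s = np.where(resp > 0, s, pooled[:, None])
            n = np.maximum(np.nan_to_num(tags) - np.nan_to_num(resp), 0.0)
            e_known += np.nan_to_num(eo)
            e_mean += n * s
            e_var += n * s * (1.0 - s)
            e_span += n
    e_mean += e_known
    e_sd = np.sqrt(e_var)

    mu0_mean = np.empty(J)
    mu0_sd = np.empty(J)
    for j in range(J):
        s_years = np.flatnonzero(surveyed[j])
        first = s_years[0]
        mu0_mean[j] = log_nhat[j, first]
        mu0_sd[j] = se_log[j, first] if first == 0 else max(
            se_log[j, first], priors.init_fallback_sd)

    md = ModelData(
        unit_ids=units, years=years, canid=canid, deer=deer,
        z_days=z_days, z_snow=z_snow, bear_x=bear_x,
        y=y, y_mask=y_mask, surveyed=surveyed,
        log_nhat=log_nhat, se_log=se_log,
        e_known=e_known, e_mean=e_mean, e_sd=e_sd, e_span=e_span,
        mu0_mean=mu0_mean, mu0_sd=mu0_sd, excluded_units=excluded)
    return Model(md, priors, harvest_mode=harvest_mode)


# --------------------------------------------------------------------------
# samplers
# --------------------------------------------------------------------------

def _slice_sample(x0: float, logf, rng: np.random.Generator, w: float = 1.0,
                  max_steps: int = 30) -> float:
    """Univariate slice sampler (stepping out + shrinkage)."""
    f0 = logf(x0)
    if not np.isfinite(f0):
        return x0
    y = f0 - rng.exponential()
    u = rng.uniform()
    left, right = x0 - w * u, x0 + w * (1.0 - u)
    for _ in range(max_steps):
        if logf(left) <= y:
            break
        left -= w
    for _ in range(max_steps):
        if logf(right) <= y:
            break
        right += w
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _gibbs_normal_mean(devs: np.ndarray, sd: float, prior_sd: float,
                       rng: np.random.Generator,
                       bounds: tuple | None = None) -> float:
    """Conjugate draw of a normal hyper-mean, optionally truncated."""
    n = devs.size
    var = max(sd, 1e-8) ** 2
    prec = n / var + 1.0 / prior_sd**2
    mean = (devs.sum() / var) / prec
    post_sd = 1.0 / math.sqrt(prec)
    if bounds is None:
        return mean + post_sd * rng.standard_normal()
    lo = ndtr((bounds[0] - mean) / post_sd)
    hi = ndtr((bounds[1] - mean) / post_sd)
    u = rng.uniform(lo, hi)
    return mean + post_sd * float(ndtri(min(max(u, 1e-15), 1 - 1e-15)))


class _Sampler:
    """One-chain adaptive Metropolis-within-Gibbs sweep machinery."""

    TARGET = 0.44

    def __init__(self, model: Model, rng: np.random.Generator):
        self.m = model
        self.md = model.data
        self.rng = rng
        J, T = self.md.J, self.md.T
        self.steps = {
            "mu": np.full((J, T + 1), math.log(0.15)),
            "E": np.full((J, T), math.log(1.0)),
            "eta": np.full((J, T), math.log(0.3)),
            "ridge": math.log(0.02),
            "level": np.full(J, math.log(0.05)),
            "segment": np.full(J, math.log(0.1)),
            "tilt": np.full(J, math.log(0.05)),
            "canid_ridge": np.full(J, math.log(0.05)),
            "trend": np.full(J, math.log(0.1)),
            "canid_ridge_pop": math.log(0.05),
            "swap_alpha": np.full(J, math.log(0.05)),
            "swap_theta_days": np.full(J, math.log(0.05)),
            "swap_theta_snow": np.full(J, math.log(0.05)),
        }
        # effort covariate aligned to destination states, zeroed on anchors
        zd = np.concatenate([np.zeros((J, 1)), model.data.z_days], axis=1)
        anchored = np.zeros((J, T + 1), dtype=bool)
        anchored[:, 0] = True
        anchored[:, 1:T] = model.data.surveyed[:, 1:]
        self._zd_free = np.where(anchored, 0.0, zd)
        for name in UNIT_PARAMS:
            self.steps[name] = np.full(J, math.log(0.02))
        # maximal runs of consecutive anchor-free states per unit (state 0
        # is anchored by the initial prior, surveyed states by the survey)
        self._runs = []
        for j in range(J):
            runs, start = [], None
            for s in range(1, T + 1):
                free = s == T or not model.data.surveyed[j, s]
                if free and start is None:
                    start = s
                if not free and start is not None:
                    runs.append((start, s - 1))
                    start = None
            if start is not None:
                runs.append((start, T))
            if not runs:
                runs = [(T, T)]
            self._runs.append(runs)
        self._n_runs = np.array([len(r) for r in self._runs])

    def _gamma(self, it: int) -> float:
        return 2.0 / (1.0 + it) ** 0.6

    # -- latent state updates --------------------------------------------

    def update_mu(self, st: dict, it: int, adapt: bool) -> None:
        m, md, rng = self.m, self.md, self.rng
        T = md.T
        cur_in = m.in_terms(st)
        cur_obs = m.obs_terms(st)
        for color in (0, 1):
            sites = np.arange(color, T + 1, 2)
            prop = st["mu"].copy()
            prop[:, sites] += (np.exp(self.steps["mu"][:, sites])
                               * rng.standard_normal((md.J, sites.size)))
            st2 = dict(st, mu=prop)
            new_in = m.in_terms(st2)
            new_obs = m.obs_terms(st2)
            with np.errstate(invalid="ignore"):
                d = new_in[:, sites] - cur_in[:, sites]
                nxt_ok = sites + 1 <= T
                d[:, nxt_ok] += (new_in[:, sites[nxt_ok] + 1]
                                 - cur_in[:, sites[nxt_ok] + 1])
                prv_ok = sites - 1 >= 0
                d[:, prv_ok] += (new_obs[:, sites[prv_ok] - 1]
                                 - cur_obs[:, sites[prv_ok] - 1])
                d = np.where(np.isnan(d), -np.inf, d)
                acc = np.log(rng.uniform(size=d.shape)) < d
            colvals = st["mu"][:, sites]
            colvals[acc] = prop[:, sites][acc]
            st["mu"][:, sites] = colvals
            # patch cached terms for accepted sites (terms are site-local)
            for cols in (sites, sites[nxt_ok] + 1):
                block = cur_in[:, cols]
                nb = new_in[:, cols]
                a = acc if cols.size == sites.size else acc[:, nxt_ok]
                block[a] = nb[a]
                cur_in[:, cols] = block
            ocols = sites[prv_ok] - 1
            block = cur_obs[:, ocols]
            nb = new_obs[:, ocols]
            block[acc[:, prv_ok]] = nb[acc[:, prv_ok]]
            cur_obs[:, ocols] = block
            if adapt:
                self.steps["mu"][:, sites] += self._gamma(it) * (
                    acc.astype(float) - self.TARGET)

    def _row_block_update(self, st: dict, st2: dict, extra, keys,
                          step_key: str, it: int, adapt: bool,
                          cache, adapt_mask=None) -> None:
        """Accept/reject a per-unit block proposal against cached densities.

        `cache` holds (cur_in, cur_obs), updated in place for accepted
        rows so consecutive block moves share one evaluation of the
        current state.  Each proposal touches only its own unit's row, so
        row-wise acceptance is exact.
        """
        m, rng = self.m, self.rng
        cur_in, cur_obs = cache
        new_in = m.in_terms(st2)
        new_obs = m.obs_terms(st2)
        with np.errstate(invalid="ignore"):
            d = ((new_in - cur_in).sum(axis=1)
                 + (new_obs - cur_obs).sum(axis=1) + extra)
            d = np.where(np.isnan(d), -np.inf, d)
            acc = np.log(rng.uniform(size=self.md.J)) < d
        for k in keys:
            vals = st[k].copy()
            vals[acc] = st2[k][acc]
            st[k] = vals
        cur_in[acc] = new_in[acc]
        cur_obs[acc] = new_obs[acc]
        if adapt:
            upd = self._gamma(it) * (acc.astype(float) - self.TARGET)
            if adapt_mask is not None:
                upd = np.where(adapt_mask, upd, 0.0)
            self.steps[step_key] = np.clip(self.steps[step_key] + upd,
                                           -10.0, 3.0)

    def _eta_compensate(self, st: dict, mu2: np.ndarray):
        """Counter-shift eta so the Poisson rates are exactly invariant.

        Large counts pin log(preharvest) to a few percent, so a path move
        with eta held fixed is rejected beyond tiny steps; moving eta with
        the path transfers the cost to the (much looser) eta prior.  The
        pair (mu, eta) -> (mu2, eta - dlog) is an involution with unit
        Jacobian, so plain Metropolis acceptance applies.
        """
        md = self.md
        with np.errstate(over="ignore"):
            dlog = np.where(
                md.y_mask,
                np.log(np.exp(mu2[:, 1:]) + st["E"])
                - np.log(np.exp(st["mu"][:, 1:]) + st["E"]),
                0.0)
        eta2 = st["eta"] - dlog
        sd = max(st["sigma_obs"], 1e-8)
        extra = np.where(md.y_mask,
                         _norm_lp(eta2, 0.0, sd)
                         - _norm_lp(st["eta"], 0.0, sd), 0.0).sum(axis=1)
        return eta2, extra

    def _pick_run_mask(self, ramp: bool = False) -> np.ndarray:
        """One random anchor-free run per unit, as a (J, T+1) mask or ramp.

        Ramps come in four shapes — symmetric pivot, left-pinned,
        right-pinned, and a random Brownian bridge — so both run ends and
        interior bulges all receive block proposals.
        """
        J, T = self.md.J, self.md.T
        rng = self.rng
        pick = (rng.uniform(size=J) * self._n_runs).astype(int)
        shape = rng.integers(0, 4, size=J) if ramp else None
        out = np.zeros((J, T + 1))
        for j in range(J):
            s, e = self._runs[j][pick[j]]
            if not ramp:
                out[j, s:e + 1] = 1.0
                continue
            n = e - s + 1
            if n < 2:
                continue
            if shape[j] == 0:
                out[j, s:e + 1] = np.linspace(-1.0, 1.0, n)
            elif shape[j] == 1:
                out[j, s:e + 1] = np.linspace(0.0, 1.0, n)
            elif shape[j] == 2:
                out[j, s:e + 1] = np.linspace(1.0, 0.0, n)
            else:
                w = np.concatenate([[0.0], np.cumsum(rng.standard_normal(n - 1))])
                w -= np.linspace(0.0, w[-1], n)  # pin both ends at 0
                peak = np.abs(w).max()
                if peak > 0:
                    out[j, s:e + 1] = w / peak
        return out

    def update_segment(self, st: dict, it: int, adapt: bool, cache) -> None:
        """Shift one whole run of unsurveyed states per unit.

        Between two survey anchors the latent path can move as a block at
        the cost of only the boundary transitions; single-site updates
        cross such gaps by slow diffusion.
        """
        mask = self._pick_run_mask()
        delta = np.exp(self.steps["segment"]) * self.rng.standard_normal(self.md.J)
        mu2 = st["mu"] + delta[:, None] * mask
        eta2, extra = self._eta_compensate(st, mu2)
        st2 = dict(st, mu=mu2, eta=eta2)
        self._row_block_update(st, st2, extra, ("mu", "eta"), "segment",
                               it, adapt, cache)

    def update_trend(self, st: dict, it: int, adapt: bool, cache) -> None:
        """Tilt one run of unsurveyed states linearly in time.

        Long gaps between surveys leave the path's slope weakly determined
        by the hunter counts alone; a centered linear ramp over the run
        explores that direction in one proposal.
        """
        ramp = self._pick_run_mask(ramp=True)
        live = ramp.any(axis=1)  # units whose picked run can actually tilt
        delta = (np.exp(self.steps["trend"]) * self.rng.standard_normal(self.md.J)
                 * live)
        mu2 = st["mu"] + delta[:, None] * ramp
        eta2, extra = self._eta_compensate(st, mu2)
        st2 = dict(st, mu=mu2, eta=eta2)
        self._row_block_update(st, st2, extra, ("mu", "eta"), "trend",
                               it, adapt, cache, adapt_mask=live)

    def update_tilt(self, st: dict, it: int, adapt: bool, cache) -> None:
        """Joint move: shift a unit's effort coefficient, tilt its path.

        Where effort trends with abundance, theta_days[j] and the shape of
        the unanchored path are nearly collinear: proposing
        theta_days[j] += delta with mu[j,s] -= delta * z_days[j,s-1] on
        unsurveyed states leaves the count likelihood almost unchanged and
        lets the process terms and priors pick the mode.
        """
        delta = np.exp(self.steps["tilt"]) * self.rng.standard_normal(self.md.J)
        mu2 = st["mu"] - delta[:, None] * self._zd_free
        # compensate eta for the residual mismatch between the covariate
        # shift and the path shift (exact through the harvest offset)
        md = self.md
        sd_o = max(st["sigma_obs"], 1e-8)
        with np.errstate(over="ignore"):
            dlog = np.where(
                md.y_mask,
                delta[:, None] * md.z_days
                + np.log(np.exp(mu2[:, 1:]) + st["E"])
                - np.log(np.exp(st["mu"][:, 1:]) + st["E"]),
                0.0)
        eta2 = st["eta"] - dlog
        extra = np.where(md.y_mask,
                         _norm_lp(eta2, 0.0, sd_o)
                         - _norm_lp(st["eta"], 0.0, sd_o), 0.0).sum(axis=1)
        sd = max(st["sigma_theta_days"], 1e-8)
        extra = extra + (_norm_lp(st["theta_days"] + delta,
                                  st["mu_theta_days"], sd)
                         - _norm_lp(st["theta_days"], st["mu_theta_days"], sd))
        st2 = dict(st, mu=mu2, eta=eta2,
                   theta_days=st["theta_days"] + delta)
        self._row_block_update(st, st2, extra, ("mu", "eta", "theta_days"),
                               "tilt", it, adapt, cache)

    def update_E(self, st: dict, it: int, adapt: bool) -> None:
        m, md, rng = self.m, self.md, self.rng
        mask = m.e_mask
        if not mask.any():
            return
        cur_in = m.in_terms(st)[:, 1:]
        cur_obs = m.obs_terms(st)
        prop = st["E"] + np.where(
            mask,
            np.exp(self.steps["E"]) * np.maximum(md.e_sd, 0.5)
            * rng.standard_normal(st["E"].shape),
            0.0)
        inb = (prop >= md.e_known) & (prop <= md.e_known + md.e_span)
        st2 = dict(st, E=prop)
        new_in = m.in_terms(st2)[:, 1:]
        new_obs = m.obs_terms(st2)
        sd = np.maximum(md.e_sd, 1e-12)
        with np.errstate(invalid="ignore"):
            d = (new_in - cur_in) + (new_obs - cur_obs) + (
                _norm_lp(prop, md.e_mean, sd) - _norm_lp(st["E"], md.e_mean, sd))
            d = np.where(mask & inb & ~np.isnan(d), d, -np.inf)
            acc = np.log(rng.uniform(size=d.shape)) < d
        st["E"][acc] = prop[acc]
        if adapt:
            upd = mask
            self.steps["E"][upd] += self._gamma(it) * (
                acc[upd].astype(float) - self.TARGET)

    def update_eta(self, st: dict, it: int, adapt: bool) -> None:
        m, md, rng = self.m, self.md, self.rng
        mask = md.y_mask
        cur_obs = m.obs_terms(st)
        prop = st["eta"] + np.where(
            mask, np.exp(self.steps["eta"]) * rng.standard_normal(st["eta"].shape),
            0.0)
        st2 = dict(st, eta=prop)
        new_obs = m.obs_terms(st2)
        sd = max(st["sigma_obs"], 1e-8)
        with np.errstate(invalid="ignore"):
            d = (new_obs - cur_obs) + (_norm_lp(prop, 0.0, sd)
                                       - _norm_lp(st["eta"], 0.0, sd))
            d = np.where(mask & ~np.isnan(d), d, -np.inf)
            acc = np.log(rng.uniform(size=d.shape)) < d
        st["eta"][acc] = prop[acc]
        if adapt:
            self.steps["eta"][mask] += self._gamma(it) * (
                acc[mask].astype(float) - self.TARGET)

    def update_level(self, st: dict, it: int, adapt: bool, cache) -> None:
        """Joint per-unit move: shift the whole latent path, counter-shift
        the detection intercept.

        The abundance level of a unit and its detection intercept trade off
        along a near-flat ridge between sparse survey anchors; single-site
        updates cross it only by a slow random walk.  Proposing
        mu_j += delta, alpha_j -= delta leaves the hunter-count likelihood
        almost unchanged and lets the surveys and priors arbitrate.
        """
        md = self.md
        delta = np.exp(self.steps["level"]) * self.rng.standard_normal(md.J)
        mu2 = st["mu"] + delta[:, None]
        # the harvest offset makes the alpha counter-shift inexact; eta
        # absorbs the residual so the count rates stay invariant
        sd_o = max(st["sigma_obs"], 1e-8)
        with np.errstate(over="ignore"):
            dlog = np.where(
                md.y_mask,
                -delta[:, None]
                + np.log(np.exp(mu2[:, 1:]) + st["E"])
                - np.log(np.exp(st["mu"][:, 1:]) + st["E"]),
                0.0)
        eta2 = st["eta"] - dlog
        extra = np.where(md.y_mask,
                         _norm_lp(eta2, 0.0, sd_o)
                         - _norm_lp(st["eta"], 0.0, sd_o), 0.0).sum(axis=1)
        sd = max(st["sigma_alpha"], 1e-8)
        extra = extra + (_norm_lp(st["alpha"] - delta, st["mu_alpha"], sd)
                         - _norm_lp(st["alpha"], st["mu_alpha"], sd))
        st2 = dict(st, mu=mu2, eta=eta2, alpha=st["alpha"] - delta)
        self._row_block_update(st, st2, extra, ("mu", "eta", "alpha"),
                               "level", it, adapt, cache)

    def update_obs_swap(self, st: dict, it: int, adapt: bool) -> None:
        """Trade each observation coefficient against the eta field.

        For p in {alpha, theta_days, theta_snow} with covariate z (1 for
        alpha): p_j += delta, eta_jt -= delta * z_jt leaves every Poisson
        rate exactly invariant, so acceptance involves only the eta prior
        and the coefficient's hyperprior.  This is the fast operator for
        the detection-parameter / overdispersion tradeoff, which otherwise
        relaxes through the latent path.
        """
        m, md, rng = self.m, self.md, self.rng
        sd_o = max(st["sigma_obs"], 1e-8)
        for name, z in (("alpha", None), ("theta_days", md.z_days),
                        ("theta_snow", md.z_snow)):
            mname, sname = _HYPER[name]
            delta = np.exp(self.steps[f"swap_{name}"]) * rng.standard_normal(md.J)
            zfield = 1.0 if z is None else z
            eta2 = np.where(md.y_mask, st["eta"] - delta[:, None] * zfield,
                            st["eta"])
            sd_p = max(st[sname], 1e-8)
            with np.errstate(invalid="ignore"):
                d = (np.where(md.y_mask,
                              _norm_lp(eta2, 0.0, sd_o)
                              - _norm_lp(st["eta"], 0.0, sd_o), 0.0).sum(axis=1)
                     + _norm_lp(st[name] + delta, st[mname], sd_p)
                     - _norm_lp(st[name], st[mname], sd_p))
                d = np.where(np.isnan(d), -np.inf, d)
                acc = np.log(rng.uniform(size=md.J)) < d
            vals = st[name].copy()
            vals[acc] += delta[acc]
            st[name] = vals
            st["eta"][acc] = eta2[acc]
            if adapt:
                self.steps[f"swap_{name}"] += self._gamma(it) * (
                    acc.astype(float) - self.TARGET)

    # -- unit-level coefficients -----------------------------------------

    def _unit_update(self, st: dict, name: str, terms_fn, it: int,
                     adapt: bool, cur) -> None:
        m, md, rng = self.m, self.md, self.rng
        mname, sname = _HYPER[name]
        prop = st[name] + np.exp(self.steps[name]) * rng.standard_normal(md.J)
        st2 = dict(st, **{name: prop})
        new = terms_fn(st2)
        sd = max(st[sname], 1e-8)
        with np.errstate(invalid="ignore"):
            d = ((new - cur).sum(axis=1)
                 + _norm_lp(prop, st[mname], sd)
                 - _norm_lp(st[name], st[mname], sd))
            if name == "b":
                lo, hi = m.priors.b_bounds
                d = np.where((prop < lo) | (prop > hi), -np.inf, d)
            d = np.where(np.isnan(d), -np.inf, d)
            acc = np.log(rng.uniform(size=md.J)) < d
        vals = st[name].copy()
        vals[acc] = prop[acc]
        st[name] = vals
        cur[acc] = new[acc]
        if adapt:
            self.steps[name] += self._gamma(it) * (acc.astype(float) - self.TARGET)

    def update_units(self, st: dict, it: int, adapt: bool) -> None:
        cur_proc = self.m.process_terms(st)
        for name in ("b", "beta_canids", "beta_cN", "beta_deer"):
            self._unit_update(st, name, self.m.process_terms, it, adapt,
                              cur_proc)
        cur_obs = self.m.obs_terms(st)
        for name in ("alpha", "theta_days", "theta_snow"):
            self._unit_update(st, name, self.m.obs_terms, it, adapt, cur_obs)

    def update_canid_ridge(self, st: dict, it: int, adapt: bool) -> None:
        """Joint per-unit move along the canid-effect tradeoff.

        The growth contribution (beta_canids + beta_cN * mu) * canid is
        nearly invariant under beta_canids += delta,
        beta_cN -= delta / mu_bar; proposing the pair lets the hyperpriors
        and the spread of mu arbitrate, where separate updates crawl.
        """
        m, md, rng = self.m, self.md, self.rng
        mu_bar = st["mu"][:, : md.T].mean(axis=1)
        if np.any(np.abs(mu_bar) < 1.0):
            return
        delta = np.exp(self.steps["canid_ridge"]) * rng.standard_normal(md.J)
        bc2 = st["beta_canids"] + delta
        bcn2 = st["beta_cN"] - delta / mu_bar
        cur = m.process_terms(st).sum(axis=1)
        st2 = dict(st, beta_canids=bc2, beta_cN=bcn2)
        new = m.process_terms(st2).sum(axis=1)
        sd_c = max(st["sigma_beta_canids"], 1e-8)
        sd_n = max(st["sigma_beta_cN"], 1e-8)
        with np.errstate(invalid="ignore"):
            d = ((new - cur)
                 + _norm_lp(bc2, st["mu_beta_canids"], sd_c)
                 - _norm_lp(st["beta_canids"], st["mu_beta_canids"], sd_c)
                 + _norm_lp(bcn2, st["mu_beta_cN"], sd_n)
                 - _norm_lp(st["beta_cN"], st["mu_beta_cN"], sd_n))
            d = np.where(np.isnan(d), -np.inf, d)
            acc = np.log(rng.uniform(size=md.J)) < d
        bc = st["beta_canids"].copy()
        bcn = st["beta_cN"].copy()
        bc[acc] = bc2[acc]
        bcn[acc] = bcn2[acc]
        st["beta_canids"], st["beta_cN"] = bc, bcn
        if adapt:
            self.steps["canid_ridge"] += self._gamma(it) * (
                acc.astype(float) - self.TARGET)

    def update_canid_ridge_pop(self, st: dict, it: int, adapt: bool) -> None:
        """Population-level version of the canid-effect tradeoff move."""
        m, md, rng = self.m, self.md, self.rng
        mu_bar = float(st["mu"].mean())
        if abs(mu_bar) < 1.0:
            return
        delta = math.exp(self.steps["canid_ridge_pop"]) * rng.standard_normal()
        pr = m.priors
        st2 = dict(st,
                   beta_canids=st["beta_canids"] + delta,
                   mu_beta_canids=st["mu_beta_canids"] + delta,
                   beta_cN=st["beta_cN"] - delta / mu_bar,
                   mu_beta_cN=st["mu_beta_cN"] - delta / mu_bar)
        with np.errstate(invalid="ignore"):
            d = (float(np.sum(m.process_terms(st2)) - np.sum(m.process_terms(st)))
                 + float(_norm_lp(st2["mu_beta_canids"], 0.0, pr.hyper_mean_sd)
                         - _norm_lp(st["mu_beta_canids"], 0.0, pr.hyper_mean_sd)
                         + _norm_lp(st2["mu_beta_cN"], 0.0, pr.hyper_mean_sd)
                         - _norm_lp(st["mu_beta_cN"], 0.0, pr.hyper_mean_sd)))
        if math.isnan(d):
            d = -math.inf
        acc = math.log(rng.uniform()) < d
        if acc:
            for k in ("beta_canids", "mu_beta_canids", "beta_cN", "mu_beta_cN"):
                st[k] = st2[k]
        if adapt:
            self.steps["canid_ridge_pop"] += self._gamma(it) * (
                float(acc) - 0.30)

    # -- population-level scalars ----------------------------------------

    def update_ridge(self, st: dict, it: int, adapt: bool) -> None:
        """Joint move along the r_max / density-dependence tradeoff.

        Shifts r_max by delta and every b (and its hyper-mean) by
        -delta / mu_bar, leaving the growth increment at the average log
        abundance unchanged; the priors then discriminate along the ridge.
        """
        m, rng = self.m, self.rng
        pr = m.priors
        mu_bar = float(np.mean(st["mu"]))
        if abs(mu_bar) < 1.0:
            return
        delta = math.exp(self.steps["ridge"]) * rng.standard_normal()
        st2 = dict(st,
                   r_max=st["r_max"] + delta,
                   mu_b=st["mu_b"] - delta / mu_bar,
                   b=st["b"] - delta / mu_bar)
        lo, hi = pr.b_bounds
        if st2["mu_b"] < lo or st2["mu_b"] > hi or np.any(
                (st2["b"] < lo) | (st2["b"] > hi)):
            return
        with np.errstate(invalid="ignore"):
            d = (float(np.sum(m.process_terms(st2)) - np.sum(m.process_terms(st)))
                 + _norm_lp(st2["r_max"], pr.r_max_mean, pr.r_max_sd)
                 - _norm_lp(st["r_max"], pr.r_max_mean, pr.r_max_sd)
                 + _norm_lp(st2["mu_b"], 0.0, pr.hyper_mean_sd)
                 - _norm_lp(st["mu_b"], 0.0, pr.hyper_mean_sd))
        if math.isnan(d):
            d = -math.inf
        acc = math.log(rng.uniform()) < d
        if acc:
            st["r_max"], st["mu_b"], st["b"] = st2["r_max"], st2["mu_b"], st2["b"]
        if adapt:
            self.steps["ridge"] += self._gamma(it) * (float(acc) - 0.30)

    def update_scalars(self, st: dict) -> None:
        m, md, rng = self.m, self.md, self.rng
        pr = m.priors

        # r_max and beta_bears only shift the linear predictor; reusing the
        # current production P0 makes each slice evaluation a handful of
        # elementwise operations instead of a full density pass
        mask = m.proc_mask
        mu_src = st["mu"][:, : md.T]
        bpred = st["beta_canids"] + st["beta_bears"] * md.bear_x
        lp0 = (mu_src * (1.0 + st["b"][:, None]) + st["r_max"]
               + bpred[:, None] * md.canid
               + st["beta_cN"][:, None] * md.canid * mu_src
               + st["beta_deer"][:, None] * md.deer)
        p0 = np.exp(lp0[mask])
        e_m = st["E"][mask]
        mu_dest = st["mu"][:, 1:][mask]
        n_proc = p0.size

        def shifted_proc_sum(shift):
            with np.errstate(over="ignore", invalid="ignore"):
                post = p0 * np.exp(shift) - e_m
                if np.any(~np.isfinite(post) | (post <= 0)):
                    return -np.inf
                z = (mu_dest - np.log(post)) / st["sigma_proj"]
                return float(-0.5 * np.sum(z * z)) - n_proc * (
                    math.log(st["sigma_proj"]) + 0.5 * _LOG_2PI)

        r0 = st["r_max"]
        st["r_max"] = _slice_sample(
            r0,
            lambda r: shifted_proc_sum(r - r0)
            + float(_norm_lp(r, pr.r_max_mean, pr.r_max_sd)),
            rng, w=0.05)
        shift_r = st["r_max"] - r0
        if np.any(md.bear_x != 0.0):
            bb0 = st["beta_bears"]
            bear_shift = (np.broadcast_to(md.bear_x[:, None] * md.canid,
                                          mask.shape))[mask]
            st["beta_bears"] = _slice_sample(
                bb0,
                lambda v: shifted_proc_sum(shift_r + (v - bb0) * bear_shift)
                + float(_norm_lp(v, 0.0, pr.hyper_mean_sd)),
                rng, w=0.05)
        else:
            st["beta_bears"] = float(rng.normal(0.0, pr.hyper_mean_sd))

        # conjugate hyper-means, slice-sampled hyper-SDs
        for uname, (mname, sname) in _HYPER.items():
            bounds = pr.b_bounds if uname == "b" else None
            st[mname] = _gibbs_normal_mean(st[uname], st[sname],
                                           pr.hyper_mean_sd, rng, bounds)
            devs = st[uname] - st[mname]
            ss = float(np.sum(devs**2))
            n = devs.size

            def logf(t, ss=ss, n=n):
                s = math.exp(t)
                return (-n * t - ss / (2 * s * s)
                        - 0.5 * (s / pr.hyper_sd_scale) ** 2 + t)

            st[sname] = math.exp(_slice_sample(math.log(max(st[sname], 1e-8)),
                                               logf, rng, w=0.7))

        # sigma_proj conditional depends on the residuals only through
        # their sum of squares
        bpred_now = st["beta_canids"] + st["beta_bears"] * md.bear_x
        lp_now = (mu_src * (1.0 + st["b"][:, None]) + st["r_max"]
                  + bpred_now[:, None] * md.canid
                  + st["beta_cN"][:, None] * md.canid * mu_src
                  + st["beta_deer"][:, None] * md.deer)
        post_now = np.exp(lp_now[mask]) - e_m
        resid = mu_dest - np.log(np.maximum(post_now, 1e-300))
        ss_proc = float(np.sum(resid * resid))

        def logf_sp(t):
            s = math.exp(t)
            return (-n_proc * t - ss_proc / (2 * s * s)
                    - 0.5 * (s / pr.sigma_proj_scale) ** 2 + t)

        st["sigma_proj"] = math.exp(_slice_sample(
            math.log(max(st["sigma_proj"], 1e-8)), logf_sp, rng, w=0.3))

        devs = st["eta"][md.y_mask]
        ss, n = float(np.sum(devs**2)), devs.size
        st["sigma_obs"] = math.exp(_slice_sample(
            math.log(max(st["sigma_obs"], 1e-8)),
            lambda t: (-n * t - ss / (2 * math.exp(2 * t))
                       - 0.5 * (math.exp(t) / pr.sigma_obs_scale) ** 2 + t),
            rng, w=0.3))

    def sweep(self, st: dict, it: int, adapt: bool) -> None:
        self.update_mu(st, it, adapt)
        cache = [self.m.in_terms(st), self.m.obs_terms(st)]
        for _ in range(2):
            self.update_level(st, it, adapt, cache)
            self.update_segment(st, it, adapt, cache)
            self.update_trend(st, it, adapt, cache)
            self.update_tilt(st, it, adapt, cache)
        self.update_E(st, it, adapt)
        self.update_eta(st, it, adapt)
        for _ in range(2):
            self.update_obs_swap(st, it, adapt)
        self.update_units(st, it, adapt)
        self.update_canid_ridge(st, it, adapt)
        self.update_canid_ridge_pop(st, it, adapt)
        self.update_ridge(st, it, adapt)
        self.update_scalars(st)


# --------------------------------------------------------------------------
# posterior container, fit, diagnostics
# --------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Labelled posterior samples, chain-aware.

    ``draws[name]`` has shape (chains, kept, ...); scalars are 2-D, unit
    coefficients (chains, kept, J), latent log abundance
    (chains, kept, J, T + 1) and harvest (chains, kept, J, T).
    """

    draws: dict
    unit_ids: np.ndarray
    years: np.ndarray
    config: FitConfig
    seed: int

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def stacked(self, name: str) -> np.ndarray:
        """Chains concatenated: shape (chains * kept, ...)."""
        a = self.draws[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def scalar_summary(self) -> pd.DataFrame:
        rows = []
        for name in SCALAR_PARAMS:
            x = self.stacked(name)
            rows.append({"parameter": name, "mean": x.mean(),
                         "median": np.median(x), "sd": x.std(ddof=1),
                         "q2.5": np.quantile(x, 0.025),
                         "q97.5": np.quantile(x, 0.975)})
        return pd.DataFrame(rows).set_index("parameter")

    def to_frame(self, include_latent: bool = False) -> pd.DataFrame:
        """Long-format draws table (chain, iteration, parameter, value)."""
        frames = []
        c_idx = np.arange(self.n_chains)
        k_idx = np.arange(self.n_kept)
        cc, kk = np.meshgrid(c_idx, k_idx, indexing="ij")
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                frames.append(pd.DataFrame({
                    "chain": cc.ravel(), "iteration": kk.ravel(),
                    "parameter": name, "value": arr.ravel()}))
            elif arr.ndim == 3:
                for j, u in enumerate(self.unit_ids):
                    frames.append(pd.DataFrame({
                        "chain": cc.ravel(), "iteration": kk.ravel(),
                        "parameter": f"{name}[{u}]", "value": arr[:, :, j].ravel()}))
            elif include_latent:
                for j, u in enumerate(self.unit_ids):
                    for t in range(arr.shape[3]):
                        yr = (self.years[t] if t < len(self.years)
                              else self.years[-1] + 1)
                        frames.append(pd.DataFrame({
                            "chain": cc.ravel(), "iteration": kk.ravel(),
                            "parameter": f"{name}[{u},{yr}]",
                            "value": arr[:, :, j, t].ravel()}))
        return pd.concat(frames, ignore_index=True)

    def save(self, path: str, include_latent: bool = True) -> None:
        """Compact columnar export (.npz) of all draw arrays."""
        import json
        arrays = {k: v for k, v in self.draws.items()
                  if include_latent or v.ndim <= 3}
        cfg = json.dumps({f: getattr(self.config, f) for f in
                          ("chains", "iterations", "burn_in", "thinning",
                           "seed", "rhat_threshold")})
        np.savez_compressed(
            path, _unit_ids=self.unit_ids, _years=self.years,
            _seed=self.seed, _config=cfg, **arrays)

    @classmethod
    def load(cls, path: str) -> "PosteriorDraws":
        import json
        with np.load(path, allow_pickle=False) as z:
            cfg = FitConfig(**json.loads(str(z["_config"])))
            draws = {k: z[k] for k in z.files if not k.startswith("_")}
            return cls(draws=draws, unit_ids=z["_unit_ids"],
                       years=z["_years"], config=cfg, seed=int(z["_seed"]))


def fit(model: Model, config: FitConfig | None = None,
        progress: bool = False) -> PosteriorDraws:
    """Sample the joint posterior; identical seeds give identical draws."""
    config = config or FitConfig()
    md = model.data
    J, T = md.J, md.T
    n_kept = config.n_kept
    draws = {name: np.empty((config.chains, n_kept)) for name in SCALAR_PARAMS}
    for name in UNIT_PARAMS:
        draws[name] = np.empty((config.chains, n_kept, J))
    draws["mu"] = np.empty((config.chains, n_kept, J, T + 1))
    draws["E"] = np.empty((config.chains, n_kept, J, T))

    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        st = model.initial_state(rng)
        lp0 = model.logp(st)
        if not np.isfinite(lp0):
            raise MooseIPMError("non-finite log posterior at the initial state")
        smp = _Sampler(model, rng)
        total = config.burn_in + config.iterations
        kept = 0
        for it in range(total):
            smp.sweep(st, it, adapt=it < config.burn_in)
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                if kept < n_kept:
                    for name in SCALAR_PARAMS:
                        draws[name][c, kept] = st[name]
                    for name in UNIT_PARAMS:
                        draws[name][c, kept] = st[name]
                    draws["mu"][c, kept] = st["mu"]
                    draws["E"][c, kept] = st["E"]
                    kept += 1
            if progress and (it + 1) % max(total // 10, 1) == 0:
                logger.info("chain %d: %d/%d sweeps", c + 1, it + 1, total)
        logger.info("chain %d finished (%d kept draws)", c + 1, kept)
    return PosteriorDraws(draws=draws, unit_ids=md.unit_ids, years=md.years,
                          config=config, seed=config.seed)


def split_rhat(x: np.ndarray) -> float:
    """Split Gelman-Rubin diagnostic for one parameter, (chains, draws)."""
    x = np.asarray(x, float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise InvalidParameterError("expected a (chains, draws) array")
    n_half = x.shape[1] // 2
    if x.shape[0] * 2 < 2 or n_half < 2:
        raise InsufficientChainsError("need >= 2 split chains of >= 2 draws")
    halves = np.concatenate([x[:, :n_half], x[:, n_half: 2 * n_half]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    w = float(np.mean(np.var(halves, axis=1, ddof=1)))
    b = n * float(np.var(chain_means, ddof=1))
    if w == 0.0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return math.sqrt(var_hat / w)


def gelman_rubin(draws: PosteriorDraws, threshold: float | None = None,
                 include_latent: bool = True) -> pd.DataFrame:
    """Split R-hat per stored parameter element, with a convergence flag."""
    if draws.n_chains < 2:
        raise InsufficientChainsError("Gelman-Rubin needs >= 2 chains")
    if draws.n_kept < 10:
        raise InsufficientChainsError("Gelman-Rubin needs >= 10 draws per chain")
    threshold = threshold if threshold is not None else draws.config.rhat_threshold
    rows = []
    for name, arr in draws.draws.items():
        if arr.ndim == 2:
            rows.append((name, split_rhat(arr)))
        elif arr.ndim == 3:
            for j, u in enumerate(draws.unit_ids):
                rows.append((f"{name}[{u}]", split_rhat(arr[:, :, j])))
        elif include_latent:
            for j, u in enumerate(draws.unit_ids):
                for t in range(arr.shape[3]):
                    rows.append((f"{name}[{u},{t}]", split_rhat(arr[:, :, j, t])))
    out = pd.DataFrame(rows, columns=["parameter", "rhat"])
    out["converged"] = out["rhat"] < threshold
    return out
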