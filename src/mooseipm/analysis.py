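"""Post-fit summaries: growth rates, provincial totals, elasticities,
and harvest counterfactuals.

All operations consume `PosteriorDraws` and propagate uncertainty by
computing each quantity per posterior draw before summarizing with
quantile-based 95% credible intervals.  The preharvest population of fall
``t`` is the realized quantity exp(mu[t + 1]) + E[t]: next winter's
postharvest abundance plus that fall's harvest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError, MooseIPMError
from .inference import PosteriorDraws
from .model_core import CovariateVector, UnitParams

__all__ = ["preharvest_draws", "unit_growth_rate", "provincial_series",
           "elasticities", "point_elasticity", "harvest_counterfactual"]


def preharvest_draws(draws: PosteriorDraws) -> np.ndarray:
    """Realized preharvest abundance per draw: (n_draws, J, T)."""
    mu = draws.stacked("mu")
    e = draws.stacked("E")
    return np.exp(mu[:, :, 1:]) + e


def _year_index(draws: PosteriorDraws, years) -> np.ndarray:
    lookup = {int(y): t for t, y in enumerate(draws.years)}
    missing = [y for y in years if int(y) not in lookup]
    if missing:
        raise MooseIPMError(f"years {missing} not present in the fitted data "
                            f"(have {draws.years.min()}-{draws.years.max()})")
    return np.asarray([lookup[int(y)] for y in years])


def unit_growth_rate(draws: PosteriorDraws, unit: str | None = None,
                     first_years: tuple = (1999, 2000),
                     last_years: tuple = (2017, 2018),
                     annualize: bool = False) -> pd.DataFrame:
    """Total growth ratio lambda over the study period, per unit.

    Per draw, lambda = (sum of preharvest abundance over `last_years`) /
    (sum over `first_years`); the unit is flagged significant when the 95%
    credible interval excludes 1.  A provincial row aggregates across
    units.  With `annualize`, lambda^(1/span) is reported alongside.
    """
    pre = preharvest_draws(draws)
    fi = _year_index(draws, first_years)
    li = _year_index(draws, last_years)
    span = (max(last_years) - min(first_years))
    num = pre[:, :, li].sum(axis=2)
    den = pre[:, :, fi].sum(axis=2)
    lam = num / den      # (n_draws, J)
    lam_prov = num.sum(axis=1) / den.sum(axis=1)

    def _row(name, x):
        lo, hi = np.quantile(x, [0.025, 0.975])
        row = {"unit_id": name, "lambda_mean": float(np.mean(x)),
               "lambda_q2.5": float(lo), "lambda_q97.5": float(hi),
               "significant": bool(hi < 1.0 or lo > 1.0)}
        if annualize:
            row["lambda_annual"] = float(np.mean(x ** (1.0 / span)))
        return row

    rows = [_row(u, lam[:, j]) for j, u in enumerate(draws.unit_ids)]
    if unit is not None:
        if unit not in set(draws.unit_ids):
            raise MooseIPMError(f"unknown unit {unit!r}")
        rows = [r for r in rows if r["unit_id"] == unit]
    else:
        rows.append(_row("provincial", lam_prov))
    return pd.DataFrame(rows).set_index("unit_id")


def provincial_series(draws: PosteriorDraws) -> pd.DataFrame:
    """Yearly provincial preharvest totals and harvest proportions.

    Sums preharvest abundance across units per draw and year; the harvest
    proportion is total harvest / total preharvest.  Quantile-based 95%
    bands accompany the posterior means.
    """
    pre = preharvest_draws(draws)
    e = draws.stacked("E")
    tot = pre.sum(axis=1)              # (n_draws, T)
    prop = e.sum(axis=1) / tot
    q = lambda x, p: np.quantile(x, p, axis=0)
    return pd.DataFrame({
        "year": draws.years,
        "preharvest_mean": tot.mean(axis=0),
        "preharvest_q2.5": q(tot, 0.025),
        "preharvest_q97.5": q(tot, 0.975),
        "harvest_prop_mean": prop.mean(axis=0),
        "harvest_prop_q2.5": q(prop, 0.025),
        "harvest_prop_q97.5": q(prop, 0.975),
    }).set_index("year")


# --------------------------------------------------------------------------
# elasticities of equilibrium abundance
# --------------------------------------------------------------------------

_ELASTICITY_PARAMS = ("r_max", "b", "beta_canids", "beta_cN", "harvest",
                      "beta_deer", "beta_bears")


def _equilibrium_mu(r, b, bc, bcN, bd, bb, x: CovariateVector, h):
    """Vectorized closed-form equilibrium log abundance; NaN if unstable."""
    b_eff = b + bcN * x.canid_rate
    numer = (r + (bc + bb * x.bear_density) * x.canid_rate
             + bd * x.deer_rate + np.log1p(-h))
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = np.where(b_eff < 0, -numer / np.where(b_eff < 0, b_eff, -1.0),
                      np.nan)
    return mu


def point_elasticity(params: UnitParams, x_bar: CovariateVector, h: float,
                     which: str, delta: float) -> float:
    """Finite-difference elasticity of equilibrium abundance for one
    parameter at a point: e = [(N*(theta(1+delta)) - N*)/N*] / delta."""
    base = dict(r_max=params.r_max, b=params.b, bc=params.beta_canids,
                bcN=params.beta_cN, bd=params.beta_deer, bb=params.beta_bears,
                h=h)
    key = {"r_max": "r_max", "b": "b", "beta_canids": "bc", "beta_cN": "bcN",
           "beta_deer": "bd", "beta_bears": "bb", "harvest": "h"}[which]
    mu0 = _equilibrium_mu(base["r_max"], base["b"], base["bc"], base["bcN"],
                          base["bd"], base["bb"], x_bar, base["h"])
    pert = dict(base)
    pert[key] = base[key] * (1.0 + delta)
    mu1 = _equilibrium_mu(pert["r_max"], pert["b"], pert["bc"], pert["bcN"],
                          pert["bd"], pert["bb"], x_bar, pert["h"])
    if np.isnan(mu0) or np.isnan(mu1):
        return float("nan")
    return float((math.exp(mu1 - mu0) - 1.0) / delta)


def harvest_rate_levels(draws: PosteriorDraws) -> dict:
    """Mean / 2.5th / 97.5th percentile of unit-year harvest proportions.

    Percentiles are taken across the posterior-mean harvest proportions of
    all unit-years, mirroring low- and high-harvest conditions actually
    realized in the data.
    """
    pre = preharvest_draws(draws)
    e = draws.stacked("E")
    hp = (e / pre).mean(axis=0)        # (J, T) posterior means
    return {"mean": float(hp.mean()),
            "low": float(np.quantile(hp, 0.025)),
            "high": float(np.quantile(hp, 0.975))}


def elasticities(draws: PosteriorDraws,
                 deltas: tuple = (0.01, 0.05, 0.10),
                 harvest_levels: dict | None = None,
                 x_bar: CovariateVector | None = None) -> pd.DataFrame:
    """Elasticity of equilibrium abundance per population-level parameter.

    Per posterior draw and for each proportional perturbation delta, the
    equilibrium is recomputed with the parameter moved to theta(1+delta)
    and the relative abundance change divided by delta.  Rows carry
    posterior means and 95% intervals per parameter, harvest level
    (mean / low 2.5% / high 97.5%) and delta; draws without a stable
    equilibrium are excluded and counted in `n_unstable`.
    """
    x_bar = x_bar or CovariateVector()
    if harvest_levels is None:
        harvest_levels = harvest_rate_levels(draws)
    base = {
        "r_max": draws.stacked("r_max"), "b": draws.stacked("mu_b"),
        "bc": draws.stacked("mu_beta_canids"), "bcN": draws.stacked("mu_beta_cN"),
        "bd": draws.stacked("mu_beta_deer"), "bb": draws.stacked("beta_bears"),
    }
    key_of = {"r_max": "r_max", "b": "b", "beta_canids": "bc",
              "beta_cN": "bcN", "beta_deer": "bd", "beta_bears": "bb",
              "harvest": "h"}
    rows = []
    for level_name, h in harvest_levels.items():
        args0 = dict(base, h=np.full_like(base["r_max"], h))
        mu0 = _equilibrium_mu(args0["r_max"], args0["b"], args0["bc"],
                              args0["bcN"], args0["bd"], args0["bb"],
                              x_bar, args0["h"])
        for which in _ELASTICITY_PARAMS:
            key = key_of[which]
            for delta in deltas:
                args1 = dict(args0)
                args1[key] = args0[key] * (1.0 + delta)
                mu1 = _equilibrium_mu(args1["r_max"], args1["b"], args1["bc"],
                                      args1["bcN"], args1["bd"], args1["bb"],
                                      x_bar, args1["h"])
                e = (np.exp(mu1 - mu0) - 1.0) / delta
                ok = np.isfinite(e)
                if ok.sum() == 0:
                    rows.append({"parameter": which, "harvest_level": level_name,
                                 "delta": delta, "mean": np.nan, "q2.5": np.nan,
                                 "q97.5": np.nan, "n_unstable": int((~ok).sum()),
                                 "significant": False})
                    continue
                ev = e[ok]
                lo, hi = np.quantile(ev, [0.025, 0.975])
                rows.append({"parameter": which, "harvest_level": level_name,
                             "delta": delta, "mean": float(ev.mean()),
                             "q2.5": float(lo), "q97.5": float(hi),
                             "n_unstable": int((~ok).sum()),
                             "significant": bool(hi < 0.0 or lo > 0.0)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# harvest counterfactuals
# --------------------------------------------------------------------------

@dataclass
class CounterfactualResult:
    """Projection bands for baseline and modified harvest schedules."""

    bands: pd.DataFrame          # per year x scenario: median, IQR, 95%
    final_ratio: pd.DataFrame    # per scenario: final/initial abundance


def harvest_counterfactual(draws: PosteriorDraws, schedule_modifier,
                           horizon: int | None = None,
                           baseline_schedule: np.ndarray | None = None,
                           mu_init: float | None = None,
                           x_bar: CovariateVector | None = None) -> CounterfactualResult:
    """Project an average unit under baseline vs modified harvest.

    Per posterior draw, population-level parameters drive a deterministic
    Gompertz projection from the posterior-median initial log abundance of
    an average unit; the modified scenario multiplies each year's
    proportional harvest by ``schedule_modifier`` (an array of per-year
    multipliers or a callable year_index -> multiplier).  Returned bands
    are the median, interquartile and 95% quantiles of abundance per year,
    plus the distribution of final/initial abundance ratios.
    """
    x_bar = x_bar or CovariateVector()
    if baseline_schedule is None:
        pre = preharvest_draws(draws)
        e = draws.stacked("E")
        baseline_schedule = (e.sum(axis=1) / pre.sum(axis=1)).mean(axis=0)
    baseline_schedule = np.asarray(baseline_schedule, float)
    if horizon is None:
        horizon = baseline_schedule.size
    if horizon < 1:
        raise InvalidParameterError("horizon must be >= 1")
    h_base = np.resize(baseline_schedule, horizon)
    if callable(schedule_modifier):
        mult = np.asarray([schedule_modifier(t) for t in range(horizon)], float)
    else:
        mult = np.resize(np.asarray(schedule_modifier, float), horizon)
    h_mod = np.clip(h_base * mult, 0.0, 0.999)

    if mu_init is None:
        mu_init = float(np.median(draws.stacked("mu")[:, :, 0]))
    r = draws.stacked("r_max")
    b = draws.stacked("mu_b")
    bc = draws.stacked("mu_beta_canids")
    bcN = draws.stacked("mu_beta_cN")
    bd = draws.stacked("mu_beta_deer")
    bb = draws.stacked("beta_bears")
    bpred = bc + bb * x_bar.bear_density

    def _project(h_sched):
        mu = np.full_like(r, mu_init)
        path = np.empty((r.size, horizon + 1))
        path[:, 0] = np.exp(mu)
        for t in range(horizon):
            incr = (r + b * mu + bpred * x_bar.canid_rate
                    + bcN * x_bar.canid_rate * mu + bd * x_bar.deer_rate)
            # cap the log state: draws with runaway growth (no stable
            # equilibrium) would otherwise overflow the projection
            log_post = np.clip(mu + incr + np.log1p(-h_sched[t]), -14.0, 28.0)
            post = np.exp(log_post)
            mu = log_post
            path[:, t + 1] = post
        return path

    out = []
    ratios = []
    for name, sched in (("baseline", h_base), ("modified", h_mod)):
        path = _project(sched)
        qs = np.quantile(path, [0.025, 0.25, 0.5, 0.75, 0.975], axis=0)
        out.append(pd.DataFrame({
            "scenario": name, "step": np.arange(horizon + 1),
            "q2.5": qs[0], "q25": qs[1], "median": qs[2],
            "q75": qs[3], "q97.5": qs[4]}))
        rt = path[:, -1] / path[:, 0]
        lo, q25, med, q75, hi = np.quantile(rt, [0.025, 0.25, 0.5, 0.75, 0.975])
        ratios.append({"scenario": name, "median": float(med),
                       "q25": float(q25), "q75": float(q75),
                       "q2.5": float(lo), "q97.5": float(hi)})
    return CounterfactualResult(bands=pd.concat(out, ignore_index=True),
                                final_ratio=pd.DataFrame(ratios).set_index("scenario"))
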