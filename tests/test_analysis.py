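"""Growth-rate summaries, provincial totals, elasticities, counterfactuals."""

import math

import numpy as np
import pytest

from mooseipm.analysis import (
    elasticities,
    harvest_counterfactual,
    harvest_rate_levels,
    point_elasticity,
    provincial_series,
    unit_growth_rate,
)
from mooseipm.exceptions import MooseIPMError
from mooseipm.inference import FitConfig, PosteriorDraws, SCALAR_PARAMS
from mooseipm.model_core import CovariateVector, UnitParams


def make_draws(mu, e, rng=None, **scalars):
    """Hand-built PosteriorDraws: mu (C, K, J, T+1), e (C, K, J, T)."""
    mu = np.asarray(mu, float)
    e = np.asarray(e, float)
    c, k, j, t1 = mu.shape
    years = 1999 + np.arange(t1 - 1)
    rng = rng or np.random.default_rng(0)
    draws = {"mu": mu, "E": e}
    defaults = dict(r_max=0.487, mu_b=-0.058, mu_beta_canids=-0.195,
                    mu_beta_cN=0.023, mu_beta_deer=-0.022, beta_bears=-0.013)
    for name in SCALAR_PARAMS:
        base = scalars.get(name, defaults.get(name, 0.1))
        draws[name] = base + 0.0 * rng.standard_normal((c, k))
    for name in ("b", "beta_canids", "beta_cN", "beta_deer", "alpha",
                 "theta_days", "theta_snow"):
        draws[name] = np.zeros((c, k, j))
    return PosteriorDraws(draws=draws, unit_ids=np.array(
        [f"U{i}" for i in range(j)]), years=years,
        config=FitConfig(chains=c, iterations=k, burn_in=0, thinning=1),
        seed=0)


def constant_draws(n_units=2, level=1000.0, harvest=50.0, n_years=20,
                   c=2, k=50):
    mu = np.full((c, k, n_units, n_years + 1), math.log(level))
    e = np.full((c, k, n_units, n_years), harvest)
    return make_draws(mu, e)


class TestUnitGrowthRate:
    def test_constant_abundance_is_lambda_one(self):
        out = unit_growth_rate(constant_draws())
        assert np.allclose(out["lambda_mean"], 1.0)
        assert not out["significant"].any()

    def test_twenty_percent_decline(self):
        # (N_2017 + N_2018) / (N_1999 + N_2000) = 160/200 = 0.8 in every draw
        draws = constant_draws(n_units=1)
        pre = np.exp(draws.draws["mu"][:, :, :, 1:]) + draws.draws["E"]
        target = np.log(np.array([100.0, 100.0]) - 50.0)
        draws.draws["mu"][:, :, :, 1:3] = target[0] * 0 + math.log(100.0 - 50.0)
        draws.draws["E"][:, :, :, :2] = 50.0
        draws.draws["mu"][:, :, :, 19:21] = math.log(80.0 - 40.0)
        draws.draws["E"][:, :, :, 18:20] = 40.0
        out = unit_growth_rate(draws)
        assert out.loc["U0", "lambda_mean"] == pytest.approx(0.8)
        assert out.loc["U0", "significant"]

    def test_quantiles_invariant_to_draw_order(self):
        rng = np.random.default_rng(3)
        mu = rng.normal(7.0, 0.3, (2, 200, 2, 21))
        e = rng.uniform(10, 60, (2, 200, 2, 20))
        draws = make_draws(mu, e)
        out1 = unit_growth_rate(draws)
        perm = rng.permutation(200)
        draws2 = make_draws(mu[:, perm], e[:, perm])
        out2 = unit_growth_rate(draws2)
        assert np.allclose(out1["lambda_q2.5"], out2["lambda_q2.5"])
        assert np.allclose(out1["lambda_q97.5"], out2["lambda_q97.5"])

    def test_missing_years_named(self):
        with pytest.raises(MooseIPMError, match="2050"):
            unit_growth_rate(constant_draws(), last_years=(2050, 2051))


class TestProvincialSeries:
    def test_single_unit_equals_unit_series(self):
        draws = constant_draws(n_units=1, level=900.0, harvest=63.0)
        out = provincial_series(draws)
        assert np.allclose(out["preharvest_mean"], 963.0)
        assert np.allclose(out["harvest_prop_mean"], 63.0 / 963.0)

    def test_invariant_to_unit_ordering(self):
        rng = np.random.default_rng(4)
        mu = rng.normal(7.0, 0.3, (2, 100, 3, 11))
        e = rng.uniform(10, 60, (2, 100, 3, 10))
        a = provincial_series(make_draws(mu, e))
        b = provincial_series(make_draws(mu[:, :, ::-1], e[:, :, ::-1]))
        assert np.allclose(a["preharvest_mean"], b["preharvest_mean"])


class TestElasticities:
    P = UnitParams(r_max=0.487, b=-0.058)
    X0 = CovariateVector()

    def test_inert_parameter_is_zero(self):
        # beta_deer cannot move the equilibrium when the deer covariate is 0
        assert point_elasticity(self.P, self.X0, 0.05, "beta_deer",
                                0.05) == pytest.approx(0.0)

    def test_r_max_elasticity_converges_to_closed_form(self):
        # d log N* / d log r_max = -r_max / b = 8.397 at the posterior means
        analytic = 0.487 / 0.058
        e_small = point_elasticity(self.P, self.X0, 0.0, "r_max", 1e-7)
        assert e_small == pytest.approx(analytic, rel=1e-5)
        # Taylor remainder: |e(delta) - analytic| <= a^2 delta/2 * exp(a delta)
        for delta in (0.01, 0.05, 0.10):
            e_d = point_elasticity(self.P, self.X0, 0.0, "r_max", delta)
            bound = analytic**2 * delta / 2 * math.exp(analytic * delta)
            assert abs(e_d - analytic) <= bound

    def test_sign_pattern_and_harvest_ordering(self):
        draws = constant_draws()
        levels = {"mean": 0.074, "low": 0.035, "high": 0.113}
        table = elasticities(draws, harvest_levels=levels)
        t = table[table["delta"] == 0.01].set_index(["parameter",
                                                     "harvest_level"])
        assert t.loc[("r_max", "mean"), "mean"] > 0
        assert t.loc[("harvest", "mean"), "mean"] < 0
        assert t.loc[("beta_deer", "mean"), "mean"] == pytest.approx(0.0)
        # harvest elasticity magnitude grows with the harvest level
        assert (abs(t.loc[("harvest", "high"), "mean"])
                > abs(t.loc[("harvest", "mean"), "mean"])
                > abs(t.loc[("harvest", "low"), "mean"]))

    def test_unstable_draws_flagged(self):
        draws = constant_draws()
        draws.draws["mu_b"][:] = 0.05          # positive density dependence
        table = elasticities(draws, harvest_levels={"mean": 0.05})
        assert (table["n_unstable"] > 0).all()

    def test_harvest_rate_levels_from_draws(self):
        draws = constant_draws(level=950.0, harvest=50.0)
        levels = harvest_rate_levels(draws)
        assert levels["mean"] == pytest.approx(50.0 / 1000.0)


class TestHarvestCounterfactual:
    def test_identity_modifier_reproduces_baseline(self):
        draws = constant_draws()
        res = harvest_counterfactual(draws, np.ones(20))
        b = res.bands[res.bands["scenario"] == "baseline"]["median"].to_numpy()
        m = res.bands[res.bands["scenario"] == "modified"]["median"].to_numpy()
        assert np.allclose(b, m)

    def test_no_harvest_dominates_baseline(self):
        rng = np.random.default_rng(5)
        mu = rng.normal(7.0, 0.2, (2, 100, 2, 21))
        e = rng.uniform(30, 80, (2, 100, 2, 20))
        draws = make_draws(mu, e)
        res = harvest_counterfactual(draws, np.zeros(20))
        b = res.bands[res.bands["scenario"] == "baseline"]
        m = res.bands[res.bands["scenario"] == "modified"]
        assert (m["median"].to_numpy() >= b["median"].to_numpy() - 1e-9).all()
        assert res.final_ratio.loc["modified", "median"] >= \
            res.final_ratio.loc["baseline", "median"]

    def test_early_harvest_reduction_moves_ratio_toward_one(self):
        # schedule above the sustainable rate early on: a 35% early-period
        # reduction must raise the final/initial ratio
        draws = constant_draws(level=1200.0)
        sched = np.array([0.10] * 8 + [0.06] * 12)
        mult = np.array([0.65] * 8 + [1.0] * 12)
        res = harvest_counterfactual(draws, mult, baseline_schedule=sched,
                                     mu_init=math.log(1200.0))
        assert (res.final_ratio.loc["modified", "median"]
                > res.final_ratio.loc["baseline", "median"])
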