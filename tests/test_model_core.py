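"""Growth map, predator coefficient, equilibrium and projection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mooseipm.exceptions import (
    DegenerateStateError,
    InvalidHarvestError,
    InvalidParameterError,
    NoStableEquilibriumError,
)
from mooseipm.model_core import (
    CovariateVector,
    HarvestRule,
    UnitParams,
    equilibrium_abundance,
    equilibrium_log_abundance,
    growth_step,
    log_growth_increment,
    predator_coefficient,
    project_trajectory,
)

X0 = CovariateVector()


class TestPredatorCoefficient:
    @pytest.mark.parametrize("bc, bb, dens, expected", [
        (-0.195, -0.013, 0.0, -0.195),   # zero bear density leaves canid effect
        (-0.195, -0.013, 1.0, -0.208),
        (0.0, 0.0, 5.0, 0.0),
    ])
    def test_values(self, bc, bb, dens, expected):
        assert predator_coefficient(bc, bb, dens) == pytest.approx(expected)

    def test_linear_in_bear_density(self):
        # unit increments of bear density change the coefficient by beta_bears
        vals = [predator_coefficient(-0.2, -0.013, d) for d in range(5)]
        diffs = np.diff(vals)
        assert np.allclose(diffs, -0.013)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidParameterError):
            predator_coefficient(float("nan"), 0.0, 0.0)


class TestGrowthStep:
    def test_fixed_point_at_equilibrium(self):
        # mu* = -r_max/b: abundance is reproduced (posterior-mean parameters)
        p = UnitParams(r_max=0.487, b=-0.058)
        mu_star = 0.487 / 0.058
        out = growth_step(mu_star, p, X0, harvest=0.0)
        assert out == pytest.approx(math.exp(mu_star), rel=1e-6)

    def test_growth_from_minimal_abundance(self):
        # at N = 1 (mu = 0) the population grows at exp(r_max) by definition
        p = UnitParams(r_max=0.3, b=0.0)
        assert growth_step(0.0, p, X0, 0.0) == pytest.approx(1.3499, abs=1e-4)

    def test_hand_arithmetic_with_harvest(self):
        # exp(5 + 0.4 - 0.25) - 60 = 112.434 (hand-computed)
        p = UnitParams(r_max=0.4, b=-0.05)
        assert growth_step(5.0, p, X0, 60.0) == pytest.approx(112.434, abs=1e-2)

    def test_overharvest_raises(self):
        p = UnitParams(r_max=0.3, b=-0.05)
        with pytest.raises(DegenerateStateError):
            growth_step(2.0, p, X0, harvest=1e6)

    def test_sign_of_change_matches_density_dependence(self):
        # growth below mu*, decline above, for random states
        rng = np.random.default_rng(42)
        p = UnitParams(r_max=0.487, b=-0.058)
        for mu in rng.uniform(1.0, 12.0, 25):
            post = growth_step(mu, p, X0, 0.0)
            drift = p.r_max + p.b * mu
            assert np.sign(math.log(post) - mu) == np.sign(drift)


def _iterate_equilibrium(p: UnitParams, x: CovariateVector, h: float,
                         n_steps: int = 500) -> float:
    """Independent oracle: fixed-point iteration of the log-scale map."""
    beta_pred = p.beta_canids + p.beta_bears * x.bear_density
    mu = 5.0
    for _ in range(n_steps):
        mu = (mu + p.r_max + p.b * mu + beta_pred * x.canid_rate
              + p.beta_cN * x.canid_rate * mu + p.beta_deer * x.deer_rate
              + math.log1p(-h))
    return math.exp(mu)


class TestEquilibrium:
    def test_table_parameter_means(self):
        p = UnitParams(r_max=0.487, b=-0.058)
        assert equilibrium_abundance(p, X0) == pytest.approx(
            math.exp(0.487 / 0.058), rel=1e-10)

    def test_unit_equilibrium(self):
        p = UnitParams(r_max=0.3, b=-0.3)
        assert equilibrium_abundance(p, X0) == pytest.approx(math.e, rel=1e-12)

    def test_closed_form_matches_iteration_oracle(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            p = UnitParams(
                r_max=rng.uniform(0.1, 0.6), b=rng.uniform(-0.5, -0.05),
                beta_canids=rng.uniform(-0.3, 0.1),
                beta_cN=rng.uniform(-0.02, 0.02),
                beta_deer=rng.uniform(-0.05, 0.05),
                beta_bears=rng.uniform(-0.05, 0.0))
            x = CovariateVector(canid_rate=rng.uniform(-1, 1),
                                deer_rate=rng.uniform(-1, 1),
                                bear_density=rng.uniform(-1, 1))
            if p.b + p.beta_cN * x.canid_rate >= -1e-3:
                continue
            h = rng.uniform(0.0, 0.2)
            closed = equilibrium_abundance(p, x, h)
            iterated = _iterate_equilibrium(p, x, h)
            assert closed == pytest.approx(iterated, rel=1e-8)
            checked += 1

    def test_continuity_in_harvest(self):
        p = UnitParams(r_max=0.487, b=-0.058)
        assert equilibrium_abundance(p, X0, 1e-9) == pytest.approx(
            equilibrium_abundance(p, X0, 0.0), rel=1e-6)

    def test_monotone_decreasing_in_harvest(self):
        p = UnitParams(r_max=0.487, b=-0.058)
        ns = [equilibrium_abundance(p, X0, h) for h in (0.0, 0.05, 0.1, 0.2)]
        assert all(a > b for a, b in zip(ns, ns[1:]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        r_max=st.floats(0.05, 0.8),
        b=st.floats(-0.8, -0.02),
        h1=st.floats(0.0, 0.4),
        h2=st.floats(0.0, 0.4),
    )
    def test_harvest_strictly_lowers_equilibrium(self, r_max, b, h1, h2):
        if abs(h1 - h2) < 1e-9:
            return
        lo, hi = sorted((h1, h2))
        p = UnitParams(r_max=r_max, b=b)
        assert equilibrium_abundance(p, X0, hi) < equilibrium_abundance(p, X0, lo)

    def test_unstable_and_invalid_inputs(self):
        with pytest.raises(NoStableEquilibriumError):
            equilibrium_log_abundance(UnitParams(r_max=0.3, b=0.05), X0)
        with pytest.raises(InvalidHarvestError):
            equilibrium_log_abundance(UnitParams(r_max=0.3, b=-0.1), X0, h=1.0)


class TestProjection:
    P = UnitParams(r_max=0.487, b=-0.058, sigma_proj=0.1)

    def test_constant_at_equilibrium(self):
        mu_star = equilibrium_log_abundance(self.P, X0, 0.05)
        tr = project_trajectory(self.P, mu_star, 0.05, X0, 10)
        assert np.allclose(tr.mu, mu_star, atol=1e-10)

    def test_monotone_convergence_from_below(self):
        tr = project_trajectory(self.P, 5.0, 0.0, X0, 400)
        assert np.all(np.diff(tr.mu) > 0)
        assert tr.postharvest[-1] == pytest.approx(math.exp(0.487 / 0.058),
                                                   rel=1e-6)

    def test_decline_above_sustainable_rate(self):
        mu0 = 7.0
        h_sust = 1.0 - math.exp(-(0.487 - 0.058 * mu0))
        tr = project_trajectory(self.P, mu0, h_sust + 0.05, X0, 15)
        assert np.all(np.diff(tr.mu[~np.isnan(tr.mu)]) < 0)

    def test_extinction_flagged_and_truncated(self):
        tr = project_trajectory(self.P, 5.0, HarvestRule.absolute(500.0),
                                X0, 10)
        assert tr.extinct and tr.extinction_year is not None
        assert np.isnan(tr.mu[tr.extinction_year + 1])

    def test_noise_reproducible_by_seed(self):
        a = project_trajectory(self.P, 7.0, 0.05, X0, 20,
                               process_noise=True, seed=11)
        b = project_trajectory(self.P, 7.0, 0.05, X0, 20,
                               process_noise=True, seed=11)
        c = project_trajectory(self.P, 7.0, 0.05, X0, 20,
                               process_noise=True, seed=12)
        assert np.array_equal(a.mu, b.mu)
        assert not np.array_equal(a.mu, c.mu)

    def test_noise_off_is_deterministic(self):
        a = project_trajectory(self.P, 7.0, 0.05, X0, 20, seed=1)
        b = project_trajectory(self.P, 7.0, 0.05, X0, 20, seed=999)
        assert np.array_equal(a.mu, b.mu)
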