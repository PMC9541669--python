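"""Model assembly, sampler correctness on reduced posteriors, diagnostics."""

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from mooseipm import synthetic_data as sd
from mooseipm.exceptions import InsufficientChainsError
from mooseipm.inference import (
    FitConfig,
    PosteriorDraws,
    PriorConfig,
    build_model,
    fit,
    gelman_rubin,
    split_rhat,
)


@pytest.fixture(scope="module")
def small_dataset():
    design = replace(sd.SyntheticDesign(), n_units=6, n_years=10)
    return sd.generate(design, seed=5)


@pytest.fixture(scope="module")
def small_model(small_dataset):
    return build_model(small_dataset.observations)


class TestBuildModel:
    def test_finite_logp_at_initial_state(self, small_model):
        st = small_model.initial_state(np.random.default_rng(1))
        assert np.isfinite(small_model.logp(st))

    def test_large_latent_perturbation_lowers_posterior(self, small_model):
        st = small_model.initial_state(np.random.default_rng(1))
        base = small_model.logp(st)
        st2 = {k: (v.copy() if isinstance(v, np.ndarray) else v)
               for k, v in st.items()}
        st2["mu"][0, 3] += 10.0
        assert small_model.logp(st2) < base

    def test_layers_factorize(self, small_model):
        # observation terms do not depend on process coefficients and
        # process terms do not depend on detection parameters
        st = small_model.initial_state(np.random.default_rng(2))
        obs0 = small_model.obs_terms(st)
        proc0 = small_model.process_terms(st)
        st_b = dict(st, b=st["b"] - 0.03)
        assert np.array_equal(small_model.obs_terms(st_b), obs0)
        st_a = dict(st, alpha=st["alpha"] + 0.5)
        assert np.array_equal(small_model.process_terms(st_a), proc0)

    def test_sparse_units_excluded_with_warning(self, small_dataset, caplog):
        obs = small_dataset.observations.copy()
        first_unit = obs["unit_id"].iloc[0]
        mask = obs["unit_id"] == first_unit
        first_year = obs["year"].min()
        obs.loc[mask & (obs["year"] > first_year), "survey_conducted"] = 0
        with caplog.at_level(logging.WARNING, logger="mooseipm"):
            model = build_model(obs)
        assert first_unit in model.data.excluded_units
        assert first_unit not in set(model.data.unit_ids)
        assert "excluding" in caplog.text


class TestSplitRhat:
    @staticmethod
    def _textbook_rhat(chains):
        """Independent formula: split chains, between/within variance ratio."""
        n = chains.shape[1] // 2
        halves = [c[i * n:(i + 1) * n] for c in chains for i in (0, 1)]
        m = len(halves)
        means = [h.mean() for h in halves]
        w = np.mean([h.var(ddof=1) for h in halves])
        grand = np.mean(means)
        b = n / (m - 1) * sum((mu - grand) ** 2 for mu in means)
        return np.sqrt(((n - 1) / n * w + b / n) / w)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = rng.normal(size=(3, 400)) + rng.uniform(0, 2)
            assert split_rhat(x) == pytest.approx(self._textbook_rhat(x),
                                                  abs=1e-10)

    def test_matches_arviz_oracle(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(1)
        x = rng.normal(size=(4, 300))
        ref = float(az.rhat(az.convert_to_dataset(x),
                            method="split")["x"].item())
        assert split_rhat(x) == pytest.approx(ref, abs=1e-10)

    def test_well_mixed_chains(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(2, 10_000))
        assert split_rhat(x) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 1000))
        x[1] += 10.0
        assert split_rhat(x) > 2.0


class TestFit:
    CFG = FitConfig(chains=2, iterations=400, burn_in=300, thinning=4, seed=7)

    def test_seed_reproducibility_bitwise(self, small_model):
        a = fit(small_model, self.CFG)
        b = fit(small_model, self.CFG)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])

    def test_longer_run_reproduces_first_half(self, small_model):
        short = fit(small_model, self.CFG)
        long = fit(small_model, replace(self.CFG, iterations=800))
        half = short.n_kept
        for name in ("r_max", "mu_b", "sigma_proj"):
            assert np.array_equal(long.draws[name][:, :half],
                                  short.draws[name])

    def test_save_load_roundtrip(self, small_model, tmp_path):
        draws = fit(small_model, self.CFG)
        path = tmp_path / "draws.npz"
        draws.save(str(path))
        loaded = PosteriorDraws.load(str(path))
        assert np.array_equal(loaded.draws["mu"], draws.draws["mu"])
        assert loaded.config.seed == self.CFG.seed
        assert list(loaded.unit_ids) == list(draws.unit_ids)

    def test_gelman_rubin_requires_chains_and_draws(self, small_model):
        draws = fit(small_model, replace(self.CFG, chains=1))
        with pytest.raises(InsufficientChainsError):
            gelman_rubin(draws)


class TestReducedPosteriors:
    def test_fully_surveyed_unit_recovers_survey_normals(self):
        """With every winter surveyed and no hunter data, each interior
        latent state's posterior is exactly the survey normal
        N(log N_hat, (se/N_hat)^2); checks the MH machinery against a
        closed-form posterior."""
        rng = np.random.default_rng(11)
        years = np.arange(1999, 2007)
        n_hat = rng.uniform(800, 1200, years.size)
        se = 0.15 * n_hat
        obs = pd.DataFrame({
            "unit_id": "U1", "year": years, "area_km2": 9000.0,
            "aerial_estimate": n_hat, "aerial_se": se, "survey_conducted": 1,
            "hunter_moose_seen": np.nan, "days_hunted": np.nan,
            "canids_per_day": rng.uniform(0, 0.1, years.size),
            "deer_per_day": rng.uniform(0, 0.5, years.size),
            "snow_index": rng.uniform(100, 300, years.size),
            "bear_density": 20.0,
        })
        for cls, tags in (("bull", 40), ("cow", 25), ("calf", 10)):
            obs[f"tags_issued_{cls}"] = tags
            obs[f"reported_harvest_{cls}"] = tags // 3
            obs[f"respondents_{cls}"] = tags       # full reporting
            obs[f"reported_success_{cls}"] = 1 / 3
        model = build_model(obs)
        cfg = FitConfig(chains=2, iterations=3000, burn_in=1000,
                        thinning=3, seed=13)
        draws = fit(model, cfg)
        mu = draws.stacked("mu")[:, 0, :]          # (n_draws, T+1)
        for t in range(1, years.size - 1):
            target_mean = np.log(n_hat[t])
            target_sd = se[t] / n_hat[t]
            n_eff_floor = 50  # conservative for autocorrelated draws
            mc_se = target_sd / np.sqrt(n_eff_floor)
            assert mu[:, t].mean() == pytest.approx(target_mean,
                                                    abs=4 * mc_se)
            assert mu[:, t].std() == pytest.approx(target_sd, rel=0.25)

    def test_data_free_parameter_recovers_prior(self):
        """beta_bears is prior-only when bear density is constant across
        units (the standardized covariate is zero): its posterior must
        reproduce the vague Normal(0, 10) prior."""
        design = replace(sd.SyntheticDesign(), n_units=4, n_years=8)
        ds = sd.generate(design, seed=21)
        obs = ds.observations.copy()
        obs["bear_density"] = 17.5
        model = build_model(obs)
        assert np.all(model.data.bear_x == 0.0)
        cfg = FitConfig(chains=2, iterations=2000, burn_in=500,
                        thinning=2, seed=3)
        draws = fit(model, cfg)
        bb = draws.stacked("beta_bears")
        assert abs(bb.mean()) < 1.0
        assert bb.std() == pytest.approx(10.0, rel=0.15)
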