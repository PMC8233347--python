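import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import reefvuln as rv
from reefvuln.stack import CovariateStack


def _obs_from_arrays(grid, y, z=None, n=None, kind="cover"):
    n = n or len(y)
    centers = grid.sea_centers()[:n]
    return rv.ObservationSet(
        pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(n)],
                "lat": centers[:, 0],
                "lon": centers[:, 1],
                "response_kind": kind,
                "y": y,
                "z": np.full(n, np.nan) if z is None else z,
            }
        ),
        response_kind=kind,
    )


class TestOccurrence:
    def test_intercept_only_recovers_base_rate(self):
        g = rv.make_grid((0, 2, 0, 2), 0.08, {"kind": "all_sea"}, seed=0)
        y = np.tile([0, 1], 200)
        obs = _obs_from_arrays(g, y, kind="occurrence")
        spec = rv.ModelSpec("occurrence", [], include_spatial=False)
        fit = rv.fit_occurrence(
            obs, CovariateStack(grid=g), spec, rv.InferenceConfig(n_draws=800, seed=1)
        )
        pi = expit(fit.b_draws[:, 0]).mean()
        assert 0.45 <= pi <= 0.55

    def test_separation_rejected(self, allsea_grid):
        obs = _obs_from_arrays(allsea_grid, np.ones(50, dtype=int), kind="occurrence")
        with pytest.raises(ValueError, match="all 0 or all 1"):
            rv.fit_occurrence(
                obs, CovariateStack(grid=allsea_grid),
                rv.ModelSpec("occurrence", [], include_spatial=False),
            )

    def test_prior_variance_insensitivity_when_identified(self, study_grid, study_stack,
                                                          study_truth):
        obs = rv.simulate_observations(study_grid, study_stack, study_truth, 800, seed=42)
        means = {}
        for pv in (100.0, 10000.0):
            spec = rv.ModelSpec("occurrence", ["sst", "bathymetry"],
                                include_spatial=False, fixed_effect_prior_variance=pv)
            fit = rv.fit_occurrence(obs, study_stack, spec,
                                    rv.InferenceConfig(n_draws=800, seed=7))
            means[pv] = fit.params.loc["beta_sst", "mean"]
        assert abs(means[100.0] - means[10000.0]) < 0.05

    def test_parameter_recovery_single_replicate(self, occurrence_fit):
        # truth: beta_sst = 1.2 with the spatial field on
        row = occurrence_fit.params.loc["beta_sst"]
        assert abs(row["mean"] - 1.2) < 0.5
        assert row["q025"] <= 1.2 <= row["q975"]


class TestConditional:
    def test_constant_response_pins_intercept(self, allsea_grid):
        z = np.full(60, np.exp(2.0))
        obs = _obs_from_arrays(allsea_grid, np.ones(60, dtype=int), z)
        spec = rv.ModelSpec("cover", [], include_spatial=False)
        fit = rv.fit_conditional_lognormal(
            obs, CovariateStack(grid=allsea_grid), spec, rv.InferenceConfig(n_draws=500, seed=2)
        )
        assert fit.params.loc["alpha", "mean"] == pytest.approx(2.0, abs=0.01)
        assert fit.params.loc["sigma2", "mean"] < 0.01

    def test_doubling_z_shifts_only_the_intercept(self, allsea_grid):
        rng = np.random.default_rng(3)
        n = 120
        z = np.exp(rng.normal(1.0, 0.5, n))
        cov = make_cov(allsea_grid, rng)
        spec = rv.ModelSpec("cover", ["x"], include_spatial=False)
        cfg = rv.InferenceConfig(n_draws=800, seed=4)
        fit1 = rv.fit_conditional_lognormal(
            _obs_from_arrays(allsea_grid, np.ones(n, dtype=int), z), cov, spec, cfg
        )
        fit2 = rv.fit_conditional_lognormal(
            _obs_from_arrays(allsea_grid, np.ones(n, dtype=int), 2 * z), cov, spec, cfg
        )
        d_alpha = fit2.params.loc["alpha", "mean"] - fit1.params.loc["alpha", "mean"]
        assert d_alpha == pytest.approx(np.log(2), abs=0.05)
        assert fit2.params.loc["beta_x", "mean"] == pytest.approx(
            fit1.params.loc["beta_x", "mean"], abs=0.05
        )
        assert fit2.params.loc["sigma2", "mean"] == pytest.approx(
            fit1.params.loc["sigma2", "mean"], rel=0.2
        )

    def test_recovery_of_conditional_truth(self, conditional_fit):
        # truth: alpha = 1.0, beta_sst = -0.8, sigma2 = 0.25
        assert abs(conditional_fit.params.loc["alpha", "mean"] - 1.0) < 0.3
        assert abs(conditional_fit.params.loc["beta_sst", "mean"] + 0.8) < 0.3
        assert abs(conditional_fit.params.loc["sigma2", "mean"] - 0.25) < 0.3

    def test_too_few_records_rejected(self, allsea_grid):
        obs = _obs_from_arrays(allsea_grid, np.ones(5, dtype=int), np.full(5, 2.0))
        with pytest.raises(ValueError, match=">= 10"):
            rv.fit_conditional_lognormal(
                obs, CovariateStack(grid=allsea_grid),
                rv.ModelSpec("cover", [], include_spatial=False),
            )


def make_cov(grid, rng):
    x = np.full(grid.shape, np.nan)
    x[grid.mask] = rng.normal(size=grid.n_sea)
    stack = CovariateStack(grid=grid)
    stack.add("x", x)
    return stack


class TestHurdle:
    def test_unconditional_mean_closed_form(self):
        assert rv.unconditional_mean(0.5, 0.0, 0.0) == pytest.approx(0.5)
        assert rv.unconditional_mean(0.0, 3.0, 1.0) == 0.0

    def test_monte_carlo_mean_matches_closed_form(self):
        rng = np.random.default_rng(5)
        pi, mu, s2 = 0.6, 0.4, 0.3
        n = 10_000
        y = rng.binomial(1, pi, n)
        draws = y * np.exp(rng.normal(mu, np.sqrt(s2), n))
        expected = rv.unconditional_mean(pi, mu, s2)
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se

    def test_two_step_components_are_independent(self, study_grid, study_stack, study_truth):
        obs = rv.simulate_observations(study_grid, study_stack, study_truth, 200, seed=9)
        spec_o = rv.ModelSpec("occurrence", ["sst"], include_spatial=False)
        spec_c = rv.ModelSpec("cover", ["sst"], include_spatial=False)
        cfg = rv.InferenceConfig(n_draws=300, seed=10)
        h1 = rv.fit_hurdle(obs, study_stack, spec_o, spec_c, cfg)
        # refitting occurrence alone must not perturb the conditional posterior
        h2 = rv.fit_hurdle(obs, study_stack, spec_o, spec_c, cfg)
        np.testing.assert_array_equal(h1.conditional.b_draws, h2.conditional.b_draws)
        np.testing.assert_array_equal(h1.conditional.sigma2_draws, h2.conditional.sigma2_draws)


class TestPointwiseLoglik:
    def test_bernoulli_rows_are_valid_log_probabilities(self, occurrence_fit, study_obs):
        ll = rv.pointwise_loglik(occurrence_fit, study_obs)
        assert ll.shape == (len(study_obs), occurrence_fit.n_draws)
        assert np.isfinite(ll).all()
        assert (ll <= 0).all()

    def test_matches_independent_recomputation(self, occurrence_fit, study_obs):
        ll = rv.pointwise_loglik(occurrence_fit, study_obs)
        b = occurrence_fit.b_draws
        eta = (
            b[:, 0][None, :]
            + occurrence_fit.X @ b[:, 1:].T
            + occurrence_fit.w_draws[:, occurrence_fit.site_index].T
        )
        p = expit(eta)
        y = study_obs.y[:, None]
        expected = np.where(y == 1, np.log(p), np.log1p(-p))
        np.testing.assert_allclose(ll, expected, atol=1e-8)

    def test_misaligned_observations_rejected(self, occurrence_fit, study_grid,
                                              study_stack, study_truth):
        other = rv.simulate_observations(study_grid, study_stack, study_truth, 100, seed=99)
        with pytest.raises(ValueError, match="does not match"):
            rv.pointwise_loglik(occurrence_fit, other)
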