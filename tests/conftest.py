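"""Shared fixtures: small seeded grids, covariate stacks and fits."""

import numpy as np
import pytest

import reefvuln as rv


@pytest.fixture(scope="session")
def allsea_grid():
    """13x13 all-sea grid at the default 0.08-degree resolution."""
    return rv.make_grid((0.0, 1.0, 0.0, 1.0), 0.08, {"kind": "all_sea"}, seed=1)


@pytest.fixture(scope="session")
def coastal_grid():
    return rv.make_grid((-3.0, -2.0, 40.0, 41.0), 0.05, {"kind": "band"}, seed=2)


@pytest.fixture(scope="session")
def study_grid():
    """Larger all-sea domain used for fitting experiments."""
    return rv.make_grid((-2.0, 1.2, 40.0, 43.2), 0.08, {"kind": "all_sea"}, seed=1)


@pytest.fixture(scope="session")
def study_stack(study_grid):
    return rv.simulate_covariates(study_grid, seed=3)


@pytest.fixture(scope="session")
def study_truth():
    """Hurdle truth with a short-range residual field so the fixed
    effects stay identifiable next to the latitudinal SST gradient."""
    return rv.ModelTruth(
        alpha_occ=0.2,
        beta_occ={"sst": 1.2, "bathymetry": 0.6},
        alpha_cond=1.0,
        beta_cond={"sst": -0.8},
        sigma2_cond=0.25,
        matern_occ=rv.MaternParams(0.6, 0.35),
        matern_cond=rv.MaternParams(0.4, 0.35),
    )


@pytest.fixture(scope="session")
def study_obs(study_grid, study_stack, study_truth):
    return rv.simulate_observations(study_grid, study_stack, study_truth, 800, seed=11)


@pytest.fixture(scope="session")
def occurrence_fit(study_obs, study_stack):
    spec = rv.ModelSpec("occurrence", ["sst", "bathymetry"], include_spatial=True)
    return rv.fit_occurrence(study_obs, study_stack, spec, rv.InferenceConfig(n_draws=600, seed=5))


@pytest.fixture(scope="session")
def conditional_fit(study_obs, study_stack):
    spec = rv.ModelSpec("cover", ["sst"], include_spatial=True)
    return rv.fit_conditional_lognormal(
        study_obs.presence_subset(), study_stack, spec, rv.InferenceConfig(n_draws=600, seed=6)
    )


def make_stack_from_arrays(grid, **layers):
    """Build a CovariateStack from flat sea-cell value arrays."""
    stack = rv.CovariateStack(grid=grid)
    for name, vals in layers.items():
        raster = np.full(grid.shape, np.nan)
        raster[grid.mask] = vals
        stack.add(name, raster)
    return stack
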