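"""Generate a synthetic coastal grid with covariates and observations.

Builds a 0.08-degree coastal-strip grid, simulates environmental
rasters (SST spanning ~21-28 degC with latitude, salinity, light
attenuation, pH, oxygen, productivity, bathymetry), and draws site
records from a hurdle model: Bernoulli presence and, where present,
lognormal percent coral cover.
"""

import reefvuln as rv

grid = rv.make_grid((-3.0, -1.0, 40.0, 41.5), resolution=0.08,
                    coastline_profile={"kind": "band"}, seed=1)
print(f"grid: {grid.n_lat} x {grid.n_lon} cells, {grid.n_sea} sea cells")

stack = rv.simulate_covariates(grid, seed=2)
sst = stack.sea_values("sst")
print(f"SST over sea cells: {sst.min():.1f} to {sst.max():.1f} degC")

truth = rv.ModelTruth(
    alpha_occ=0.3, beta_occ={"sst": 1.0, "bathymetry": 0.6},
    alpha_cond=2.2, beta_cond={"sst": -0.5}, sigma2_cond=0.3,
    matern_occ=rv.MaternParams(sigma=0.6, range_=0.35),
    matern_cond=rv.MaternParams(sigma=0.4, range_=0.35),
)
obs = rv.simulate_observations(grid, stack, truth, n_sites=200, seed=3)
pres = obs.presence_subset()
print(f"{len(obs)} site records, {obs.y.mean():.0%} presences")
print(f"conditional cover where present: mean {pres.z.mean():.1f}% of benthos")
# The presence fraction reflects the logit intercept and SST effect;
# percent cover is the conditional-to-presence response of the hurdle.
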