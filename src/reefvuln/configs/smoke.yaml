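# Smoke pipeline: a 20x20-cell coastal strip with 150 observation sites.
# Runs every stage end-to-end in a few minutes on one CPU.
seed: 20

grid:
  extent: [-3.0, -2.0, 40.0, 41.0]
  resolution: 0.05
  coastline:
    kind: band
    band_width: 0.7

observations:
  n_sites: 150
  records_per_site: 1

truth:
  cover:
    alpha_occ: 0.3
    beta_occ: {sst: 1.0, bathymetry: 0.6}
    alpha_cond: 2.2
    beta_cond: {sst: -0.5}
    sigma2_cond: 0.3
    matern_occ: {sigma: 0.6, range: 0.4}
    matern_cond: {sigma: 0.4, range: 0.4}
  bleaching:
    alpha_occ: 0.3
    beta_occ: {sst: 1.0, bathymetry: 0.6}
    alpha_cond: 1.5
    beta_cond: {sst: 0.8}
    sigma2_cond: 0.4
    matern_occ: {sigma: 0.6, range: 0.4}
    matern_cond: {sigma: 0.4, range: 0.4}

screening:
  gvif_threshold: 3.0
  corr_threshold: 0.70

selection:
  enabled: true
  candidates: [sst, bathymetry, kd]
  include_spatial_step: true

inference:
  n_draws: 500
  sigma_grid: [0.3, 0.8]
  range_fractions: [0.2, 0.5]
  sigma2_grid_size: 5

vulnerability:
  thresholds: auto
  standardize_future_by: current
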