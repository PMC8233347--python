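# Methods

## Models

Three responses are modelled on site records pooled across species (an
assemblage, with no species effect; an optional records-per-site
multiplier emulates multiple species records at one site):

* **Occurrence** `Y_i ∈ {0,1}`: Bernoulli with logit link,
  `logit(π_i) = α^(Y) + X_i β + W_i^(Y)`.
* **Conditional cover / bleaching** `Z_i > 0` (percent, only where
  `Y_i = 1`): lognormal on the natural-log scale,
  `log Z_i ~ N(α^(Z) + X_i β + W_i^(Z), σ²)`.

The two hurdle components are fitted independently (two-step); the
unconditional expected response is `π_i · exp(μ_i + σ²/2)`, evaluated
per posterior draw and then averaged.  Coefficients act on z-scored
covariates (standardized over sea cells, population sd); the recorded
means/sds are reapplied to future covariate stacks so a +3 °C shift
stays visible as +3/sd.  Fixed effects carry vague N(0, 100) priors.
Occurrence and conditional coefficient vectors are independent — the
two predictors share no parameters.

`W` is a zero-mean Gaussian field with Matérn covariance
`C(d) = σ_w² · 2^(1-ν)/Γ(ν) (κd)^ν K_ν(κd)`, `κ = √(8ν)/range`, so the
correlation is ≈ 0.14 at distance `range`.  Distances are planar in
decimal degrees (the coastal-strip domains are narrow; great-circle
kilometres available via `metric="great_circle"`).  Smoothness ν
defaults to 1 and is exposed, not asserted.  The field is represented
exactly at the unique site locations via a dense Cholesky factor
(desk scale, ≲ 2,000 sites); no sparse-mesh approximation is needed at
these sizes.

## Inference

A deterministic Laplace / empirical-Bayes scheme:

* Spatial hyperparameters live on a small grid: σ_w over
  `sigma_grid` (default 0.3/0.75/1.5) with an Exponential(1) prior
  that shrinks toward "no spatial effect", and range over fractions
  (default 0.15/0.35/0.7) of the site bounding-box diagonal, uniform.
* Per grid point, the joint posterior of `(α, β, W)` is exact for the
  Gaussian likelihood and a Newton-optimised Gaussian (Laplace)
  approximation for the Bernoulli likelihood (damped steps, warm
  starts across the grid, convergence flagged in diagnostics).
* Grid points are weighted by (approximate) marginal likelihood ×
  hyperprior; posterior draws (default 1000) are sampled from the
  resulting Gaussian mixture.  For the conditional model, σ² steers
  the latent posterior through an empirical-Bayes grid around the OLS
  residual variance, and each retained draw then refreshes σ² from
  its inverse-gamma conditional (Jeffreys prior) so its posterior
  spread is continuous.
* Pointwise log-likelihoods (n_obs × n_draws) are stored with every
  fit; the lognormal rows include the −log z Jacobian so they are
  densities of z, not of log z.

Convergence failures warn and are recorded, never silent.  The engine
commits to the model contract (posterior summaries + pointwise
log-likelihoods) and is validated by parameter recovery and interval
calibration, not by matching any reference sampler.

## Model selection

`waic` follows the pointwise form: `elpd_i = log mean_d exp(ll_id)`,
`p_i = var_d(ll_id)`, `WAIC = −2 Σ_i (elpd_i − p_i)`.  `lcpo` uses the
harmonic-mean CPO estimator, `LCPO = −(1/n) Σ log CPO_i`; it is ≥ 0
for discrete likelihoods and unbounded above in general — a claimed
[0, 1] range for a summed version is not reproducible for this
standard definition, so the standard definition is what is
implemented.  "Lowest WAIC and LCPO combined" is realised as the sum
of within-trace ranks (ties → WAIC); both raw values are always
reported so users can re-rank.  Forward selection is greedy from the
intercept-only non-spatial null, covariates one by one, the spatial
effect tried last (exhaustive subsets available for ≤ 5 candidates).

## Covariate preparation

* Rugosity = seabed slope in degrees from Horn's 3×3 gradient;
  edge cells replicate their own value outward and missing neighbours
  fall back to the centre value.
* Regridding is missing-aware block-mean aggregation restricted to
  whole-number coarsening factors; refining raises.
* Cover records reported as a fraction of total coral cover are
  rescaled to percent of benthos by multiplying with total coral
  cover.
* Screening removes one variable at a time, recomputing after each
  removal: first the largest df-corrected GVIF above 3 (the threshold
  applies to the corrected value `GVIF^(1/(2·df))`), then, when none
  remain, the member of the highest-|r| pair above 0.70 with the
  larger mean |r| to the others; ties break alphabetically for a
  deterministic audit trail.  Statistics are computed at the
  observation sites (where models are fitted), not over all cells;
  both orders of offender type are reachable through the thresholds.

## Prediction and scenarios

Posterior draws of the linear predictor are pushed through the link at
every sea cell.  The spatial field is carried to unobserved cells by
barycentric (Delaunay) linear interpolation of the per-draw field
values from the fitted sites; cells outside the site hull fall back to
the nearest site and are counted.  Cells whose covariates leave the
fitted per-covariate range are flagged as extrapolation but still
predicted.  Future surfaces reuse the fit unchanged — SST/SSS shifted
by the scenario deltas (+1/+1 mid-century, +3/+1.5 end-century by
default), all other layers bit-identical, the spatial field held
fixed (a config toggle can zero it).

## Vulnerability

Each of the three surfaces is divided by its maximum over sea cells;
future surfaces are divided by the **current** scenario's maximum per
response so scores stay on one scale across scenarios (per-scenario
maxima available via config).  The cell-wise product is the
vulnerability score in [0, 1].  Class thresholds are the 25th/75th
percentiles (linear-interpolation convention) of the current
projection's sea-cell values, or a fixed override such as
(0.21, 0.78); classes are half-open — low `[0, q_low)`, intermediate
`[q_low, q_high)`, hotspot `[q_high, 1]` — which closes the gaps that
rounded printed bounds would leave.  Thresholds are frozen from the
current scenario for all future classifications, which is what makes
"the low class shrank by 50%" a well-defined statement.  Gaussian
KDEs on a common lattice compare value distributions across
scenarios; summaries report percent change of the mean and of
per-class mass.

## Synthetic data

The generator emulates a tropical-to-subtropical coastal strip: a
sinusoidal-coastline band mask; SST as a monotone latitudinal ramp
spanning 21–28 °C plus short-range Matérn noise; SSS/KD/pH/O₂/PP as
Matérn fields around realistic open-coast means; bathymetry deepening
offshore.  Observations follow exactly the hurdle model above, with z
capped at 100% (capped draws counted and warned).  It does **not**
emulate real-data features such as irregular survey effort, temporal
span, detection error, species-specific thermal tolerances, or
correlated covariate fields with realistic cross-covariances — so
passing tests demonstrate correctness of the machinery and
recoverability under the assumed model, not field performance.

Recovery experiments use a residual-field range (0.35°) shorter than
the domain-scale SST gradient.  This is the identifiable regime: when
the spatial effect's range approaches the domain size it becomes
confounded with smooth covariates (posterior mass is shared between
β_SST and the field), a bias that does not vanish with n.  With one
record per site, σ² and the field variance are likewise only jointly
weakly identified; fixed-effect intervals remain calibrated, σ²
intervals less so.

## Numerical choices and sizes

Covariance factorisations add jitter 1e-8·σ²; Matérn correlation
evaluates to its limits at under/overflowing arguments.  Newton stops
at relative log-posterior change < 1e-8 with gradient check, max 50
iterations.  Posterior quantiles use draws (default 1000; 300–600 in
the fast test configurations).  Test problem sizes: recovery at
n ∈ {100, 400, 1600} (40/40/20 replicates; extra replicates at the
cheap sizes keep the Monte-Carlo error of the sample median below the
expected bias gaps) and interval calibration at n = 800 × 20
replicates; field fidelity at 10,000 replicate draws on 64 cells; the
bundled smoke pipeline is a 20×20-cell strip with 150 sites.  Raster,
surface and observation exchange is long-format CSV with the grid
geometry embedded in JSON header comments; configs are YAML; run
manifests record config hash, seed, package version and SHA-256 of
every artifact.
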