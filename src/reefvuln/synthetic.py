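"""Seeded synthetic coastal-grid data with the structure the models assume.

Generates a coastal-strip grid, spatially autocorrelated covariate
rasters emulating marine environmental layers (SST, SSS, KD, pH, O2,
PP, bathymetry), latent Matérn spatial fields, Bernoulli-logit
occurrence records with conditional lognormal percent responses, and
future-scenario covariate stacks (RCP8.5-style SST/SSS shifts), so the
whole pipeline is testable without any downloads.

Covariate coefficients in :class:`ModelTruth` act on the z-scored
(standardized over sea cells) covariates, matching the scale on which
the models are fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .grid import SpatialGrid, make_grid  # noqa: F401  (re-exported)
from .matern import MaternParams, matern_covariance
from .observations import ObservationSet
from .stack import CovariateStack

#: Scenario shifts applied to (SST in degC, SSS in PSU): RCP8.5-style
#: mean increases by 2040-2050 and 2090-2100.
SCENARIO_DELTAS = {
    "mid_century": {"sst": 1.0, "sss": 1.0},
    "end_century": {"sst": 3.0, "sss": 1.5},
}

#: Default synthetic covariates.  SST follows a monotone latitudinal
#: trend spanning ~21-28 degC (a tropical-to-subtropical coastal
#: gradient) plus Matérn noise; the others are Matérn fields around
#: realistic open-coast means; bathymetry deepens offshore.
DEFAULT_COVARIATE_SPEC: dict[str, dict] = {
    "sst": {"kind": "lat_trend", "low": 21.0, "high": 28.0, "noise_sd": 0.2, "noise_range": 0.6},
    "sss": {"kind": "matern_mean", "mean": 36.5, "sd": 0.6, "range": 1.0},
    "kd": {"kind": "matern_mean", "mean": 0.10, "sd": 0.03, "range": 0.8, "min": 0.01},
    "ph": {"kind": "matern_mean", "mean": 8.05, "sd": 0.04, "range": 1.0},
    "o2": {"kind": "matern_mean", "mean": 220.0, "sd": 12.0, "range": 1.0},
    "pp": {"kind": "matern_mean", "mean": 500.0, "sd": 120.0, "range": 0.8, "min": 1.0},
    "bathymetry": {
        "kind": "bathymetry",
        "shelf_depth": 5.0,
        "slope_depth": 150.0,
        "noise_sd": 5.0,
        "range": 0.5,
    },
}

_KINDS = {"lat_trend", "matern_mean", "bathymetry"}


@dataclass
class ModelTruth:
    """True generative parameters for one hurdle response.

    Intercepts ``alpha_occ``/``alpha_cond``, coefficient dicts keyed by
    covariate name (on the z-scored covariate scale), the lognormal
    log-scale variance ``sigma2_cond``, and Matérn hyperparameters of
    the occurrence and conditional spatial fields (None disables the
    field).
    """

    alpha_occ: float = 0.0
    alpha_cond: float = 0.0
    beta_occ: dict[str, float] = field(default_factory=dict)
    beta_cond: dict[str, float] = field(default_factory=dict)
    sigma2_cond: float = 0.25
    matern_occ: MaternParams | None = None
    matern_cond: MaternParams | None = None

    def __post_init__(self) -> None:
        if self.sigma2_cond <= 0:
            raise ValueError(f"sigma2_cond must be > 0, got {self.sigma2_cond}")

    @property
    def covariate_names(self) -> list[str]:
        return sorted(set(self.beta_occ) | set(self.beta_cond))


def simulate_matern_field(
    grid: SpatialGrid,
    params: MaternParams,
    seed: int,
    size: int = 1,
    metric: str = "planar",
) -> np.ndarray:
    """Zero-mean Matérn Gaussian field draw(s) over the sea cells.

    Uses the exact dense Cholesky factor of the Matérn covariance of
    the sea-cell centers.  Returns shape (n_sea,) for ``size=1``, else
    (size, n_sea).  Reproducible per seed.
    """
    coords = grid.sea_centers()
    n = len(coords)
    if n < 2:
        raise ValueError("grid must have at least 2 sea cells")
    rng = np.random.default_rng(seed)
    if params.sigma == 0:
        draws = np.zeros((size, n))
    else:
        cov = matern_covariance(coords, params, metric=metric)
        chol = np.linalg.cholesky(cov)
        draws = rng.standard_normal((size, n)) @ chol.T
    return draws[0] if size == 1 else draws


def _field_raster(grid: SpatialGrid, params: MaternParams, seed: int) -> np.ndarray:
    out = np.full(grid.shape, np.nan)
    out[grid.mask] = simulate_matern_field(grid, params, seed)
    return out


def simulate_covariates(
    grid: SpatialGrid,
    seed: int,
    spec: dict[str, dict] | None = None,
) -> CovariateStack:
    """Generate one raster per covariate on the grid's sea mask.

    ``spec`` maps covariate names (a subset of the default set) to
    generator parameters; unknown names raise.  Layers are seeded
    independently (sorted-name order) from ``seed``, so two seeds give
    different noise but the same deterministic trend components.
    """
    spec = DEFAULT_COVARIATE_SPEC if spec is None else spec
    unknown = sorted(set(spec) - set(DEFAULT_COVARIATE_SPEC))
    if unknown:
        raise ValueError(f"unknown covariate name(s) in spec: {unknown}")

    stack = CovariateStack(grid=grid, scenario="current")
    seeds = {
        name: s
        for name, s in zip(
            sorted(spec), np.random.SeedSequence(seed).generate_state(len(spec))
        )
    }
    lat2d = np.broadcast_to(grid.lat_centers[:, None], grid.shape)
    sea_lats = lat2d[grid.mask]

    for name in sorted(spec):
        conf = {**DEFAULT_COVARIATE_SPEC[name], **spec[name]}
        kind = conf["kind"]
        if kind not in _KINDS:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")
        layer = np.full(grid.shape, np.nan)
        if kind == "lat_trend":
            lo, hi = sea_lats.min(), sea_lats.max()
            span = hi - lo if hi > lo else 1.0
            trend = conf["low"] + (conf["high"] - conf["low"]) * (lat2d - lo) / span
            layer[grid.mask] = trend[grid.mask]
            if conf["noise_sd"] > 0:
                pars = MaternParams(conf["noise_sd"], conf["noise_range"])
                layer[grid.mask] += simulate_matern_field(grid, pars, seeds[name])
        elif kind == "matern_mean":
            pars = MaternParams(conf["sd"], conf["range"])
            layer[grid.mask] = conf["mean"] + simulate_matern_field(grid, pars, seeds[name])
            if "min" in conf:
                layer[grid.mask] = np.maximum(layer[grid.mask], conf["min"])
        elif kind == "bathymetry":
            # depth increases with distance from the western (coastal)
            # edge of the sea band in each row
            dist = np.zeros(grid.shape)
            for i in range(grid.n_lat):
                sea_j = np.flatnonzero(grid.mask[i])
                if sea_j.size:
                    dist[i, sea_j] = (sea_j - sea_j[0]) / max(sea_j.size - 1, 1)
            depth = -(conf["shelf_depth"] + conf["slope_depth"] * dist**1.5)
            layer[grid.mask] = depth[grid.mask]
            if conf["noise_sd"] > 0:
                pars = MaternParams(conf["noise_sd"], conf["range"])
                layer[grid.mask] += simulate_matern_field(grid, pars, seeds[name])
            layer[grid.mask] = np.minimum(layer[grid.mask], -0.5)
        stack.add(name, layer)
    return stack


def _standardized_design(stack: CovariateStack, names: list[str]) -> dict[str, np.ndarray]:
    """z-score each named layer over sea cells (generator-internal)."""
    out = {}
    for name in names:
        v = stack.sea_values(name)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"covariate {name!r} is constant over sea cells")
        out[name] = (v - v.mean()) / sd
    return out


def simulate_observations(
    grid: SpatialGrid,
    covariates: CovariateStack,
    truth: ModelTruth,
    n_sites: int,
    seed: int,
    response_kind: str = "cover",
    records_per_site: int = 1,
) -> ObservationSet:
    """Draw site records from the hurdle generative model.

    Sites are distinct sea cells sampled without replacement.  For each
    record, ``y ~ Bernoulli(expit(alpha_occ + X beta_occ + W_occ))``
    and, where y = 1, ``z ~ Lognormal(alpha_cond + X beta_cond +
    W_cond, sigma2_cond)`` on the natural-log scale, expressed in
    percent and capped at 100 (capped draws are counted in
    ``obs.n_capped``).  ``records_per_site`` replicates records at each
    site (pooled assemblage records sharing the site's covariates and
    spatial-field value).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if n_sites > grid.n_sea:
        raise ValueError(f"n_sites={n_sites} exceeds number of sea cells ({grid.n_sea})")
    missing = [n for n in truth.covariate_names if n not in covariates]
    if missing:
        raise ValueError(f"truth references covariates not in stack: {missing}")

    ss = np.random.SeedSequence(seed).generate_state(4)
    rng = np.random.default_rng(ss[0])
    sea_flat = grid.sea_indices()
    pick = rng.choice(grid.n_sea, size=n_sites, replace=False)
    centers = grid.cell_centers()[sea_flat[pick]]

    std = _standardized_design(covariates, truth.covariate_names)

    def site_eta(alpha: float, beta: dict[str, float], pars, field_seed) -> np.ndarray:
        eta = np.full(n_sites, alpha)
        for name, b in beta.items():
            eta += b * std[name][pick]
        if pars is not None and pars.sigma > 0:
            w = simulate_matern_field(grid, pars, field_seed)
            eta += w[pick]
        return eta

    eta_occ = site_eta(truth.alpha_occ, truth.beta_occ, truth.matern_occ, ss[1])
    eta_cond = site_eta(truth.alpha_cond, truth.beta_cond, truth.matern_cond, ss[2])

    k = records_per_site
    rng_obs = np.random.default_rng(ss[3])
    y = rng_obs.binomial(1, expit(np.repeat(eta_occ, k)))
    z = np.full(n_sites * k, np.nan)
    pres = y == 1
    raw = np.exp(rng_obs.normal(np.repeat(eta_cond, k)[pres], np.sqrt(truth.sigma2_cond)))
    n_capped = int((raw > 100.0).sum())
    if n_capped:
        warnings.warn(f"{n_capped} lognormal draw(s) exceeded 100% and were capped")
    z[pres] = np.minimum(raw, 100.0)

    df = pd.DataFrame(
        {
            "site_id": [f"s{int(i):05d}" for i in np.repeat(np.arange(n_sites), k)],
            "lat": np.repeat(centers[:, 0], k),
            "lon": np.repeat(centers[:, 1], k),
            "response_kind": response_kind,
            "y": y,
            "z": z,
        }
    )
    obs = ObservationSet(df, response_kind=response_kind)
    obs.n_capped = n_capped
    return obs


def make_future_covariates(
    stack: CovariateStack,
    scenario: str,
    deltas: dict[str, float] | None = None,
) -> CovariateStack:
    """Shift SST/SSS by the scenario deltas; all other layers unchanged.

    Defaults: +1 degC / +1 PSU for ``mid_century``; +3 degC / +1.5 PSU
    for ``end_century`` (high-emission RCP8.5-style mean changes, with
    every non-SST/SSS layer held constant).
    """
    if scenario not in SCENARIO_DELTAS:
        raise ValueError(f"scenario must be one of {sorted(SCENARIO_DELTAS)}, got {scenario!r}")
    for req in ("sst", "sss"):
        if req not in stack:
            raise ValueError(f"stack is missing required layer {req!r}")
    shifts = dict(SCENARIO_DELTAS[scenario]) if deltas is None else dict(deltas)
    out = stack.copy(scenario=scenario)
    for name, delta in shifts.items():
        if name not in out:
            raise ValueError(f"delta given for layer {name!r} not in stack")
        out.layers[name] = out.layers[name] + delta
    return out
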