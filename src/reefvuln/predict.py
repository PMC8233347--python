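"""Projection of fitted models onto the grid under each scenario.

Posterior draws of the linear predictor are evaluated at every sea
cell: fixed effects through the standardized covariate rasters, the
spatial field by linear (barycentric) interpolation of the posterior
field draws from the fitted site locations, with a nearest-node
fallback outside the site hull (counted on the surface).  Cells whose
covariates fall outside the fitted covariate range are flagged as
extrapolation.  Future-scenario surfaces reuse the fit unchanged (no
refitting); the spatial field is carried across scenarios by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError
from scipy.special import expit

from .grid import SpatialGrid
from .model import HurdleFit, PosteriorFit
from .stack import CovariateStack


@dataclass
class ProbabilitySurface:
    """Per-cell posterior-mean probability (or expected percent cover)
    with posterior sd and an extrapolation flag, NaN on land."""

    grid: SpatialGrid
    scenario: str
    response_kind: str
    values: np.ndarray
    uncertainty: np.ndarray
    extrapolation: np.ndarray = None
    n_nearest_fallback: int = 0

    def sea_values(self) -> np.ndarray:
        return self.values[self.grid.mask]

    def copy_with(self, values: np.ndarray, scenario: str | None = None) -> "ProbabilitySurface":
        return ProbabilitySurface(
            grid=self.grid,
            scenario=self.scenario if scenario is None else scenario,
            response_kind=self.response_kind,
            values=values,
            uncertainty=self.uncertainty.copy(),
            extrapolation=None if self.extrapolation is None else self.extrapolation.copy(),
            n_nearest_fallback=self.n_nearest_fallback,
        )


@dataclass
class DeltaSurface:
    """Cell-wise future minus current difference of two surfaces."""

    grid: SpatialGrid
    pair: tuple[str, str]
    response_kind: str
    values: np.ndarray


def _interpolate_field(
    site_coords: np.ndarray, w_draws: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, int]:
    """Linear interpolation of per-draw field values from fitted sites
    to target points; nearest-site fallback outside the hull."""
    vals = w_draws.T  # (m, n_draws)
    nearest = NearestNDInterpolator(site_coords, vals)
    try:
        lin = LinearNDInterpolator(site_coords, vals)
        out = lin(targets)
    except (QhullError, ValueError):
        out = np.full((len(targets), vals.shape[1]), np.nan)
    miss = np.isnan(out).any(axis=1)
    n_fallback = int(miss.sum())
    if n_fallback:
        out[miss] = nearest(targets[miss])
    return out, n_fallback  # (n_targets, n_draws)


def _eta_draws(fit: PosteriorFit, stack: CovariateStack) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_sea, n_draws) linear predictor draws at sea cells, the
    extrapolation flags, and the nearest-fallback count."""
    grid = stack.grid
    names = fit.spec.covariate_names
    missing = [n for n in names if n not in stack]
    if missing:
        raise ValueError(f"stack is missing covariate(s) required by the fit: {missing}")
    std_stack = fit.standardization.apply(stack)
    Xc = std_stack.design_matrix(names)
    if np.isnan(Xc).any():
        raise ValueError("missing covariate values at sea cells")
    eta = fit.b_draws[:, 0][None, :] + Xc @ fit.b_draws[:, 1:].T

    if names:
        lo = fit.X.min(axis=0)
        hi = fit.X.max(axis=0)
        extrap_sea = ((Xc < lo) | (Xc > hi)).any(axis=1)
    else:
        extrap_sea = np.zeros(grid.n_sea, dtype=bool)

    n_fallback = 0
    if fit.w_draws.shape[1]:
        w_cells, n_fallback = _interpolate_field(
            fit.site_coords, fit.w_draws, grid.sea_centers()
        )
        eta = eta + w_cells
    return eta, extrap_sea, n_fallback


def _to_raster(grid: SpatialGrid, sea_vals: np.ndarray) -> np.ndarray:
    out = np.full(grid.shape, np.nan)
    out[grid.mask] = sea_vals
    return out


def predict_surface(
    fit: PosteriorFit | HurdleFit,
    stack: CovariateStack,
    grid: SpatialGrid | None = None,
) -> ProbabilitySurface:
    """Posterior predictive surface of a fit on the stack's grid.

    Occurrence fits yield the posterior-mean probability (expit of the
    linear predictor averaged over draws); conditional fits yield the
    expected conditional percent, exp(eta + sigma2/2); hurdle fits
    yield the unconditional expected percent pi * exp(eta + sigma2/2),
    paired draw by draw.
    """
    if grid is not None and not grid.same_lattice(stack.grid):
        raise ValueError("grid does not match the covariate stack's lattice")
    grid = stack.grid

    if isinstance(fit, HurdleFit):
        eta_occ, ex1, f1 = _eta_draws(fit.occurrence, stack)
        eta_cond, ex2, f2 = _eta_draws(fit.conditional, stack)
        k = min(eta_occ.shape[1], eta_cond.shape[1])
        s2 = fit.conditional.sigma2_draws[:k][None, :]
        draws = expit(eta_occ[:, :k]) * np.exp(eta_cond[:, :k] + s2 / 2.0)
        extrap = ex1 | ex2
        n_fb = f1 + f2
        kind = fit.conditional.spec.response_kind
    else:
        eta, extrap, n_fb = _eta_draws(fit, stack)
        kind = fit.spec.response_kind
        if kind == "occurrence":
            draws = expit(eta)
        else:
            draws = np.exp(eta + fit.sigma2_draws[None, :] / 2.0)

    return ProbabilitySurface(
        grid=grid,
        scenario=stack.scenario,
        response_kind=kind,
        values=_to_raster(grid, draws.mean(axis=1)),
        uncertainty=_to_raster(grid, draws.std(axis=1, ddof=1)),
        extrapolation=_to_raster(grid, extrap.astype(float)) > 0.5,
        n_nearest_fallback=n_fb,
    )


def predict_scenarios(
    fit: PosteriorFit | HurdleFit,
    current_stack: CovariateStack,
    future_stacks: list[CovariateStack],
) -> list[ProbabilitySurface]:
    """One surface per scenario from the same fit (no refitting; the
    spatial field is held fixed across scenarios)."""
    surfaces = [predict_surface(fit, current_stack)]
    for fs in future_stacks:
        if not fs.grid.same_lattice(current_stack.grid):
            raise ValueError(f"future stack {fs.scenario!r} is on a different lattice")
        surfaces.append(predict_surface(fit, fs))
    return surfaces


def delta_map(future: ProbabilitySurface, current: ProbabilitySurface) -> DeltaSurface:
    """Cell-wise future minus current surface, land masked."""
    if not future.grid.same_lattice(current.grid):
        raise ValueError("surfaces are on different grids")
    if future.response_kind != current.response_kind:
        raise ValueError(
            f"response kinds differ: {future.response_kind!r} vs {current.response_kind!r}"
        )
    return DeltaSurface(
        grid=current.grid,
        pair=(future.scenario, current.scenario),
        response_kind=current.response_kind,
        values=future.values - current.values,
    )
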