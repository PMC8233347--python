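"""Matérn correlation and covariance for latent spatial fields.

The spatial random effects W in the occurrence and conditional models
are zero-mean Gaussian fields with Matérn covariance

    C(d) = sigma^2 * 2^(1-nu)/Gamma(nu) * (kappa d)^nu * K_nu(kappa d),

with kappa = sqrt(8 nu) / range, the common convention under which the
correlation has dropped to roughly 0.14 at distance ``range``.  For
nu = 1/2 this reduces to the exponential correlation
exp(-sqrt(4) d / range) = exp(-2 d / range).

Distances are planar in decimal degrees by default (the coastal-strip
domains modelled here are narrow, so the planar metric is adequate);
great-circle (haversine, in kilometres) is available via ``metric``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import kv

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class MaternParams:
    """Hyperparameters of a Matérn spatial field.

    sigma : marginal standard deviation of the field (> 0, or 0 for a
        degenerate identically-zero field).
    range_ : correlation range in coordinate units (> 0).
    nu : smoothness (> 0); default 1.
    """

    sigma: float
    range_: float
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.range_ <= 0:
            raise ValueError(f"range_ must be > 0, got {self.range_}")
        if self.nu <= 0:
            raise ValueError(f"nu must be > 0, got {self.nu}")

    @property
    def kappa(self) -> float:
        return np.sqrt(8.0 * self.nu) / self.range_


def matern_correlation(distance, params: MaternParams) -> np.ndarray:
    """Matérn correlation at the given distance(s); in (0, 1], 1 at d = 0."""
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    nu = params.nu
    x = params.kappa * d
    with np.errstate(invalid="ignore", over="ignore"):
        corr = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * np.power(x, nu) * kv(nu, x)
    # x -> 0 limit is 1 (x^nu and K_nu over/underflow there);
    # K_nu underflow to 0 at large x is the correct limit
    corr = np.where(x < 1e-8, 1.0, np.nan_to_num(corr, nan=0.0, posinf=1.0))
    out = np.clip(corr, 0.0, 1.0)
    return out if out.ndim else float(out)


def pairwise_distances(coords: np.ndarray, metric: str = "planar") -> np.ndarray:
    """Pairwise distances between (lat, lon) points.

    ``planar``: Euclidean in decimal degrees. ``great_circle``:
    haversine in kilometres.
    """
    coords = np.asarray(coords, dtype=float)
    if metric == "planar":
        diff = coords[:, None, :] - coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))
    if metric == "great_circle":
        lat = np.radians(coords[:, 0])
        lon = np.radians(coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    raise ValueError(f"unknown metric: {metric!r}")


def matern_covariance(
    coords: np.ndarray,
    params: MaternParams,
    metric: str = "planar",
    jitter: float = 1e-8,
) -> np.ndarray:
    """Dense Matérn covariance matrix between (lat, lon) points."""
    d = pairwise_distances(coords, metric=metric)
    cov = params.sigma**2 * matern_correlation(d, params)
    if jitter:
        cov = cov + jitter * max(params.sigma**2, 1.0) * np.eye(len(cov))
    return cov
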