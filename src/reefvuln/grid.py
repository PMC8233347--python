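"""Regular latitude/longitude lattices used as prediction domains.

A :class:`SpatialGrid` is a regular grid of square cells (in decimal
degrees) with a boolean sea mask.  The default resolution of 0.08
decimal degrees matches the coarsest layer of typical marine
environmental databases, to which all covariates are aggregated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DEFAULT_RESOLUTION = 0.08


@dataclass
class SpatialGrid:
    """Regular lat/lon cell lattice with a sea mask.

    Cell counts use the ceiling convention: ``n_lat = ceil((lat_max -
    lat_min) / resolution)``, so the lattice always covers the requested
    extent.  Cell centers are at ``min + (i + 0.5) * resolution``.

    Attributes
    ----------
    lat_min, lat_max, lon_min, lon_max : float
        Bounding box in decimal degrees.
    resolution : float
        Cell side in decimal degrees (> 0).
    mask : ndarray of bool, shape (n_lat, n_lon)
        True for sea cells (modelled), False for land.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = DEFAULT_RESOLUTION
    mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ValueError(
                "degenerate extent: require lat_min < lat_max and lon_min < lon_max "
                f"(got lat [{self.lat_min}, {self.lat_max}], lon [{self.lon_min}, {self.lon_max}])"
            )
        if self.mask is None:
            self.mask = np.ones((self.n_lat, self.n_lon), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (self.n_lat, self.n_lon):
                raise ValueError(
                    f"mask shape {self.mask.shape} != grid shape {(self.n_lat, self.n_lon)}"
                )

    @property
    def n_lat(self) -> int:
        return math.ceil(round((self.lat_max - self.lat_min) / self.resolution, 9))

    @property
    def n_lon(self) -> int:
        return math.ceil(round((self.lon_max - self.lon_min) / self.resolution, 9))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def n_sea(self) -> int:
        return int(self.mask.sum())

    @property
    def lat_centers(self) -> np.ndarray:
        """Latitudes of cell-row centers (ascending)."""
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution

    @property
    def lon_centers(self) -> np.ndarray:
        """Longitudes of cell-column centers (ascending)."""
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of (lat, lon) for every cell, row-major."""
        lat, lon = np.meshgrid(self.lat_centers, self.lon_centers, indexing="ij")
        return np.column_stack([lat.ravel(), lon.ravel()])

    def sea_centers(self) -> np.ndarray:
        """(n_sea, 2) array of (lat, lon) for sea cells only."""
        return self.cell_centers()[self.mask.ravel()]

    def sea_indices(self) -> np.ndarray:
        """Flat (row-major) indices of sea cells."""
        return np.flatnonzero(self.mask.ravel())

    def cell_of(self, lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given coordinates."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.clip(((lat - self.lat_min) / self.resolution).astype(int), 0, self.n_lat - 1)
        j = np.clip(((lon - self.lon_min) / self.resolution).astype(int), 0, self.n_lon - 1)
        return i, j

    def same_lattice(self, other: "SpatialGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.resolution, other.resolution)
            and np.isclose(self.lat_min, other.lat_min)
            and np.isclose(self.lon_min, other.lon_min)
            and np.array_equal(self.mask, other.mask)
        )

    def to_dict(self) -> dict:
        return {
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "resolution": self.resolution,
        }


def make_grid(
    extent: tuple[float, float, float, float],
    resolution: float = DEFAULT_RESOLUTION,
    coastline_profile: dict | None = None,
    seed: int = 0,
) -> SpatialGrid:
    """Build a grid whose sea mask emulates a coastal strip.

    Parameters
    ----------
    extent : (lat_min, lat_max, lon_min, lon_max)
        Bounding box in decimal degrees.
    resolution : float
        Cell side in decimal degrees; default 0.08.
    coastline_profile : dict, optional
        Parametric coastline. ``kind``:

        - ``"all_sea"``: every cell is sea.
        - ``"band"`` (default): a contiguous longitudinal band of sea
          cells whose western edge follows a sinusoidal coastline,
          ``lon_coast(lat) = lon_min + offset + amplitude *
          sin(2*pi*(lat - lat_min)/wavelength + phase)``, with a small
          seeded smooth wiggle.  Keys: ``band_width`` (degrees of sea,
          default 60% of the lon extent), ``amplitude`` (default 8% of
          the lon extent), ``wavelength`` (default lat extent),
          ``wiggle`` (sd of the seeded smooth perturbation, default
          half the amplitude).
    seed : int
        Controls only the coastline wiggle; the grid is deterministic
        given (extent, resolution, profile, seed).
    """
    lat_min, lat_max, lon_min, lon_max = extent
    grid = SpatialGrid(lat_min, lat_max, lon_min, lon_max, resolution)
    profile = dict(coastline_profile or {})
    kind = profile.pop("kind", "band")
    if kind == "all_sea":
        if profile:
            raise ValueError(f"unknown coastline_profile keys: {sorted(profile)}")
        return grid
    if kind != "band":
        raise ValueError(f"unknown coastline profile kind: {kind!r}")

    lon_extent = lon_max - lon_min
    lat_extent = lat_max - lat_min
    band_width = profile.pop("band_width", 0.6 * lon_extent)
    amplitude = profile.pop("amplitude", 0.08 * lon_extent)
    wavelength = profile.pop("wavelength", lat_extent)
    phase = profile.pop("phase", 0.0)
    wiggle = profile.pop("wiggle", 0.5 * amplitude)
    if profile:
        raise ValueError(f"unknown coastline_profile keys: {sorted(profile)}")

    lats = grid.lat_centers
    coast = lon_min + amplitude * (1 + np.sin(2 * np.pi * (lats - lat_min) / wavelength + phase))
    if wiggle > 0:
        rng = np.random.default_rng(seed)
        rough = rng.normal(0.0, 1.0, size=lats.size)
        # smooth the white noise so the coastline stays contiguous
        kernel = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(np.pad(rough, 4, mode="edge"), kernel, mode="valid")
        coast = coast + wiggle * smooth
    coast = np.clip(coast, lon_min, lon_max - resolution)

    lons = grid.lon_centers
    mask = (lons[None, :] >= coast[:, None]) & (lons[None, :] < coast[:, None] + band_width)
    # guarantee at least one sea cell per row so the band is contiguous
    empty = ~mask.any(axis=1)
    if empty.any():
        j = np.clip(((coast[empty] - lon_min) / resolution).astype(int), 0, grid.n_lon - 1)
        mask[np.flatnonzero(empty), j] = True
    grid.mask = mask
    return grid
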