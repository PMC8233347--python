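"""Named raster stacks on a :class:`~reefvuln.grid.SpatialGrid`."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import SpatialGrid


@dataclass
class CovariateStack:
    """A set of named environmental rasters sharing one grid.

    Each layer is a float array of shape ``grid.shape`` with NaN on
    land cells.  ``scenario`` labels the climate period the stack
    represents ("current", "mid_century", "end_century").
    """

    grid: SpatialGrid
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    scenario: str = "current"

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, grid is {self.grid.shape}"
                )
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return sorted(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def add(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(f"layer {name!r} shape {values.shape} != {self.grid.shape}")
        self.layers[name] = values

    def copy(self, scenario: str | None = None) -> "CovariateStack":
        return CovariateStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            scenario=self.scenario if scenario is None else scenario,
        )

    def sea_values(self, name: str) -> np.ndarray:
        """Values of one layer at sea cells (row-major order)."""
        return self.layers[name][self.grid.mask]

    def at_sites(self, lat, lon, names: list[str] | None = None) -> pd.DataFrame:
        """Extract covariate values at point locations (containing cell)."""
        names = self.names if names is None else list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"covariates not in stack: {missing}")
        i, j = self.grid.cell_of(np.asarray(lat), np.asarray(lon))
        return pd.DataFrame({n: self.layers[n][i, j] for n in names})

    def design_matrix(self, names: list[str]) -> np.ndarray:
        """(n_sea, len(names)) matrix of layer values over sea cells."""
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"covariates not in stack: {missing}")
        return np.column_stack([self.sea_values(n) for n in names]) if names else np.empty(
            (self.grid.n_sea, 0)
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long format (lat, lon, name, value) over sea cells."""
        centers = self.grid.sea_centers()
        frames = []
        for name in self.names:
            frames.append(
                pd.DataFrame(
                    {
                        "lat": centers[:, 0],
                        "lon": centers[:, 1],
                        "name": name,
                        "value": self.sea_values(name),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)
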