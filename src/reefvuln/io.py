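"""CSV and config I/O.

Rasters, stacks and surfaces are exchanged as long-format CSV
(lat, lon, name/value columns over sea cells) with the grid geometry
and scenario embedded as JSON in ``#``-prefixed header lines, so a
file round-trips to the identical in-memory object.  Configs are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import SpatialGrid
from .observations import ObservationSet
from .predict import ProbabilitySurface
from .stack import CovariateStack


def _write_with_meta(df: pd.DataFrame, meta: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        df.to_csv(fh, index=False)


def _read_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = json.loads(val)
    df = pd.read_csv(path, skiprows=skip)
    return df, meta


def _grid_from_meta(meta: dict, df: pd.DataFrame) -> SpatialGrid:
    g = meta["grid"]
    grid = SpatialGrid(**g)
    mask = np.zeros(grid.shape, dtype=bool)
    i, j = grid.cell_of(df["lat"].to_numpy(), df["lon"].to_numpy())
    mask[i, j] = True
    grid.mask = mask
    return grid


def write_stack(stack: CovariateStack, path) -> None:
    meta = {"grid": stack.grid.to_dict(), "scenario": stack.scenario}
    _write_with_meta(stack.to_dataframe(), meta, path)


def read_stack(path) -> CovariateStack:
    df, meta = _read_with_meta(path)
    first = df[df["name"] == df["name"].iloc[0]]
    grid = _grid_from_meta(meta, first)
    stack = CovariateStack(grid=grid, scenario=meta.get("scenario", "current"))
    for name, sub in df.groupby("name", sort=True):
        layer = np.full(grid.shape, np.nan)
        i, j = grid.cell_of(sub["lat"].to_numpy(), sub["lon"].to_numpy())
        layer[i, j] = sub["value"].to_numpy()
        stack.add(str(name), layer)
    return stack


def write_surface(surface: ProbabilitySurface, path) -> None:
    grid = surface.grid
    centers = grid.sea_centers()
    df = pd.DataFrame(
        {
            "lat": centers[:, 0],
            "lon": centers[:, 1],
            "value": surface.values[grid.mask],
            "sd": surface.uncertainty[grid.mask],
            "extrapolation": (
                surface.extrapolation[grid.mask].astype(int)
                if surface.extrapolation is not None
                else 0
            ),
        }
    )
    meta = {
        "grid": grid.to_dict(),
        "scenario": surface.scenario,
        "response_kind": surface.response_kind,
        "n_nearest_fallback": surface.n_nearest_fallback,
    }
    _write_with_meta(df, meta, path)


def read_surface(path) -> ProbabilitySurface:
    df, meta = _read_with_meta(path)
    grid = _grid_from_meta(meta, df)
    values = np.full(grid.shape, np.nan)
    sd = np.full(grid.shape, np.nan)
    ex = np.zeros(grid.shape, dtype=bool)
    i, j = grid.cell_of(df["lat"].to_numpy(), df["lon"].to_numpy())
    values[i, j] = df["value"].to_numpy()
    sd[i, j] = df["sd"].to_numpy()
    ex[i, j] = df["extrapolation"].to_numpy().astype(bool)
    return ProbabilitySurface(
        grid=grid,
        scenario=meta.get("scenario", "current"),
        response_kind=meta.get("response_kind", "occurrence"),
        values=values,
        uncertainty=sd,
        extrapolation=ex,
        n_nearest_fallback=int(meta.get("n_nearest_fallback", 0)),
    )


def read_observations(path, response_kind: str | None = None) -> ObservationSet:
    return ObservationSet.from_csv(path, response_kind=response_kind)


def write_observations(obs: ObservationSet, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    obs.to_csv(path)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
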