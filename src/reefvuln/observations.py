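"""Site-level observation tables for occurrence, cover and bleaching.

An :class:`ObservationSet` holds assemblage records: a presence
indicator ``y`` per record and, where the assemblage is present, a
positive percent value ``z`` (coral cover or percent bleached),
conditional-to-presence.  Multiple records may share a site (pooled
assemblage records).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import SpatialGrid

RESPONSE_KINDS = ("occurrence", "cover", "bleaching")
CSV_COLUMNS = ["site_id", "lat", "lon", "response_kind", "y", "z"]


@dataclass
class ObservationSet:
    """Validated table of site records.

    ``df`` columns: site_id, lat, lon, response_kind, y (0/1), z
    (positive percent, NaN where y = 0 or for pure occurrence data).
    """

    df: pd.DataFrame
    response_kind: str = "occurrence"

    def __post_init__(self) -> None:
        if self.response_kind not in RESPONSE_KINDS:
            raise ValueError(f"response_kind must be one of {RESPONSE_KINDS}")
        df = self.df
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        y = df["y"].to_numpy()
        if not np.isin(y, [0, 1]).all():
            raise ValueError("y must be 0 or 1")
        z = df["z"].to_numpy(dtype=float)
        has_z = ~np.isnan(z)
        if np.any(has_z & (y == 0)):
            raise ValueError("z present where y = 0 (conditional-to-presence violated)")
        if np.any(z[has_z] <= 0):
            raise ValueError("z must be > 0 where present")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lat(self) -> np.ndarray:
        return self.df["lat"].to_numpy(dtype=float)

    @property
    def lon(self) -> np.ndarray:
        return self.df["lon"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=int)

    @property
    def z(self) -> np.ndarray:
        return self.df["z"].to_numpy(dtype=float)

    def presence_subset(self) -> "ObservationSet":
        """Records with y = 1 and a z value (input to conditional models)."""
        sub = self.df[(self.df["y"] == 1) & self.df["z"].notna()].reset_index(drop=True)
        return ObservationSet(sub, response_kind=self.response_kind)

    def validate_on_grid(self, grid: SpatialGrid) -> None:
        """Check every record falls in a sea cell of the grid."""
        i, j = grid.cell_of(self.lat, self.lon)
        if not grid.mask[i, j].all():
            bad = np.flatnonzero(~grid.mask[i, j])
            raise ValueError(f"{bad.size} observation(s) fall on land cells, e.g. row {bad[0]}")

    def to_csv(self, path) -> None:
        self.df[CSV_COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, response_kind: str | None = None) -> "ObservationSet":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"malformed observation CSV, missing column(s): {missing}")
        if response_kind is None:
            kinds = df["response_kind"].unique()
            if len(kinds) != 1:
                raise ValueError(f"mixed response kinds in file: {sorted(kinds)}")
            response_kind = str(kinds[0])
        return cls(df, response_kind=response_kind)
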