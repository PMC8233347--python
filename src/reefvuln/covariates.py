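"""Covariate preparation and collinearity screening.

Rugosity (seabed slope) derivation from bathymetry, block-mean
regridding to a common resolution, z-score standardization with
reusable transform parameters, the cover-rescaling rule for records
reported as a fraction of total coral cover, and the stepwise
correlation / GVIF screening that decides which covariates enter the
models (variables are removed one at a time while any df-corrected
GVIF exceeds 3 or any pairwise |Pearson r| exceeds 0.70).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observations import ObservationSet
from .stack import CovariateStack


# ---------------------------------------------------------------- rasters

def derive_rugosity(bathymetry: np.ndarray, cell_size: float = 1.0) -> np.ndarray:
    """Seabed slope (degrees) from a bathymetry raster, Horn's method.

    Horn's 3x3 finite-difference gradient; edge cells reuse their own
    value for neighbours outside the raster (edge replication), and
    missing neighbours are replaced by the center value so isolated
    gaps do not propagate.  ``cell_size`` is the cell side in the same
    units as the bathymetry's horizontal coordinates.
    """
    b = np.asarray(bathymetry, dtype=float)
    if b.ndim != 2 or b.shape[0] < 3 or b.shape[1] < 3:
        raise ValueError("bathymetry must be a 2-D raster with at least 3x3 cells")
    if np.isnan(b).all():
        raise ValueError("bathymetry raster is entirely missing")

    pad = np.pad(b, 1, mode="edge")

    def shift(di: int, dj: int) -> np.ndarray:
        s = pad[1 + di : 1 + di + b.shape[0], 1 + dj : 1 + dj + b.shape[1]]
        return np.where(np.isnan(s), b, s)

    nw, n_, ne = shift(-1, -1), shift(-1, 0), shift(-1, 1)
    w_, e_ = shift(0, -1), shift(0, 1)
    sw, s_, se = shift(1, -1), shift(1, 0), shift(1, 1)

    gx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8.0 * cell_size)
    gy = ((sw + 2 * s_ + se) - (nw + 2 * n_ + ne)) / (8.0 * cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    slope[np.isnan(b)] = np.nan
    return slope


def regrid(raster: np.ndarray, source_resolution: float, target_resolution: float) -> np.ndarray:
    """Block-mean aggregation onto a coarser lattice (missing-aware).

    The coarsening factor must be a whole number of source cells;
    asking for a finer target raises (aggregation cannot invent
    detail).  Ragged edges are padded with NaN, and an all-missing
    block stays NaN.
    """
    r = np.asarray(raster, dtype=float)
    ratio = target_resolution / source_resolution
    if ratio < 1 - 1e-9:
        raise ValueError(
            f"target resolution {target_resolution} is finer than source {source_resolution}"
        )
    f = int(round(ratio))
    if abs(ratio - f) > 1e-9:
        raise ValueError(f"coarsening factor {ratio} is not a whole number of source cells")
    if f == 1:
        return r.copy()
    ni = -(-r.shape[0] // f) * f
    nj = -(-r.shape[1] // f) * f
    padded = np.full((ni, nj), np.nan)
    padded[: r.shape[0], : r.shape[1]] = r
    blocks = padded.reshape(ni // f, f, nj // f, f)
    with np.errstate(invalid="ignore"):
        return np.nanmean(blocks, axis=(1, 3))


@dataclass
class Standardization:
    """Per-variable means/sds recorded at standardization time.

    Applying the same transform to a future stack keeps scenario shifts
    interpretable (a +3 degC shift stays visible as +3/sd).
    """

    means: dict[str, float]
    sds: dict[str, float]

    def apply(self, stack: CovariateStack) -> CovariateStack:
        out = stack.copy()
        for name in self.means:
            if name not in out:
                raise KeyError(f"standardization has no matching layer {name!r} in stack")
            out.layers[name] = (out.layers[name] - self.means[name]) / self.sds[name]
        return out

    def transform_values(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for name in df.columns:
            if name in self.means:
                out[name] = (df[name] - self.means[name]) / self.sds[name]
        return out


def standardize(stack: CovariateStack) -> tuple[CovariateStack, Standardization]:
    """z-score every layer over sea cells; returns the new stack and the
    recorded transform (population sd, ddof=0)."""
    means, sds = {}, {}
    for name in stack.names:
        v = stack.sea_values(name)
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError(f"covariate {name!r} has fewer than 2 non-missing sea values")
        m, s = float(v.mean()), float(v.std())
        if s == 0:
            raise ValueError(f"covariate {name!r} has zero variance; cannot standardize")
        means[name], sds[name] = m, s
    params = Standardization(means, sds)
    return params.apply(stack), params


def rescale_cover(species_fraction_of_coral, total_coral_cover):
    """Percent of total benthos from a fraction-of-coral record.

    Species cover reported as a fraction of total coral cover is
    multiplied by the total coral cover (percent of benthos) to express
    it on the common percent-of-benthos scale.
    """
    frac = np.asarray(species_fraction_of_coral, dtype=float)
    total = np.asarray(total_coral_cover, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("species fraction must lie in [0, 1]")
    if np.any((total < 0) | (total > 100)):
        raise ValueError("total coral cover must lie in [0, 100] percent")
    out = frac * total
    return out if out.ndim else float(out)


# ---------------------------------------------------------- collinearity

def _site_design(stack: CovariateStack, sites: ObservationSet | pd.DataFrame,
                 names: list[str] | None = None) -> pd.DataFrame:
    if isinstance(sites, ObservationSet):
        lat, lon = sites.lat, sites.lon
    else:
        lat, lon = sites["lat"].to_numpy(), sites["lon"].to_numpy()
    return stack.at_sites(lat, lon, names)


def pearson_matrix(stack: CovariateStack, sites, names: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation of covariates at observation sites."""
    X = _site_design(stack, sites, names).dropna()
    if len(X) < 3:
        raise ValueError(f"need at least 3 complete site rows, got {len(X)}")
    return X.corr(method="pearson")


def gvif(stack: CovariateStack, sites, names: list[str] | None = None) -> pd.DataFrame:
    """Generalized variance inflation factors at observation sites.

    For 1-df continuous variables GVIF equals the ordinary VIF,
    1/(1 - R^2) from regressing the variable on all the others (with
    intercept).  The df-corrected value GVIF^(1/(2 df)) is reported
    alongside so thresholds are comparable across terms.  Perfect
    collinearity yields inf rather than an exception.
    """
    X = _site_design(stack, sites, names).dropna()
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("GVIF needs at least 2 variables")
    rows = []
    for name in cols:
        y = X[name].to_numpy(dtype=float)
        others = X.drop(columns=name).to_numpy(dtype=float)
        A = np.column_stack([np.ones(len(X)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        tss = ((y - y.mean()) ** 2).sum()
        rss = (resid**2).sum()
        r2 = 0.0 if tss == 0 else 1.0 - rss / tss
        v = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"variable": name, "gvif": v, "df": 1, "gvif_corrected": np.sqrt(v)})
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class ScreeningReport:
    """Audit trail of stepwise collinearity screening."""

    correlation_matrix: pd.DataFrame
    gvif_table: pd.DataFrame
    removed: list[tuple[str, str, float]] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["Covariate screening audit", "========================="]
        for name, reason, value in self.removed:
            lines.append(f"removed {name}: {reason} = {value:.4g}")
        lines.append(f"retained: {', '.join(self.retained) if self.retained else '(none)'}")
        return "\n".join(lines)


def screen_covariates(
    stack: CovariateStack,
    sites,
    names: list[str] | None = None,
    gvif_threshold: float = 3.0,
    corr_threshold: float = 0.70,
) -> ScreeningReport:
    """Stepwise removal until all corrected GVIF and |r| thresholds hold.

    At each step the single worst offender is removed and everything is
    recomputed: first the variable with the highest corrected GVIF
    above ``gvif_threshold``; if none, the member of the highest-|r|
    pair above ``corr_threshold`` with the larger mean |r| to all other
    variables.  Ties break alphabetically for a deterministic audit
    trail.  An empty retained set is a valid outcome.
    """
    X0 = _site_design(stack, sites, names).dropna()
    if X0.shape[1] < 2:
        raise ValueError("screening needs at least 2 candidate variables")
    initial_corr = X0.corr(method="pearson")

    current = sorted(X0.columns)
    removed: list[tuple[str, str, float]] = []
    while len(current) >= 2:
        sub = X0[current]
        gtab = _gvif_from_design(sub)
        over = gtab[gtab["gvif_corrected"] > gvif_threshold]
        if len(over):
            # highest corrected GVIF first; ties alphabetical (index is sorted)
            name = over["gvif_corrected"].idxmax()
            removed.append((name, "gvif_corrected", float(gtab.loc[name, "gvif_corrected"])))
            current.remove(name)
            continue
        corr = sub.corr(method="pearson")
        absr = corr.abs().to_numpy()
        np.fill_diagonal(absr, 0.0)
        if absr.max() > corr_threshold:
            i, j = np.unravel_index(np.argmax(absr), absr.shape)
            a, b = corr.columns[i], corr.columns[j]
            mean_a = absr[i].sum() / (len(current) - 1)
            mean_b = absr[j].sum() / (len(current) - 1)
            if mean_a > mean_b or (mean_a == mean_b and a < b):
                name = a
            else:
                name = b
            removed.append((name, "correlation", float(corr.loc[a, b])))
            current.remove(name)
            continue
        break

    final_gvif = (
        _gvif_from_design(X0[current]) if len(current) >= 2 else pd.DataFrame(
            columns=["gvif", "df", "gvif_corrected"]
        )
    )
    return ScreeningReport(
        correlation_matrix=initial_corr,
        gvif_table=final_gvif,
        removed=removed,
        retained=current,
    )


def _gvif_from_design(X: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for name in X.columns:
        y = X[name].to_numpy(dtype=float)
        A = np.column_stack([np.ones(len(X)), X.drop(columns=name).to_numpy(dtype=float)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = ((y - A @ coef) ** 2).sum()
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 0.0 if tss == 0 else 1.0 - rss / tss
        v = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"variable": name, "gvif": v, "df": 1, "gvif_corrected": np.sqrt(v)})
    return pd.DataFrame(rows).set_index("variable")
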