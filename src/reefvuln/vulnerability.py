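"""Bleaching-vulnerability mapping and hotspot classification.

The occurrence, cover and bleaching surfaces are each standardized by
their maximum (so none dominates the overlap), multiplied cell-wise
into a vulnerability score in [0, 1], and classified into low /
intermediate / hotspot by the quartiles of the current projection's
distribution (hotspot = upper-quartile class).  Thresholds are frozen
from the current scenario and reused for future scenarios so class
areas are comparable; fixed literature thresholds (0.21, 0.78) are
available as an override.  Kernel density estimates compare the value
distributions across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .grid import SpatialGrid
from .predict import ProbabilitySurface

CLASS_NAMES = ("low", "intermediate", "hotspot")
PAPER_THRESHOLDS = (0.21, 0.78)


@dataclass
class VulnerabilitySurface:
    """Product of three max-standardized surfaces, in [0, 1] on sea."""

    grid: SpatialGrid
    scenario: str
    values: np.ndarray
    thresholds: tuple[float, float] | None = None
    class_map: np.ndarray | None = None  # int codes 0/1/2, -1 on land

    def sea_values(self) -> np.ndarray:
        return self.values[self.grid.mask]


@dataclass
class AreaReport:
    """Per-class sea-cell counts and area percentages for one scenario."""

    scenario: str
    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(CLASS_NAMES),
                "count": [self.counts[c] for c in CLASS_NAMES],
                "percent": [self.percentages[c] for c in CLASS_NAMES],
            }
        ).assign(scenario=self.scenario)


def max_standardize(surface: ProbabilitySurface, maximum: float | None = None) -> ProbabilitySurface:
    """Divide a surface by its maximum over sea cells (result in [0, 1]).

    ``maximum`` overrides the divisor — used to scale future-scenario
    surfaces by the current scenario's maximum so scenarios stay
    comparable.  An all-zero surface has no scale and raises.
    """
    sea = surface.sea_values()
    mx = float(np.nanmax(sea)) if maximum is None else float(maximum)
    if not np.isfinite(mx) or mx <= 0:
        raise ValueError("surface maximum must be positive to max-standardize")
    return surface.copy_with(values=surface.values / mx)


def overlap(
    occ: ProbabilitySurface,
    cover: ProbabilitySurface,
    bleach: ProbabilitySurface,
    tol: float = 1e-8,
    check_standardized: bool = True,
) -> VulnerabilitySurface:
    """Cell-wise product of the three max-standardized surfaces.

    All three must share grid and scenario and have sea maximum 1
    (i.e. already max-standardized); the product is 0 wherever any
    factor is 0 and lies in [0, 1].  ``check_standardized=False``
    skips the max-equals-1 check: future-scenario surfaces scaled by
    the *current* scenario's maximum legitimately peak away from 1.
    """
    for s in (cover, bleach):
        if not s.grid.same_lattice(occ.grid):
            raise ValueError("surfaces are on different grids")
        if s.scenario != occ.scenario:
            raise ValueError(
                f"scenario mismatch: {s.scenario!r} vs {occ.scenario!r}"
            )
    if check_standardized:
        for s, name in ((occ, "occurrence"), (cover, "cover"), (bleach, "bleaching")):
            mx = float(np.nanmax(s.sea_values()))
            if abs(mx - 1.0) > tol:
                raise ValueError(f"{name} surface is not max-standardized (max = {mx:.6g})")
    return VulnerabilitySurface(
        grid=occ.grid,
        scenario=occ.scenario,
        values=occ.values * cover.values * bleach.values,
    )


def quartile_thresholds(
    vuln: VulnerabilitySurface,
    override: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """(q_low, q_high) = 25th/75th percentiles of the sea-cell values
    (linear-interpolation percentile convention), or a verbatim
    override such as the fixed literature bounds (0.21, 0.78)."""
    if override is not None:
        lo, hi = float(override[0]), float(override[1])
        if lo > hi:
            raise ValueError("thresholds must satisfy q_low <= q_high")
        return (lo, hi)
    sea = vuln.sea_values()
    sea = sea[~np.isnan(sea)]
    if sea.size < 4:
        raise ValueError(f"need at least 4 sea cells for quartiles, got {sea.size}")
    q_low, q_high = np.percentile(sea, [25.0, 75.0], method="linear")
    return (float(q_low), float(q_high))


def classify(
    vuln: VulnerabilitySurface,
    thresholds: tuple[float, float],
) -> tuple[VulnerabilitySurface, AreaReport]:
    """Classify cells into low < q_low <= intermediate < q_high <= hotspot.

    Half-open intervals close the gaps the printed class bounds would
    leave; percentages are over sea cells and sum to 100.
    """
    q_low, q_high = thresholds
    if q_low > q_high:
        raise ValueError(f"inverted thresholds: {thresholds}")
    v = vuln.values
    cls = np.full(vuln.grid.shape, -1, dtype=int)
    sea = vuln.grid.mask
    cls[sea & (v < q_low)] = 0
    cls[sea & (v >= q_low) & (v < q_high)] = 1
    cls[sea & (v >= q_high)] = 2
    counts = {name: int((cls == i).sum()) for i, name in enumerate(CLASS_NAMES)}
    total = sum(counts.values())
    pct = {name: 100.0 * c / total for name, c in counts.items()}
    out = VulnerabilitySurface(
        grid=vuln.grid,
        scenario=vuln.scenario,
        values=v,
        thresholds=(float(q_low), float(q_high)),
        class_map=cls,
    )
    return out, AreaReport(scenario=vuln.scenario, counts=counts, percentages=pct)


def class_area_change(current: AreaReport, future: AreaReport) -> pd.DataFrame:
    """Percent change of each class's area between scenarios,
    100 * (future - current) / current; a class empty in the current
    scenario is flagged undefined rather than raising."""
    if current.total != future.total:
        raise ValueError("area reports cover different numbers of sea cells")
    rows = []
    for name in CLASS_NAMES:
        c, f = current.counts[name], future.counts[name]
        if c == 0:
            rows.append({"class": name, "percent_change": np.nan, "undefined": True})
        else:
            rows.append(
                {"class": name, "percent_change": 100.0 * (f - c) / c, "undefined": False}
            )
    return pd.DataFrame(rows)


@dataclass
class KdeComparison:
    """Gaussian-kernel densities of cell values per scenario on a
    common lattice, plus percent-change summaries vs the first
    (reference) scenario."""

    eval_grid: np.ndarray
    densities: dict[str, np.ndarray]
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def kde_compare(
    surfaces: list,
    bandwidth: str | float = "scott",
    n_points: int = 512,
    thresholds: tuple[float, float] | None = None,
) -> KdeComparison:
    """Compare the value distributions of >= 2 surfaces on one grid.

    The first surface is the reference (current scenario).  Reports
    the percent change of the distribution mean and, when thresholds
    are given, of the mass in each vulnerability class.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces to compare")
    g0 = surfaces[0].grid
    vals = {}
    for s in surfaces:
        if not s.grid.same_lattice(g0):
            raise ValueError("surfaces are on different grids")
        v = s.sea_values()
        v = v[~np.isnan(v)]
        if v.size == 0:
            raise ValueError(f"surface {s.scenario!r} is empty")
        vals[s.scenario] = v

    all_v = np.concatenate(list(vals.values()))
    spread = all_v.std() or 1.0
    lo = all_v.min() - 3 * spread
    hi = all_v.max() + 3 * spread
    xs = np.linspace(lo, hi, n_points)
    densities = {}
    for name, v in vals.items():
        if v.std() == 0:
            # degenerate sample: represent as a narrow Gaussian spike
            bw = 1e-3 * (spread or 1.0)
            d = np.exp(-0.5 * ((xs - v[0]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
        else:
            d = gaussian_kde(v, bw_method=bandwidth)(xs)
        densities[name] = d

    ref_name = surfaces[0].scenario
    ref = vals[ref_name]
    rows = []
    for s in surfaces[1:]:
        v = vals[s.scenario]
        row = {
            "scenario": s.scenario,
            "mean_percent_change": 100.0 * (v.mean() - ref.mean()) / ref.mean()
            if ref.mean() != 0
            else np.nan,
        }
        if thresholds is not None:
            q_low, q_high = thresholds
            for name, (a, b) in {
                "low": (-np.inf, q_low),
                "intermediate": (q_low, q_high),
                "hotspot": (q_high, np.inf),
            }.items():
                m_ref = float(np.mean((ref >= a) & (ref < b)))
                m_fut = float(np.mean((v >= a) & (v < b)))
                row[f"{name}_mass_change"] = (
                    100.0 * (m_fut - m_ref) / m_ref if m_ref > 0 else np.nan
                )
        rows.append(row)
    return KdeComparison(eval_grid=xs, densities=densities, summary=pd.DataFrame(rows))
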