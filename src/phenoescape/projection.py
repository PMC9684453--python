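"""Gridded projection of fitted phenology onto climate surfaces.

Posterior-mean coefficients are pushed through aligned spring-temperature
and elevation grids to produce predicted day-of-year surfaces (first
flowering for wildflowers, leaf-out for canopy trees), spring light
windows (LOD − FFD, days; positive when flowering precedes leaf-out),
scenario differences (ΔWindow = future − current, so positive means the
light window lengthens), deciduous-forest masking at a 1% cover
threshold, and continental mean ± s.d. summaries over unmasked cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import AlignmentError, ClimateGrid
from .results import ParameterSummary


@dataclass
class PhenologySurface:
    """Predicted DOY on a grid for one stratum/scenario."""

    grid: ClimateGrid  # variable stays "spring_temp"-shaped; values are DOY
    stratum: str
    continent: str
    scenario: str


@dataclass
class WindowMap:
    """Spring-light-window duration (or ΔWindow) in days on a grid."""

    grid: ClimateGrid
    scenario: str  # "current" | "future" | "delta"
    masked: bool = False


def predict_surface(
    summaries: dict[str, ParameterSummary],
    temp: ClimateGrid,
    elev: ClimateGrid,
    stratum: str = "",
    continent: str = "",
) -> PhenologySurface:
    """Community-level posterior-mean DOY prediction per cell:
    (beta0 + mean_j alpha_j) + beta1·T + beta2·E.

    ``summaries`` must carry community_intercept, beta1 and beta2 (the
    species offsets are aggregated as their arithmetic mean, which is what
    community_intercept already includes).
    """
    temp.assert_aligned(elev)
    needed = ("community_intercept", "beta1", "beta2")
    missing = [k for k in needed if k not in summaries]
    if missing:
        raise KeyError(f"missing parameter summaries: {missing}")
    b0 = summaries["community_intercept"].mean
    b1 = summaries["beta1"].mean
    b2 = summaries["beta2"].mean
    valid = temp.mask_valid & elev.mask_valid
    vals = np.full(temp.shape, temp.nodata, dtype=np.float64)
    vals[valid] = b0 + b1 * temp.values[valid].astype(np.float64) + b2 * elev.values[
        valid
    ].astype(np.float64)
    grid = temp.with_values(vals, variable="spring_temp", scenario=temp.scenario)
    return PhenologySurface(grid, stratum=stratum, continent=continent,
                            scenario=temp.scenario)


def light_window(ffd: PhenologySurface, lod: PhenologySurface) -> WindowMap:
    """Spring light window = LOD − FFD (days), cellwise.

    Positive where wildflower flowering precedes canopy closure; negative
    where leaf-out comes first.  Both surfaces must share scenario and
    alignment.
    """
    if ffd.scenario != lod.scenario:
        raise ValueError(
            f"scenario mismatch: FFD {ffd.scenario!r} vs LOD {lod.scenario!r}"
        )
    ffd.grid.assert_aligned(lod.grid)
    valid = ffd.grid.mask_valid & lod.grid.mask_valid
    vals = np.full(ffd.grid.shape, ffd.grid.nodata, dtype=np.float64)
    vals[valid] = (
        lod.grid.values[valid].astype(np.float64)
        - ffd.grid.values[valid].astype(np.float64)
    )
    return WindowMap(ffd.grid.with_values(vals), scenario=ffd.scenario)


def delta_window(
    current: WindowMap, future: WindowMap, future_minus_current: bool = True
) -> WindowMap:
    """ΔWindow = future − current (days); positive = window lengthens.

    Set ``future_minus_current=False`` to flip the sign convention.
    Masking state must match between the two maps.
    """
    if current.masked != future.masked:
        raise ValueError("mask state differs between current and future maps")
    current.grid.assert_aligned(future.grid)
    valid = current.grid.mask_valid & future.grid.mask_valid
    vals = np.full(current.grid.shape, current.grid.nodata, dtype=np.float64)
    diff = (
        future.grid.values[valid].astype(np.float64)
        - current.grid.values[valid].astype(np.float64)
    )
    vals[valid] = diff if future_minus_current else -diff
    return WindowMap(
        current.grid.with_values(vals), scenario="delta", masked=current.masked
    )


def mask_forest(
    obj: WindowMap | PhenologySurface,
    forest: ClimateGrid,
    threshold: float = 0.01,
):
    """Set cells with deciduous-forest fraction below ``threshold`` to
    nodata.  Idempotent; the default 1% threshold reproduces the masking
    applied to projection maps."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if forest.variable != "forest_fraction":
        raise ValueError("mask grid must be a forest_fraction grid")
    grid = obj.grid
    grid.assert_aligned(forest)
    keep = forest.mask_valid & (forest.values >= threshold)
    vals = np.where(keep, grid.values, np.float32(grid.nodata))
    new = grid.with_values(vals)
    if isinstance(obj, WindowMap):
        return WindowMap(new, scenario=obj.scenario, masked=True)
    return PhenologySurface(new, stratum=obj.stratum, continent=obj.continent,
                            scenario=obj.scenario)


def continental_summary(wmap: WindowMap | ClimateGrid) -> tuple[float, float]:
    """Mean ± population s.d. over unmasked cells (equal cell weighting)."""
    grid = wmap.grid if isinstance(wmap, WindowMap) else wmap
    vals = grid.values[grid.mask_valid].astype(np.float64)
    if vals.size == 0:
        raise ValueError("fully masked map: no cells to summarise")
    return float(vals.mean()), float(vals.std(ddof=0))


def scenario_delta_summary(
    current_temp: ClimateGrid,
    future_temp: ClimateGrid,
    mask: ClimateGrid | None = None,
    threshold: float = 0.01,
) -> tuple[float, float]:
    """Mean ± s.d. of the cellwise future − current temperature change,
    optionally restricted to forest-masked cells."""
    current_temp.assert_aligned(future_temp)
    valid = current_temp.mask_valid & future_temp.mask_valid
    diff = np.full(current_temp.shape, current_temp.nodata, dtype=np.float64)
    diff[valid] = (
        future_temp.values[valid].astype(np.float64)
        - current_temp.values[valid].astype(np.float64)
    )
    grid = current_temp.with_values(diff)
    wmap = WindowMap(grid, scenario="delta")
    if mask is not None:
        wmap = mask_forest(wmap, mask, threshold=threshold)
    return continental_summary(wmap)
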