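"""Raster grids for climate, elevation and land cover.

A :class:`ClimateGrid` is a 2-D, north-up, cell-centre-registered raster
(WGS84 decimal degrees) with an affine geotransform ``(x0, y0, dx, dy)``:
the centre of cell ``[i, j]`` is at ``(x0 + j*dx, y0 + i*dy)`` with
``dy < 0`` (rows run north to south).  Grids that are combined
arithmetically must share shape and transform exactly.

Persistence is NetCDF (classic format via the SciPy backend); float32
payloads round-trip bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import xarray as xr

VARIABLES = ("tmean_month", "spring_temp", "elevation", "forest_fraction")
SCENARIOS = ("current", "future", "none")

NODATA = np.float32(-9999.0)


class AlignmentError(ValueError):
    """Two grids that must share shape/transform do not."""


@dataclass
class ClimateGrid:
    """A 2-D raster with geotransform metadata.

    ``values`` is float32, row-major, north-up; ``nodata`` cells carry the
    sentinel.  ``variable`` names the physical quantity; monthly temperature
    stacks set ``month`` (1–12); scenario labels distinguish current-climate
    from end-of-century grids.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float]  # (x0, y0, dx, dy), dy < 0
    variable: str = "spring_temp"
    nodata: float = float(NODATA)
    crs_label: str = "EPSG:4326"
    month: int | None = None
    scenario: str = "none"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.dtype not in (np.dtype(np.float32), np.dtype(np.float64)):
            v = v.astype(np.float32)
        self.values = v
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.variable not in VARIABLES:
            raise ValueError(f"variable {self.variable!r} not in {VARIABLES}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario {self.scenario!r} not in {SCENARIOS}")
        if self.month is not None and not 1 <= int(self.month) <= 12:
            raise ValueError(f"month {self.month} outside 1..12")
        if self.variable == "forest_fraction":
            v = self.values[self.mask_valid]
            if v.size and ((v < 0) | (v > 1)).any():
                raise ValueError("forest_fraction values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def mask_valid(self) -> np.ndarray:
        """Boolean mask of cells that are not nodata and finite."""
        return np.isfinite(self.values) & (self.values != np.float32(self.nodata))

    def lat_lon(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre latitude (per row) and longitude (per column)."""
        x0, y0, dx, dy = self.transform
        ny, nx = self.shape
        return y0 + dy * np.arange(ny), x0 + dx * np.arange(nx)

    def assert_aligned(self, other: "ClimateGrid") -> None:
        if self.shape != other.shape or not np.allclose(
            self.transform, other.transform, rtol=0, atol=0
        ):
            raise AlignmentError(
                f"grids not aligned: shape {self.shape} vs {other.shape}, "
                f"transform {self.transform} vs {other.transform}"
            )

    def with_values(self, values: np.ndarray, **meta) -> "ClimateGrid":
        """A copy carrying new values (and optionally new metadata)."""
        return replace(self, values=np.asarray(values), **meta)


def write_grid(grid: ClimateGrid, path: str | Path) -> None:
    """Persist a grid (or use :func:`write_monthly_stack` for 12 months)."""
    _dataset_from_grids([grid]).to_netcdf(path, engine="scipy")


def write_monthly_stack(grids: Sequence[ClimateGrid], path: str | Path) -> None:
    """Persist a stack of monthly grids sharing shape/transform."""
    for g in grids[1:]:
        grids[0].assert_aligned(g)
    _dataset_from_grids(grids).to_netcdf(path, engine="scipy")


def read_grid(path: str | Path) -> ClimateGrid:
    """Read a single-layer NetCDF grid written by :func:`write_grid`."""
    out = read_grids(path)
    if len(out) != 1:
        raise ValueError(f"{path} holds {len(out)} layers; use read_grids")
    return out[0]


def read_grids(path: str | Path) -> list[ClimateGrid]:
    """Read all layers (e.g. a 12-month stack) from a NetCDF file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        grids = []
        for name in ds.data_vars:
            da = ds[name]
            attrs = da.attrs
            grids.append(
                ClimateGrid(
                    values=np.asarray(da.values),
                    transform=tuple(float(t) for t in attrs["transform"]),
                    variable=str(attrs["variable"]),
                    nodata=float(attrs["nodata"]),
                    crs_label=str(attrs.get("crs_label", "EPSG:4326")),
                    month=int(attrs["month"]) if "month" in attrs and int(attrs["month"]) > 0 else None,
                    scenario=str(attrs.get("scenario", "none")),
                )
            )
    return grids


def _dataset_from_grids(grids: Sequence[ClimateGrid]) -> xr.Dataset:
    data = {}
    for k, g in enumerate(grids):
        name = g.variable if len(grids) == 1 else f"{g.variable}_{k:02d}"
        lat, lon = g.lat_lon()
        da = xr.DataArray(
            g.values,
            dims=("lat", "lon"),
            coords={"lat": lat.astype(np.float64), "lon": lon.astype(np.float64)},
            attrs={
                "transform": [float(t) for t in g.transform],
                "variable": g.variable,
                "nodata": float(g.nodata),
                "crs_label": g.crs_label,
                "month": int(g.month) if g.month is not None else -1,
                "scenario": g.scenario,
            },
        )
        data[name] = da
    return xr.Dataset(data)
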