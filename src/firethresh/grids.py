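"""Gridded climate containers and NetCDF plumbing.

A "climate grid" is an :class:`xarray.DataArray` with dims ``(time, lat, lon)``,
a declared ``units`` attribute (``degC``, ``K``, ``kPa`` or ``%``) and a no-leap
time axis described by the attributes ``start_year``, ``n_years`` and
``steps_per_day``.  The time coordinate is the integer step index; operations
never mix grids whose axes or units disagree.

NetCDF files are written in classic (NetCDF-3) format through xarray's scipy
backend, with CF-style dimension names and units attributes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import xarray as xr

from .timeaxis import DAYS_PER_YEAR

VALID_UNITS = {"degC", "K", "kPa", "%"}


class UnitsError(ValueError):
    """Raised when grid units are missing, unknown or mixed."""


class GridMismatchError(ValueError):
    """Raised when two grids do not share spatial/temporal axes."""


def make_grid(
    values: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
    *,
    name: str,
    units: str,
    start_year: int,
    steps_per_day: int,
) -> xr.DataArray:
    """Wrap a (time, lat, lon) array as a climate grid with a no-leap axis."""
    if units not in VALID_UNITS:
        raise UnitsError(f"unknown units {units!r}; expected one of {sorted(VALID_UNITS)}")
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected 3-D (time, lat, lon) array, got shape {values.shape}")
    n_time = values.shape[0]
    steps_per_year = DAYS_PER_YEAR * steps_per_day
    if n_time % steps_per_year != 0:
        raise ValueError(
            f"time length {n_time} is not a whole number of {steps_per_year}-step years"
        )
    da = xr.DataArray(
        values,
        dims=("time", "lat", "lon"),
        coords={
            "time": np.arange(n_time),
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
        },
        name=name,
        attrs={
            "units": units,
            "calendar": "noleap",
            "start_year": int(start_year),
            "n_years": n_time // steps_per_year,
            "steps_per_day": int(steps_per_day),
        },
    )
    return da


def units_of(grid: xr.DataArray) -> str:
    units = grid.attrs.get("units")
    if units is None:
        raise UnitsError(f"grid {grid.name!r} has no units attribute")
    return units


def require_units(grid: xr.DataArray, expected: str) -> None:
    units = units_of(grid)
    if units != expected:
        raise UnitsError(f"grid {grid.name!r} has units {units!r}, expected {expected!r}")


def check_same_axes(a: xr.DataArray, b: xr.DataArray) -> None:
    """Reject grids that do not share spatial and temporal axes exactly."""
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    for dim in ("time", "lat", "lon"):
        if not np.array_equal(a.coords[dim].values, b.coords[dim].values):
            raise GridMismatchError(f"{dim} axes differ between grids")
    for key in ("steps_per_day", "start_year"):
        if a.attrs.get(key) != b.attrs.get(key):
            raise GridMismatchError(
                f"attribute {key!r} differs: {a.attrs.get(key)} vs {b.attrs.get(key)}"
            )


def check_same_spatial(a: xr.DataArray, b: xr.DataArray) -> None:
    for dim in ("lat", "lon"):
        if dim in a.dims and dim in b.dims:
            if not np.array_equal(a.coords[dim].values, b.coords[dim].values):
                raise GridMismatchError(f"{dim} axes differ between grids")


def years_of(grid: xr.DataArray) -> list[int]:
    start = int(grid.attrs["start_year"])
    return list(range(start, start + int(grid.attrs["n_years"])))


def write_netcdf(grid: xr.DataArray, path: str | Path) -> None:
    ds = grid.to_dataset(name=grid.name or "variable")
    ds.attrs.update(grid.attrs)
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path: str | Path, var: str | None = None) -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        if var is None:
            data_vars = list(ds.data_vars)
            if len(data_vars) != 1:
                raise ValueError(f"{path} holds {data_vars}; pass var= to choose one")
            var = data_vars[0]
        da = ds[var].load()
    # scipy backend keeps dataset attrs separate from variable attrs
    for key in ("units", "calendar", "start_year", "n_years", "steps_per_day"):
        if key not in da.attrs and key in ds.attrs:
            da.attrs[key] = ds.attrs[key]
    for key in ("start_year", "n_years", "steps_per_day"):
        if key in da.attrs:
            da.attrs[key] = int(da.attrs[key])
    return da
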