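"""Daily-maximum vapour pressure deficit from sub-daily temperature and humidity.

VPD is the gap between the saturation vapour pressure at air temperature and
the actual vapour pressure, here in kPa.  The daily value used throughout the
package is computed *at the time of the daily maximum air temperature*: for
each cell-day the sub-daily step with the highest temperature is located and
VPD is evaluated from the temperature and humidity at that step — not as the
maximum of pointwise VPD over the day, which can differ when the driest air
does not coincide with the warmest hour.

Saturation vapour pressure uses the Magnus–Tetens form over liquid water,

    e_s(t) = 0.6108 * exp(17.27 t / (t + 237.3))   [kPa, t in degC]

a standard choice in fuel-moisture work; it is isolated in a single function
so an alternative curve can be swapped in.
"""

from __future__ import annotations

import logging

import numpy as np
import xarray as xr

from .grids import UnitsError, check_same_axes, make_grid, units_of

logger = logging.getLogger(__name__)

_T_MIN, _T_MAX = -90.0, 60.0
_RH_HARD_MAX = 100.5  # % — above this, inputs are rejected rather than clamped


def saturation_vapour_pressure(t: np.ndarray | float) -> np.ndarray | float:
    """Magnus–Tetens saturation vapour pressure (kPa) at air temperature t (degC)."""
    t = np.asarray(t, dtype=float)
    if np.any((t < _T_MIN) | (t > _T_MAX)):
        bad = t[(t < _T_MIN) | (t > _T_MAX)]
        raise ValueError(
            f"temperature outside physical range [{_T_MIN}, {_T_MAX}] degC: "
            f"e.g. {bad.flat[0]:.1f}"
        )
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return es if es.ndim else float(es)


def vpd_from_dewpoint(t: np.ndarray | float, t_d: np.ndarray | float) -> np.ndarray | float:
    """VPD (kPa) from air temperature and dew point (degC); requires t_d <= t."""
    t = np.asarray(t, dtype=float)
    t_d = np.asarray(t_d, dtype=float)
    if np.any(t_d > t):
        n_bad = int(np.sum(t_d > t))
        raise ValueError(
            f"dew point exceeds air temperature at {n_bad} point(s) — "
            "supersaturated input is not physical for this calculation"
        )
    out = saturation_vapour_pressure(t) - saturation_vapour_pressure(t_d)
    return out if np.ndim(out) else float(out)


def vpd_from_rh(t: np.ndarray | float, rh: np.ndarray | float) -> np.ndarray | float:
    """VPD (kPa) from air temperature (degC) and relative humidity (%).

    RH marginally above 100% (<= 100.5, from input rounding) is clamped to
    saturation with a logged count; larger values or negatives are rejected.
    """
    t = np.asarray(t, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0) or np.any(rh > _RH_HARD_MAX):
        raise ValueError(f"relative humidity outside [0, {_RH_HARD_MAX}] %")
    n_clamped = int(np.sum(rh > 100.0))
    if n_clamped:
        logger.info("clamped %d RH value(s) in (100, %.1f]%% to saturation", n_clamped, _RH_HARD_MAX)
        rh = np.minimum(rh, 100.0)
    out = saturation_vapour_pressure(t) * (1.0 - rh / 100.0)
    return out if np.ndim(out) else float(out)


def _as_celsius(grid: xr.DataArray) -> np.ndarray:
    units = units_of(grid)
    if units == "degC":
        return grid.values
    if units == "K":
        return grid.values - 273.15
    raise UnitsError(f"temperature grid has units {units!r}; expected degC or K")


def daily_max_vpd(
    t_subdaily: xr.DataArray,
    humidity_subdaily: xr.DataArray,
    humidity_kind: str,
) -> xr.DataArray:
    """Daily VPD grid (kPa) at the time of each cell-day's maximum temperature.

    ``humidity_kind`` is ``"dewpoint"`` (grid in degC or K) or ``"rh"`` (grid
    in %).  Ties in the daily temperature maximum resolve to the earliest
    step.  A day whose temperature is missing at every step is an error;
    steps with missing temperature are ignored when locating the maximum.
    """
    if humidity_kind not in ("dewpoint", "rh"):
        raise ValueError(f"humidity_kind must be 'dewpoint' or 'rh', got {humidity_kind!r}")
    check_same_axes(t_subdaily, humidity_subdaily)
    if humidity_kind == "rh" and units_of(humidity_subdaily) != "%":
        raise UnitsError("rh humidity grid must carry units '%'")

    spd = int(t_subdaily.attrs["steps_per_day"])
    t = _as_celsius(t_subdaily)
    n_time, n_lat, n_lon = t.shape
    n_days = n_time // spd
    t_days = t.reshape(n_days, spd, n_lat, n_lon)

    masked = np.where(np.isnan(t_days), -np.inf, t_days)
    if np.any(np.all(~np.isfinite(masked), axis=1)):
        raise ValueError("at least one cell-day has temperature missing at every step")
    # np.argmax returns the first maximiser: earliest step wins on ties
    arg = np.argmax(masked, axis=1)

    take = lambda arr: np.take_along_axis(
        arr.reshape(n_days, spd, n_lat, n_lon), arg[:, None, :, :], axis=1
    )[:, 0, :, :]
    t_at_max = take(t)
    if humidity_kind == "dewpoint":
        h_at_max = take(_as_celsius(humidity_subdaily))
        vpd = vpd_from_dewpoint(t_at_max, h_at_max)
    else:
        h_at_max = take(humidity_subdaily.values)
        vpd = vpd_from_rh(t_at_max, h_at_max)

    return make_grid(
        np.asarray(vpd),
        lats=t_subdaily.coords["lat"].values,
        lons=t_subdaily.coords["lon"].values,
        name="vpd",
        units="kPa",
        start_year=int(t_subdaily.attrs["start_year"]),
        steps_per_day=1,
    )
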