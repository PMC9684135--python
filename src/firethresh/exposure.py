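"""Threshold-exceedance climatologies and population / carbon exposure maps.

An *exceedance day* is a day whose daily-maximum VPD is strictly greater than
the cell's fire-activity threshold (VPD_P50, painted from its stratum onto
every cell the stratum covers).  The climatology is the mean annual count of
such days; projected change is the delta of two climatologies under the same
threshold map.  Exposure multiplies that change by a density layer — persons
per cell or tonnes of aboveground biomass per cell — giving person-days/year
or tonne-days/year.  Density rasters arrive at finer resolution and are
resampled to the climate grid with the median rule, omitting exact zeros
(the missing-data convention of biomass products); a coarse cell with no
positive fine cell is missing, not zero.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .grids import check_same_spatial, require_units
from .sampling import StratumSpec
from .timeaxis import DAYS_PER_YEAR

EXPOSURE_UNITS = {"population": "person-days/year", "biomass": "tonne-days/year"}


def thresholds_from_strata(
    strata: list[StratumSpec], p50_by_stratum: dict[str, float], shape: tuple[int, int]
) -> np.ndarray:
    """Paint per-stratum VPD_P50 values onto the climate grid (NaN outside)."""
    out = np.full(shape, np.nan)
    for spec in strata:
        if spec.stratum_id in p50_by_stratum:
            out[spec.mask] = p50_by_stratum[spec.stratum_id]
    return out


def exceedance_days(
    vpd_daily: xr.DataArray,
    thresholds: np.ndarray,
    period_label: str = "",
    threshold_source: str = "",
) -> xr.DataArray:
    """Mean annual count of days with VPD strictly above the cell threshold.

    ``thresholds`` is a (lat, lon) array in kPa; cells with NaN threshold
    (outside every stratum) are missing in the output, not zero.  The period
    must span at least one full no-leap year.
    """
    require_units(vpd_daily, "kPa")
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.shape != vpd_daily.shape[1:]:
        raise ValueError("threshold map does not match the climate grid")
    n_days = vpd_daily.shape[0]
    if n_days < DAYS_PER_YEAR:
        raise ValueError(f"period of {n_days} days is shorter than one full year")
    n_years = n_days / DAYS_PER_YEAR
    counts = np.sum(vpd_daily.values > thresholds[None, :, :], axis=0) / n_years
    counts = np.where(np.isnan(thresholds), np.nan, counts)
    out = xr.DataArray(
        counts,
        dims=("lat", "lon"),
        coords={"lat": vpd_daily.coords["lat"], "lon": vpd_daily.coords["lon"]},
        name="exceedance_days",
        attrs={
            "units": "days/year",
            "period": period_label,
            "threshold_source": threshold_source,
        },
    )
    return out


def change_in_exceedance(
    future: xr.DataArray, modelled_present: xr.DataArray
) -> xr.DataArray:
    """Future minus modelled-present exceedance days, same threshold map.

    Climatologies computed under different threshold sources are rejected —
    a difference of counts over different thresholds is meaningless.
    """
    check_same_spatial(future, modelled_present)
    if future.attrs.get("threshold_source") != modelled_present.attrs.get("threshold_source"):
        raise ValueError(
            "exceedance climatologies use different threshold sources: "
            f"{future.attrs.get('threshold_source')!r} vs "
            f"{modelled_present.attrs.get('threshold_source')!r}"
        )
    out = future - modelled_present
    out.name = "change_in_exceedance_days"
    out.attrs = {
        "units": "days/year",
        "threshold_source": future.attrs.get("threshold_source", ""),
        "epochs": f"{modelled_present.attrs.get('period','')} -> {future.attrs.get('period','')}",
    }
    return out


def resample_density(fine: xr.DataArray, template: xr.DataArray) -> xr.DataArray:
    """Median-rule resampling of a fine density raster to the climate grid.

    Each coarse cell takes the median of the strictly positive fine cells it
    covers; exact zeros (the missing-data convention) are omitted, and a
    coarse cell with no positive fine cell is NaN.  The fine grid must nest
    an integer number of times in the template.
    """
    n_lat = template.sizes["lat"]
    n_lon = template.sizes["lon"]
    fy, fx = fine.shape
    if fy % n_lat or fx % n_lon or (fy // n_lat) != (fx // n_lon):
        raise ValueError(
            f"fine raster {fine.shape} does not nest in climate grid ({n_lat}, {n_lon})"
        )
    r = fy // n_lat
    blocks = fine.values.reshape(n_lat, r, n_lon, r).transpose(0, 2, 1, 3).reshape(n_lat, n_lon, r * r)
    coarse = np.full((n_lat, n_lon), np.nan)
    for i in range(n_lat):
        for j in range(n_lon):
            positive = blocks[i, j][blocks[i, j] > 0]
            if len(positive):
                coarse[i, j] = np.median(positive)
    return xr.DataArray(
        coarse,
        dims=("lat", "lon"),
        coords={"lat": template.coords["lat"], "lon": template.coords["lon"]},
        name=fine.name,
        attrs=dict(fine.attrs),
    )


def exposure(change: xr.DataArray, density: xr.DataArray, kind: str) -> xr.DataArray:
    """Per-cell exposure: change in exceedance days times density.

    ``kind`` must agree with the density raster's own kind tag; the output
    is person-days/year or tonne-days/year and is zero wherever density is
    zero, missing wherever either input is missing.
    """
    if kind not in EXPOSURE_UNITS:
        raise ValueError(f"kind must be one of {sorted(EXPOSURE_UNITS)}")
    if density.attrs.get("kind") not in (None, kind):
        raise ValueError(
            f"density raster is tagged {density.attrs.get('kind')!r}, not {kind!r}"
        )
    if change.attrs.get("units") != "days/year":
        raise ValueError("change grid must be in days/year")
    check_same_spatial(change, density)
    out = change * density
    out.name = f"{kind}_exposure"
    out.attrs = {
        "units": EXPOSURE_UNITS[kind],
        "kind": kind,
        "threshold_source": change.attrs.get("threshold_source", ""),
    }
    return out
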