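"""Empirical quantile mapping of model VPD onto a reference climatology.

Climate-model VPD carries distributional bias; before counting threshold
exceedances, the model-historical series is mapped quantile-by-quantile onto
the reference (reanalysis) series, and the same transfer function corrects
the model-future series.  Projected change is then always reported with the
*delta* convention — corrected-model future minus corrected-model present —
so any residual constant model bias cancels and the observed climatology is
never mixed into a difference.

The map is empirical: quantiles of both series at shared probability levels
(99 percentiles by default), applied by piecewise-linear interpolation with
additive extrapolation beyond the outermost quantiles, fitted per calendar
month by default to respect seasonality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import timeaxis
from .grids import check_same_spatial
from .timeaxis import DAYS_PER_YEAR

logger = logging.getLogger(__name__)


@dataclass
class QuantileMap:
    """Empirical source->target quantile transfer for one series (or month)."""

    q_levels: np.ndarray       # probabilities in (0, 1), increasing
    source_quantiles: np.ndarray  # kPa, model-historical
    target_quantiles: np.ndarray  # kPa, reference
    degenerate: bool = False   # constant source: identity-with-offset fallback

    def __post_init__(self) -> None:
        for name in ("q_levels", "source_quantiles", "target_quantiles"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.q_levels) == len(self.source_quantiles) == len(self.target_quantiles)):
            raise ValueError("quantile arrays must share length with q_levels")
        if np.any(np.diff(self.source_quantiles) < 0) or np.any(np.diff(self.target_quantiles) < 0):
            raise ValueError("quantile arrays must be non-decreasing")


def fit_quantile_map(
    model_hist: np.ndarray,
    reference: np.ndarray,
    n_quantiles: int = 99,
) -> QuantileMap:
    """Fit the empirical transfer from one model series to one reference series.

    A degenerate (constant) model series cannot define a spread correction;
    the map then falls back to a pure offset and is flagged.
    """
    model_hist = np.asarray(model_hist, dtype=float).ravel()
    reference = np.asarray(reference, dtype=float).ravel()
    if len(model_hist) == 0 or len(reference) == 0:
        raise ValueError("both series must be non-empty")
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    levels = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    src = np.quantile(model_hist, levels)
    tgt = np.quantile(reference, levels)
    degenerate = bool(np.ptp(model_hist) == 0)
    if degenerate:
        offset = float(np.median(reference) - model_hist[0])
        logger.warning("constant model series: falling back to identity-with-offset map")
        src = np.full_like(levels, model_hist[0])
        tgt = src + offset
    return QuantileMap(levels, src, tgt, degenerate=degenerate)


def apply_quantile_map(qmap: QuantileMap, series: np.ndarray) -> np.ndarray:
    """Correct a series through the fitted map.

    Values between stored source quantiles interpolate linearly; values
    beyond the outermost quantiles are shifted by the edge quantile's
    additive offset (so extreme tails keep the model's shape but lose its
    mean bias).  Output is clamped at 0 kPa.
    """
    series = np.asarray(series, dtype=float)
    src, tgt = qmap.source_quantiles, qmap.target_quantiles
    if qmap.degenerate:
        out = series + (tgt[0] - src[0])
        return np.clip(out, 0.0, None)
    out = np.interp(series, src, tgt)
    below = series < src[0]
    above = series > src[-1]
    out[below] = series[below] + (tgt[0] - src[0])
    out[above] = series[above] + (tgt[-1] - src[-1])
    return np.clip(out, 0.0, None)


@dataclass
class MonthlyQuantileMap:
    """Per-calendar-month quantile maps for one grid cell (or pooled series)."""

    maps: dict[int, QuantileMap]  # month (1..12) -> map; key 0 = all-year

    def apply(self, series: np.ndarray, months: np.ndarray | None = None) -> np.ndarray:
        if 0 in self.maps:
            return apply_quantile_map(self.maps[0], series)
        if months is None:
            raise ValueError("per-month map needs the month of each value")
        out = np.empty_like(np.asarray(series, dtype=float))
        for m, qm in self.maps.items():
            sel = months == m
            out[sel] = apply_quantile_map(qm, np.asarray(series)[sel])
        return out


def _daily_months(n_days: int) -> np.ndarray:
    doy = np.arange(n_days) % DAYS_PER_YEAR + 1
    return np.asarray(timeaxis.month_of_doy(doy))


def fit_quantile_map_grid(
    model_hist: xr.DataArray,
    reference: xr.DataArray,
    n_quantiles: int = 99,
    by_month: bool = True,
) -> list[list[MonthlyQuantileMap]]:
    """Fit one (monthly) quantile map per climate grid cell."""
    check_same_spatial(model_hist, reference)
    months_m = _daily_months(model_hist.shape[0])
    months_r = _daily_months(reference.shape[0])
    n_lat, n_lon = model_hist.shape[1:]
    out: list[list[MonthlyQuantileMap]] = []
    for i in range(n_lat):
        row = []
        for j in range(n_lon):
            mh = model_hist.values[:, i, j]
            rf = reference.values[:, i, j]
            if by_month:
                maps = {
                    m: fit_quantile_map(mh[months_m == m], rf[months_r == m], n_quantiles)
                    for m in range(1, 13)
                }
            else:
                maps = {0: fit_quantile_map(mh, rf, n_quantiles)}
            row.append(MonthlyQuantileMap(maps))
        out.append(row)
    return out


def apply_quantile_map_grid(
    maps: list[list[MonthlyQuantileMap]], series: xr.DataArray
) -> xr.DataArray:
    """Apply per-cell (monthly) maps to a daily VPD grid."""
    months = _daily_months(series.shape[0])
    corrected = np.empty_like(series.values)
    for i, row in enumerate(maps):
        for j, qm in enumerate(row):
            corrected[:, i, j] = qm.apply(series.values[:, i, j], months)
    out = series.copy(data=corrected)
    out.attrs["bias_corrected"] = 1
    return out


def quantile_maps_to_frame(maps: list[list[MonthlyQuantileMap]]) -> pd.DataFrame:
    """Serialise fitted maps as a tidy table (cell, month, level, source, target)."""
    rows = []
    for i, row in enumerate(maps):
        for j, mqm in enumerate(row):
            for month, qm in mqm.maps.items():
                for lvl, s, t in zip(qm.q_levels, qm.source_quantiles, qm.target_quantiles):
                    rows.append(
                        {
                            "cell_lat_idx": i,
                            "cell_lon_idx": j,
                            "month": month,
                            "level": lvl,
                            "source_q": s,
                            "target_q": t,
                        }
                    )
    return pd.DataFrame(rows)


def delta_change(future_stat: xr.DataArray, modelled_present_stat: xr.DataArray) -> xr.DataArray:
    """Per-cell change: modelled future minus modelled present, same grid.

    The observed ("current") climatology never enters this difference — the
    delta convention cancels constant model bias by construction.
    """
    check_same_spatial(future_stat, modelled_present_stat)
    if future_stat.shape != modelled_present_stat.shape:
        raise ValueError("future and present statistics must share a grid")
    out = future_stat - modelled_present_stat
    out.attrs.update(future_stat.attrs)
    out.name = "delta_" + str(future_stat.name or "stat")
    return out
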