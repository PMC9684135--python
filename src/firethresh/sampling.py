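"""Stratified presence / quasi-absence sampling linking fire events to VPD.

Presences are the daily VPD values at the same day and nearest climate cell
to each burned-area record; because the fire product is finer than the
climate grid, several burned cells can legitimately share one VPD value.
Quasi-absences are unburned cells at uniform-random dates, drawn without
replacement so that each stratum-year has *exactly* as many absences as
presences.  Cells that burned within the preceding five years are excluded
from the absence pool, mirroring the fire-history filter of the occurrence
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import timeaxis
from .grids import require_units
from .timeaxis import DAYS_PER_YEAR

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["vpd_kpa", "burned", "year", "stratum"]

EARTH_RADIUS_KM = 6371.0


@dataclass
class StratumSpec:
    """One biome x sub-continental-window stratum on the climate grid."""

    stratum_id: str
    mask: np.ndarray  # 2-D bool, (lat, lon) on the climate grid
    biome: str = ""
    window: str = ""
    biome_group: str = ""  # e.g. tropical / mediterranean / temperate_boreal

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("stratum mask must be 2-D (lat, lon)")


BurnHistory = dict[tuple[int, int], np.ndarray]  # cell -> sorted burn ordinals


def build_burn_history(*event_tables: pd.DataFrame) -> BurnHistory:
    """Collect per-cell sorted burn-date ordinals from event tables.

    Pass both the study-period events and any pre-period history; with no
    pre-period table the first years of the study are left-censored with
    respect to the five-year filter, which is logged rather than hidden.
    """
    frames = [t for t in event_tables if t is not None and len(t)]
    if len(frames) < 2:
        logger.info("burn history built from %d table(s); pre-period burns may be left-censored", len(frames))
    history: dict[tuple[int, int], list[int]] = {}
    for table in frames:
        for row in table.itertuples(index=False):
            year, doy = timeaxis.parse_date(row.date)
            cell = (int(row.cell_lat_idx), int(row.cell_lon_idx))
            history.setdefault(cell, []).append(timeaxis.date_to_ordinal(year, doy))
    return {cell: np.array(sorted(dates)) for cell, dates in history.items()}


def _haversine_km(lat1, lon1, lat2, lon2):
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def match_presences(events: pd.DataFrame, vpd_daily: xr.DataArray) -> pd.DataFrame:
    """One presence row per event, with the VPD of the nearest climate cell.

    Nearest is great-circle distance to the cell centre; exact ties resolve
    to the lowest (lat index, lon index), row-major, so matching is
    deterministic.  Events outside the grid's spatial bounds (cell centres
    padded by half a cell) are dropped with a logged count.
    """
    require_units(vpd_daily, "kPa")
    lats = vpd_daily.coords["lat"].values
    lons = vpd_daily.coords["lon"].values
    half_lat = (np.diff(lats).mean() / 2) if len(lats) > 1 else 0.5
    half_lon = (np.diff(lons).mean() / 2) if len(lons) > 1 else 0.5
    in_bounds = (
        (events["lat"].values >= lats.min() - half_lat)
        & (events["lat"].values <= lats.max() + half_lat)
        & (events["lon"].values >= lons.min() - half_lon)
        & (events["lon"].values <= lons.max() + half_lon)
    )
    n_dropped = int((~in_bounds).sum())
    if n_dropped:
        logger.info("dropped %d event(s) outside the climate grid bounds", n_dropped)
    events = events.loc[in_bounds]

    grid_lat = np.repeat(lats, len(lons))
    grid_lon = np.tile(lons, len(lats))
    start_year = int(vpd_daily.attrs["start_year"])
    n_days = vpd_daily.shape[0]

    rows = []
    for row in events.itertuples(index=False):
        d = _haversine_km(row.lat, row.lon, grid_lat, grid_lon)
        # geometric ties carry float noise; treat anything within 1e-6 km of
        # the minimum as tied and take the lowest (lat, lon) index, row-major
        flat = int(np.flatnonzero(d <= d.min() + 1e-6)[0])
        i, j = divmod(flat, len(lons))
        year, doy = timeaxis.parse_date(row.date)
        t = (year - start_year) * DAYS_PER_YEAR + doy - 1
        if not 0 <= t < n_days:
            raise ValueError(f"event date {row.date} not covered by the VPD grid")
        rows.append(
            {
                "vpd_kpa": float(vpd_daily.values[t, i, j]),
                "burned": 1,
                "year": year,
                "stratum": row.stratum,
                "date": row.date,
                "cell_lat_idx": i,
                "cell_lon_idx": j,
            }
        )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS + ["date", "cell_lat_idx", "cell_lon_idx"])


def eligible_absence_cells(
    stratum: StratumSpec,
    history: BurnHistory,
    date: tuple[int, int],
    lookback_years: int = 5,
) -> set[tuple[int, int]]:
    """Cells in the stratum that are absence-eligible on ``date`` (year, doy).

    Eligible means unburned on the date itself and with no burn in the
    half-open window [date − lookback_years, date).
    """
    if lookback_years < 0:
        raise ValueError("lookback_years must be >= 0")
    d = timeaxis.date_to_ordinal(*date)
    lo = d - lookback_years * DAYS_PER_YEAR
    eligible = set()
    for i, j in zip(*np.nonzero(stratum.mask)):
        burns = history.get((int(i), int(j)))
        if burns is not None:
            # any burn in [lo, d] disqualifies: window [lo, d) plus same-day d
            k = np.searchsorted(burns, lo, side="left")
            if k < len(burns) and burns[k] <= d:
                continue
        eligible.add((int(i), int(j)))
    if not eligible:
        logger.warning(
            "stratum %s has no absence-eligible cell on %s; date skipped",
            stratum.stratum_id,
            timeaxis.format_date(*date),
        )
    return eligible


def _eligibility_matrix(
    stratum: StratumSpec, history: BurnHistory, year: int, lookback_years: int
) -> tuple[np.ndarray, np.ndarray]:
    """(cells, 365) bool eligibility for every masked cell and day of `year`."""
    cells = np.argwhere(stratum.mask)
    day_ords = timeaxis.date_to_ordinal(year, 1) + np.arange(DAYS_PER_YEAR)
    lo = day_ords - lookback_years * DAYS_PER_YEAR
    elig = np.ones((len(cells), DAYS_PER_YEAR), dtype=bool)
    for c, (i, j) in enumerate(cells):
        burns = history.get((int(i), int(j)))
        if burns is None or not len(burns):
            continue
        k = np.searchsorted(burns, lo, side="left")
        has_burn = (k < len(burns)) & (burns[np.minimum(k, len(burns) - 1)] <= day_ords)
        elig[c] = ~has_burn
    return cells, elig


def sample_quasi_absences(
    events: pd.DataFrame,
    vpd_daily: xr.DataArray,
    stratum: StratumSpec,
    seed: int,
    history: BurnHistory | None = None,
    lookback_years: int = 5,
) -> pd.DataFrame:
    """Absence rows matching the per-year presence counts of ``events``.

    For each calendar year with n presences in this stratum, draw exactly n
    (cell, date) pairs uniformly *without replacement* from the eligible pool
    (masked cells, uniform dates over the year, five-year burn exclusion).
    An exhausted pool is a hard error naming the year and stratum.
    """
    require_units(vpd_daily, "kPa")
    if history is None:
        history = build_burn_history(events)
    rng = np.random.default_rng(seed)
    start_year = int(vpd_daily.attrs["start_year"])
    ev = events[events["stratum"] == stratum.stratum_id]
    per_year = ev.groupby("year").size()

    rows = []
    for year, n_needed in per_year.items():
        cells, elig = _eligibility_matrix(stratum, history, int(year), lookback_years)
        pool = np.argwhere(elig)  # (cell index, day-of-year index 0-based)
        if len(pool) < n_needed:
            raise RuntimeError(
                f"absence pool exhausted: stratum {stratum.stratum_id}, year {year}: "
                f"need {n_needed}, eligible cell-dates {len(pool)}"
            )
        pick = rng.choice(len(pool), size=int(n_needed), replace=False)
        for c_idx, day0 in pool[pick]:
            i, j = (int(v) for v in cells[c_idx])
            t = (int(year) - start_year) * DAYS_PER_YEAR + int(day0)
            rows.append(
                {
                    "vpd_kpa": float(vpd_daily.values[t, i, j]),
                    "burned": 0,
                    "year": int(year),
                    "stratum": stratum.stratum_id,
                    "date": timeaxis.format_date(int(year), int(day0) + 1),
                    "cell_lat_idx": i,
                    "cell_lon_idx": j,
                }
            )
    return pd.DataFrame(rows, columns=SAMPLE_COLUMNS + ["date", "cell_lat_idx", "cell_lon_idx"])


def assemble_stratum_samples(
    presences: pd.DataFrame, absences: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Concatenate and deterministically shuffle presence/absence rows.

    Logs per-stratum row counts; an empty stratum simply yields no rows and
    is reported as unfittable by the model stage.
    """
    combined = pd.concat([presences, absences], ignore_index=True)
    if combined.empty:
        logger.warning("assembled sample is empty — stratum is unfittable")
        return combined
    rng = np.random.default_rng(seed)
    combined = combined.iloc[rng.permutation(len(combined))].reset_index(drop=True)
    for stratum, group in combined.groupby("stratum"):
        logger.info(
            "stratum %s: %d rows (%d presences, %d absences)",
            stratum,
            len(group),
            int((group["burned"] == 1).sum()),
            int((group["burned"] == 0).sum()),
        )
    return combined
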