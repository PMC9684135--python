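"""Seeded synthetic stand-ins for the external datasets the pipeline consumes.

Every generator here produces data with *known* statistical structure so the
downstream stages — VPD computation, presence/quasi-absence sampling, logistic
threshold fitting, quantile-mapping bias correction and exceedance/exposure
mapping — can be validated offline against planted truth:

* paired air-temperature / dew-point grids with seasonal and diurnal cycles
  plus AR(1) noise (reanalysis-like at 24 steps/day, GCM-like at 8);
* daily-maximum VPD series whose stationary marginal is a known Gaussian, so
  exceedance probabilities above any threshold have a closed form;
* fire occurrence drawn cell-day by cell-day from a planted logistic law in
  VPD, whose 50% point -beta0/beta1 the fitting stage must recover;
* an affinely distorted "GCM" series (scale, shift, additive future delta)
  for bias-correction recovery tests;
* log-normal population / biomass rasters on a finer nested grid, with exact
  zeros standing in for missing-data holes.

All randomness flows from the seed in :class:`WorldSpec`; the calendar is the
365-day no-leap calendar throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit
from scipy.stats import norm

from . import timeaxis
from .grids import make_grid, require_units
from .timeaxis import DAYS_PER_YEAR


@dataclass(frozen=True)
class WorldSpec:
    """Geometry, calendar and noise parameters of a synthetic world.

    ``steps_per_day=24`` emulates hourly reanalysis, ``8`` emulates 3-hourly
    GCM output.  Temperature parameters are in degC; the dew-point depression
    (temperature minus dew point) is drawn non-negative so dew point never
    exceeds air temperature.
    """

    n_lat: int = 4
    n_lon: int = 4
    years: tuple[int, ...] = (2003, 2004, 2005)
    steps_per_day: int = 24
    seed: int = 0
    # climate process parameters
    t_mean: float = 18.0          # degC, domain-mean temperature
    t_ann_amp: float = 8.0        # degC, amplitude of the annual cycle
    t_diur_amp: float = 5.0       # degC, amplitude of the diurnal cycle
    ar1_rho: float = 0.7          # lag-1 autocorrelation of cell noise
    noise_sd: float = 2.0         # degC, innovation SD of per-cell AR(1) noise
    regional_sd: float = 1.0      # degC, innovation SD of the shared regional AR(1)
    dew_depression_mean: float = 8.0  # degC, mean dew-point depression
    dew_depression_sd: float = 3.0    # degC, SD of the depression (folded normal)
    lat0: float = -40.0
    lon0: float = 140.0
    cell_deg: float = 0.25        # grid spacing, degrees

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("n_lat and n_lon must be >= 1")
        if not timeaxis.years_are_consecutive(list(self.years)):
            raise ValueError("years must be non-empty and consecutive")
        if self.steps_per_day < 1 or 24 % self.steps_per_day != 0:
            raise ValueError(f"steps_per_day={self.steps_per_day} must divide 24")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_steps(self) -> int:
        return self.n_years * DAYS_PER_YEAR * self.steps_per_day

    @property
    def lats(self) -> np.ndarray:
        return self.lat0 + self.cell_deg * np.arange(self.n_lat)

    @property
    def lons(self) -> np.ndarray:
        return self.lon0 + self.cell_deg * np.arange(self.n_lon)


@dataclass(frozen=True)
class PlantedFireLaw:
    """True logistic law P(burn) = expit(beta0 + beta1 * VPD), beta1 > 0.

    The planted 50% threshold is ``-beta0/beta1``; recovery of this value by
    the fitting stage is the core validation of the whole pipeline.
    """

    beta0: float = -5.0
    beta1: float = 2.0  # per kPa

    def __post_init__(self) -> None:
        if not self.beta1 > 0:
            raise ValueError("beta1 must be > 0 for a well-defined 50% threshold")

    @property
    def threshold(self) -> float:
        return -self.beta0 / self.beta1

    def probability(self, vpd: np.ndarray) -> np.ndarray:
        return expit(self.beta0 + self.beta1 * np.asarray(vpd))


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], rho: float, sd: float) -> np.ndarray:
    """AR(1) series along axis 0, started from the stationary distribution."""
    n = shape[0]
    out = np.empty(shape)
    stat_sd = sd / np.sqrt(1.0 - rho**2) if abs(rho) < 1 else sd
    out[0] = rng.normal(0.0, stat_sd, shape[1:])
    innov = rng.normal(0.0, sd, (n - 1,) + shape[1:])
    for t in range(1, n):
        out[t] = rho * out[t - 1] + innov[t - 1]
    return out


def generate_climate(spec: WorldSpec) -> tuple[xr.DataArray, xr.DataArray]:
    """Paired air-temperature and dew-point grids (degC) on the spec's world.

    Temperature = mean + annual sinusoid (phase flipped across the equator)
    + diurnal sinusoid + shared regional AR(1) + per-cell AR(1).  Dew point =
    temperature − a non-negative folded-normal depression, so T_d <= T holds
    at every cell-step by construction.
    """
    rng = np.random.default_rng(spec.seed)
    spd = spec.steps_per_day
    nt = spec.n_steps
    step = np.arange(nt)
    doy = (step // spd) % DAYS_PER_YEAR + 1
    hour = (step % spd) * (24 // spd)

    annual = np.sin(2 * np.pi * (doy - 1) / DAYS_PER_YEAR - np.pi / 2)
    diurnal = np.sin(2 * np.pi * hour / 24 - np.pi / 2)
    # southern-hemisphere cells peak half a year later
    hemis = np.where(spec.lats < 0, -1.0, 1.0)[:, None]

    regional = _ar1(rng, (nt,), spec.ar1_rho, spec.regional_sd)
    cell_noise = _ar1(rng, (nt, spec.n_lat, spec.n_lon), spec.ar1_rho, spec.noise_sd)

    t = (
        spec.t_mean
        + spec.t_ann_amp * annual[:, None, None] * hemis[None, :, :]
        + spec.t_diur_amp * diurnal[:, None, None]
        + regional[:, None, None]
        + cell_noise
    )
    depression = np.abs(
        rng.normal(spec.dew_depression_mean, spec.dew_depression_sd, t.shape)
    )
    td = t - depression

    kwargs = dict(
        lats=spec.lats,
        lons=spec.lons,
        units="degC",
        start_year=spec.years[0],
        steps_per_day=spd,
    )
    return (
        make_grid(t, name="air_temperature", **kwargs),
        make_grid(td, name="dew_point", **kwargs),
    )


def generate_vpd_daily(
    spec: WorldSpec,
    mean: float = 2.0,
    sd: float = 0.6,
    rho: float = 0.5,
) -> xr.DataArray:
    """Daily-maximum VPD grid (kPa) with a known Gaussian stationary marginal.

    Each cell is an independent AR(1) started from its stationary distribution
    N(mean, sd^2); negative values are clamped to 0 kPa.  Because clamping
    only moves mass below zero, P(VPD > theta) for any theta > 0 is exactly
    the Gaussian tail — see :func:`gaussian_exceedance_probability` — which is
    what end-to-end exceedance tests rely on.
    """
    rng = np.random.default_rng(spec.seed)
    n_days = spec.n_years * DAYS_PER_YEAR
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    noise = _ar1(rng, (n_days, spec.n_lat, spec.n_lon), rho, innov_sd)
    vpd = np.clip(mean + noise, 0.0, None)
    da = make_grid(
        vpd,
        lats=spec.lats,
        lons=spec.lons,
        name="vpd",
        units="kPa",
        start_year=spec.years[0],
        steps_per_day=1,
    )
    da.attrs["marginal_mean"] = float(mean)
    da.attrs["marginal_sd"] = float(sd)
    return da


def gaussian_exceedance_probability(mean: float, sd: float, threshold: float) -> float:
    """Closed-form P(VPD > threshold) under the generator's Gaussian marginal."""
    return float(norm.sf(threshold, loc=mean, scale=sd))


def generate_fire_occurrence(
    vpd_daily: xr.DataArray,
    law: PlantedFireLaw,
    spec: WorldSpec,
    stratum_map: np.ndarray | None = None,
    history_years: int = 0,
    history_events_per_year: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw burned cell-days from the planted logistic law.

    Each cell-day burns independently with probability
    ``expit(beta0 + beta1 * VPD)``.  Returns ``(events, history)`` tables with
    columns ``cell_lat_idx, cell_lon_idx, lat, lon, date, year, doy, stratum``.
    The history table holds uniform-random burns in the ``history_years``
    years before the study period, drawn independently of the planted law so
    that burn-exclusion filter tests have exact expected counts.
    """
    require_units(vpd_daily, "kPa")
    if int(vpd_daily.attrs["steps_per_day"]) != 1:
        raise ValueError("generate_fire_occurrence needs a daily-resolution VPD grid")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF1EE]))
    vpd = vpd_daily.values
    p = law.probability(vpd)
    burned = rng.random(p.shape) < p
    t_idx, i_idx, j_idx = np.nonzero(burned)
    start_year = int(vpd_daily.attrs["start_year"])
    years = start_year + t_idx // DAYS_PER_YEAR
    doys = t_idx % DAYS_PER_YEAR + 1

    if stratum_map is None:
        stratum_map = np.zeros((vpd.shape[1], vpd.shape[2]), dtype=object)
        stratum_map[:] = "s0"
    lats = vpd_daily.coords["lat"].values
    lons = vpd_daily.coords["lon"].values
    events = pd.DataFrame(
        {
            "cell_lat_idx": i_idx,
            "cell_lon_idx": j_idx,
            "lat": lats[i_idx],
            "lon": lons[j_idx],
            "date": [timeaxis.format_date(y, d) for y, d in zip(years, doys)],
            "year": years,
            "doy": doys,
            "stratum": [stratum_map[i, j] for i, j in zip(i_idx, j_idx)],
        }
    )

    hist_rows = []
    for k in range(history_years):
        year = start_year - history_years + k
        for _ in range(history_events_per_year):
            i = int(rng.integers(vpd.shape[1]))
            j = int(rng.integers(vpd.shape[2]))
            doy = int(rng.integers(1, DAYS_PER_YEAR + 1))
            hist_rows.append(
                {
                    "cell_lat_idx": i,
                    "cell_lon_idx": j,
                    "lat": lats[i],
                    "lon": lons[j],
                    "date": timeaxis.format_date(year, doy),
                    "year": year,
                    "doy": doy,
                    "stratum": stratum_map[i, j],
                }
            )
    history = pd.DataFrame(
        hist_rows,
        columns=["cell_lat_idx", "cell_lon_idx", "lat", "lon", "date", "year", "doy", "stratum"],
    )
    return events, history


def generate_gcm_like(
    reference: xr.DataArray,
    bias_shift: float,
    bias_scale: float,
    future_delta: float,
    spec: WorldSpec,
) -> tuple[xr.DataArray, xr.DataArray]:
    """Model-historical and model-future VPD with a planted affine distortion.

    A fresh realisation of the reference process (same Gaussian marginal,
    different seed) stands for the climate the model *should* produce; the
    model's bias is the affine distortion ``scale * x + shift`` applied to
    whatever it simulates.  The historical series is the distorted base
    process; the future series is the distortion of (base + future_delta),
    i.e. the warming signal lives in reference space and the model's bias
    applies to it like to everything else — so an exact quantile-mapping
    correction recovers ``future_delta`` in corrected units.  The distortion
    parameters are retained in the attrs for test assertions.
    """
    if not bias_scale > 0:
        raise ValueError("bias_scale must be > 0")
    mean = float(reference.attrs.get("marginal_mean", float(reference.mean())))
    sd = float(reference.attrs.get("marginal_sd", float(reference.std())))
    like_spec = replace(spec, seed=int(np.random.SeedSequence([spec.seed, 0x6C4D]).generate_state(1)[0] % 2**31))
    base = generate_vpd_daily(like_spec, mean=mean, sd=sd)
    hist_vals = np.clip(bias_scale * base.values + bias_shift, 0.0, None)
    fut_vals = np.clip(bias_scale * (base.values + future_delta) + bias_shift, 0.0, None)

    def _wrap(vals: np.ndarray, name: str) -> xr.DataArray:
        da = base.copy(data=vals)
        da.name = name
        da.attrs.update(
            bias_shift=float(bias_shift),
            bias_scale=float(bias_scale),
            future_delta=float(future_delta),
            marginal_mean=mean * bias_scale + bias_shift,
            marginal_sd=sd * bias_scale,
        )
        return da

    hist = _wrap(hist_vals, "vpd_model_hist")
    fut = _wrap(fut_vals, "vpd_model_future")
    fut.attrs["marginal_mean"] += future_delta * bias_scale
    return hist, fut


def generate_occurrence_samples(
    law: PlantedFireLaw,
    n: int,
    seed: int,
    vpd_mean: float | None = None,
    vpd_sd: float = 1.0,
    stratum: str = "s0",
    year: int = 2003,
) -> pd.DataFrame:
    """Labelled (vpd, burned) rows drawn directly from the planted law.

    VPD is Gaussian (clipped at 0 kPa) centred by default on the law's 50%
    threshold, so labels come out near-balanced without case-control
    selection and the logistic fit is an unbiased estimate of the planted
    coefficients — the cleanest possible recovery benchmark.
    """
    rng = np.random.default_rng(seed)
    if vpd_mean is None:
        vpd_mean = law.threshold
    vpd = np.clip(rng.normal(vpd_mean, vpd_sd, n), 0.0, None)
    burned = (rng.random(n) < law.probability(vpd)).astype(int)
    return pd.DataFrame(
        {"vpd_kpa": vpd, "burned": burned, "year": year, "stratum": stratum}
    )


def generate_density_raster(
    spec: WorldSpec,
    kind: str,
    zero_fraction: float = 0.1,
    fine_ratio: int = 4,
    log_mean: float = 4.0,
    log_sd: float = 1.0,
) -> xr.DataArray:
    """Population or biomass raster on a grid nesting ``fine_ratio``x finer.

    Values are log-normal (non-negative by construction); an independent
    Bernoulli(zero_fraction) mask sets cells to exactly 0, emulating the
    missing-data holes of real biomass products.  Units are persons per cell
    or tonnes per cell — the exposure product is linear in density, so the
    absolute scale is arbitrary.
    """
    if kind not in ("population", "biomass"):
        raise ValueError(f"kind must be population or biomass, got {kind!r}")
    if not 0 <= zero_fraction < 1:
        raise ValueError("zero_fraction must be in [0, 1)")
    if fine_ratio < 1:
        raise ValueError("fine_ratio must be >= 1")
    kind_tag = {"population": 1, "biomass": 2}[kind]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xDE45, kind_tag]))
    shape = (spec.n_lat * fine_ratio, spec.n_lon * fine_ratio)
    vals = rng.lognormal(log_mean, log_sd, shape)
    vals[rng.random(shape) < zero_fraction] = 0.0
    fine_step = spec.cell_deg / fine_ratio
    ys = spec.lat0 - spec.cell_deg / 2 + fine_step * (0.5 + np.arange(shape[0]))
    xs = spec.lon0 - spec.cell_deg / 2 + fine_step * (0.5 + np.arange(shape[1]))
    da = xr.DataArray(
        vals,
        dims=("y", "x"),
        coords={"y": ys, "x": xs},
        name=f"{kind}_density",
        attrs={
            "units": "persons" if kind == "population" else "tonnes",
            "kind": kind,
            "fine_ratio": int(fine_ratio),
        },
    )
    return da
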