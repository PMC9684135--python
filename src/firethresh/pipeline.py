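"""End-to-end orchestration: simulate -> vpd -> sample -> fit -> bias-correct
-> exceedance -> exposure, with a manifest, provenance metadata and format
validation.

Every stage reads and writes files in the run directory, so each can be
rerun or inspected in isolation.  All randomness flows from the master seed
in the config; each stage derives its own seed as
``(master_seed + crc32(stage_name)) % 2**31`` so stages are independently
reproducible.  A completed stage whose outputs already exist is skipped
unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import biascorr, raster, sampling, synth
from . import model as model_mod
from . import vpd as vpd_mod
from .exposure import (
    change_in_exceedance,
    exceedance_days,
    exposure as compute_exposure,
    resample_density,
    thresholds_from_strata,
)
from .grids import read_netcdf, write_netcdf
from .sampling import StratumSpec

logger = logging.getLogger(__name__)

STAGES = ["simulate", "vpd", "sample", "fit", "bias_correct", "exceedance", "exposure"]


class StageError(RuntimeError):
    """A stage failed; the message names the stage and the missing input."""


@dataclass
class RunConfig:
    """Flat configuration for a full synthetic run."""

    outdir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    force: bool = False
    world: dict = field(default_factory=dict)
    # default law keeps fire rare (~1e-3 per cell-day at typical VPD), as in
    # real burned-area records, so the 5-year exclusion leaves an absence pool
    law: dict = field(default_factory=lambda: {"beta0": -9.5, "beta1": 2.0})
    vpd_marginal: dict = field(default_factory=lambda: {"mean": 2.0, "sd": 0.6, "rho": 0.5})
    gcm: dict = field(default_factory=lambda: {"bias_shift": 0.3, "bias_scale": 1.2, "future_delta": 0.5})
    scenario: str = "RCP8.5"
    epochs: dict = field(default_factory=lambda: {"present": "1981-2000", "future": "2081-2100"})
    sampling: dict = field(default_factory=lambda: {"lookback_years": 5, "history_years": 5, "history_events_per_year": 2})
    bias_correction: dict = field(default_factory=lambda: {"n_quantiles": 99, "by_month": False})
    density: dict = field(default_factory=lambda: {"zero_fraction": 0.1, "fine_ratio": 4})
    strata: list[dict] = field(default_factory=list)  # [{id, lat_rows, biome_group, law?}]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + zlib.crc32(stage.encode())) % 2**31

    def world_spec(self, seed_override: int | None = None) -> synth.WorldSpec:
        kwargs = dict(self.world)
        if "years" in kwargs:
            kwargs["years"] = tuple(kwargs["years"])
        kwargs["seed"] = self.stage_seed("simulate") if seed_override is None else seed_override
        return synth.WorldSpec(**kwargs)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths and run flags excluded)."""
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("outdir", "force", "stages")}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_strata(config: RunConfig, shape: tuple[int, int]) -> list[StratumSpec]:
    if not config.strata:
        mask = np.ones(shape, dtype=bool)
        return [StratumSpec("s0", mask, biome_group="all")]
    out = []
    for entry in config.strata:
        mask = np.zeros(shape, dtype=bool)
        lo, hi = entry["lat_rows"]
        mask[lo:hi, :] = True
        out.append(
            StratumSpec(
                entry["id"],
                mask,
                biome=entry.get("biome", ""),
                window=entry.get("window", ""),
                biome_group=entry.get("biome_group", ""),
            )
        )
    return out


def _stratum_map(strata: list[StratumSpec], shape: tuple[int, int]) -> np.ndarray:
    smap = np.full(shape, "", dtype=object)
    for spec in strata:
        smap[spec.mask] = spec.stratum_id
    return smap


def _stratum_law(config: RunConfig, entry_id: str | None) -> synth.PlantedFireLaw:
    if entry_id is not None:
        for entry in config.strata:
            if entry["id"] == entry_id and "law" in entry:
                return synth.PlantedFireLaw(**entry["law"])
    return synth.PlantedFireLaw(**config.law)


def run(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    A failing stage halts the run with the stage named; outputs of the
    failed stage are recorded as invalid in the manifest on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "stages": {},
    }
    manifest_path = outdir / "manifest.json"

    for stage in STAGES:
        if stage not in config.stages:
            continue
        fn = _STAGE_FUNCS[stage]
        expected = [outdir / name for name in _STAGE_OUTPUTS[stage](config)]
        if not config.force and expected and all(p.exists() for p in expected):
            logger.info("stage %s: outputs exist, skipping (use force to rerun)", stage)
            manifest["stages"][stage] = {"outputs": [str(p) for p in expected], "skipped": True}
            continue
        try:
            outputs = fn(config, outdir)
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc), "invalid": True}
            manifest_path.write_text(json.dumps(manifest, indent=2))
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {"outputs": [str(p) for p in outputs]}
        manifest_path.write_text(json.dumps(manifest, indent=2))

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


# --- individual stages -----------------------------------------------------


def _stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    spec = config.world_spec()
    t_grid, td_grid = synth.generate_climate(spec)
    write_netcdf(t_grid, outdir / "air_temperature.nc")
    write_netcdf(td_grid, outdir / "dew_point.nc")

    vpd_daily = vpd_mod.daily_max_vpd(t_grid, td_grid, "dewpoint")
    strata = _build_strata(config, vpd_daily.shape[1:])
    smap = _stratum_map(strata, vpd_daily.shape[1:])
    samp_cfg = config.sampling
    events_parts, history_parts = [], []
    for k, stratum in enumerate(strata):
        law = _stratum_law(config, stratum.stratum_id)
        sub_spec = synth.WorldSpec(**{**config.world, "years": spec.years,
                                      "seed": (spec.seed + 1000 * (k + 1)) % 2**31})
        ev, hist = synth.generate_fire_occurrence(
            vpd_daily,
            law,
            sub_spec,
            stratum_map=smap,
            history_years=samp_cfg.get("history_years", 0),
            history_events_per_year=samp_cfg.get("history_events_per_year", 0),
        )
        in_mask = stratum.mask[ev["cell_lat_idx"], ev["cell_lon_idx"]]
        events_parts.append(ev[in_mask])
        hist_in = hist.loc[stratum.mask[hist["cell_lat_idx"], hist["cell_lon_idx"]]] if len(hist) else hist
        history_parts.append(hist_in)
    events = pd.concat(events_parts, ignore_index=True)
    history = pd.concat(history_parts, ignore_index=True)
    events.to_csv(outdir / "fire_events.csv", index=False)
    history.to_csv(outdir / "fire_history.csv", index=False)

    ref_spec = synth.WorldSpec(**{**config.world, "years": spec.years,
                                  "seed": config.stage_seed("simulate") + 1})
    vm = config.vpd_marginal
    reference = synth.generate_vpd_daily(ref_spec, **vm)
    write_netcdf(reference, outdir / "vpd_reference.nc")
    gcm = config.gcm
    hist_vpd, fut_vpd = synth.generate_gcm_like(
        reference, gcm["bias_shift"], gcm["bias_scale"], gcm["future_delta"], ref_spec
    )
    write_netcdf(hist_vpd, outdir / "vpd_model_hist.nc")
    write_netcdf(fut_vpd, outdir / "vpd_model_future.nc")

    dens = config.density
    for kind, fname in (("population", "population.tif"), ("biomass", "biomass.tif")):
        da = synth.generate_density_raster(
            spec, kind, zero_fraction=dens["zero_fraction"], fine_ratio=dens["fine_ratio"]
        )
        raster.write_tiff(da, outdir / fname)
    return [outdir / n for n in _STAGE_OUTPUTS["simulate"](config)]


def _stage_vpd(config: RunConfig, outdir: Path) -> list[Path]:
    t_grid = read_netcdf(outdir / "air_temperature.nc")
    td_grid = read_netcdf(outdir / "dew_point.nc")
    vpd_daily = vpd_mod.daily_max_vpd(t_grid, td_grid, "dewpoint")
    write_netcdf(vpd_daily, outdir / "vpd_daily.nc")
    return [outdir / "vpd_daily.nc"]


def _stage_sample(config: RunConfig, outdir: Path) -> list[Path]:
    events = pd.read_csv(outdir / "fire_events.csv")
    history_df = pd.read_csv(outdir / "fire_history.csv")
    vpd_daily = read_netcdf(outdir / "vpd_daily.nc")
    strata = _build_strata(config, vpd_daily.shape[1:])
    history = sampling.build_burn_history(events, history_df)
    presences = sampling.match_presences(events, vpd_daily)
    parts = []
    seed = config.stage_seed("sample")
    for k, stratum in enumerate(strata):
        absences = sampling.sample_quasi_absences(
            events,
            vpd_daily,
            stratum,
            seed=seed + k,
            history=history,
            lookback_years=config.sampling.get("lookback_years", 5),
        )
        pres = presences[presences["stratum"] == stratum.stratum_id]
        parts.append(sampling.assemble_stratum_samples(pres, absences, seed=seed + 500 + k))
    samples = pd.concat(parts, ignore_index=True)
    samples.to_csv(outdir / "samples.csv", index=False)
    return [outdir / "samples.csv"]


def _stage_fit(config: RunConfig, outdir: Path) -> list[Path]:
    samples = pd.read_csv(outdir / "samples.csv")
    groups = {e["id"]: e.get("biome_group", "") for e in config.strata} or None
    table, medians, unfittable = model_mod.fit_all_strata(samples, biome_groups=groups)
    table.to_csv(outdir / "thresholds.csv", index=False)
    (outdir / "fit_summary.json").write_text(
        json.dumps({"medians": medians, "unfittable": unfittable}, indent=2)
    )
    return [outdir / "thresholds.csv", outdir / "fit_summary.json"]


def _stage_bias_correct(config: RunConfig, outdir: Path) -> list[Path]:
    reference = read_netcdf(outdir / "vpd_reference.nc")
    hist_vpd = read_netcdf(outdir / "vpd_model_hist.nc")
    fut_vpd = read_netcdf(outdir / "vpd_model_future.nc")
    bc = config.bias_correction
    maps = biascorr.fit_quantile_map_grid(
        hist_vpd, reference, n_quantiles=bc["n_quantiles"], by_month=bc["by_month"]
    )
    corrected_hist = biascorr.apply_quantile_map_grid(maps, hist_vpd)
    corrected_fut = biascorr.apply_quantile_map_grid(maps, fut_vpd)
    corrected_hist.name = "vpd_corrected_hist"
    corrected_fut.name = "vpd_corrected_future"
    write_netcdf(corrected_hist, outdir / "vpd_corrected_hist.nc")
    write_netcdf(corrected_fut, outdir / "vpd_corrected_future.nc")
    biascorr.quantile_maps_to_frame(maps).to_csv(outdir / "quantile_map.csv", index=False)
    return [outdir / "vpd_corrected_hist.nc", outdir / "vpd_corrected_future.nc", outdir / "quantile_map.csv"]


def _stage_exceedance(config: RunConfig, outdir: Path) -> list[Path]:
    thresholds_path = outdir / "thresholds.csv"
    if not thresholds_path.exists():
        raise StageError("exceedance requested but the fitted threshold table is missing")
    table = pd.read_csv(thresholds_path)
    vpd_daily = read_netcdf(outdir / "vpd_daily.nc")
    strata = _build_strata(config, vpd_daily.shape[1:])
    p50 = dict(zip(table["stratum"], table["vpd_p50"]))
    thr = thresholds_from_strata(strata, p50, vpd_daily.shape[1:])
    np.savetxt(outdir / "threshold_map.csv", thr, delimiter=",")

    source = f"fit:{config.config_hash()}"
    current = exceedance_days(vpd_daily, thr, period_label="current", threshold_source=source)
    hist = exceedance_days(
        read_netcdf(outdir / "vpd_corrected_hist.nc"), thr,
        period_label=config.epochs["present"], threshold_source=source,
    )
    fut = exceedance_days(
        read_netcdf(outdir / "vpd_corrected_future.nc"), thr,
        period_label=config.epochs["future"], threshold_source=source,
    )
    change = change_in_exceedance(fut, hist)
    change.attrs["scenario"] = config.scenario
    for da, name in ((current, "exceedance_current.nc"), (hist, "exceedance_hist.nc"),
                     (fut, "exceedance_future.nc"), (change, "exceedance_change.nc")):
        ds = da.to_dataset(name=da.name or "exceedance")
        ds.attrs.update(da.attrs)
        ds.to_netcdf(outdir / name, engine="scipy")
    return [outdir / n for n in ("threshold_map.csv", "exceedance_current.nc",
                                 "exceedance_hist.nc", "exceedance_future.nc", "exceedance_change.nc")]


def _read_2d(path: Path) -> xr.DataArray:
    with xr.open_dataset(path, engine="scipy") as ds:
        name = list(ds.data_vars)[0]
        da = ds[name].load()
        da.attrs.update({k: v for k, v in ds.attrs.items() if k not in da.attrs})
    return da


def _stage_exposure(config: RunConfig, outdir: Path) -> list[Path]:
    change = _read_2d(outdir / "exceedance_change.nc")
    outputs = []
    for kind, tif in (("population", "population.tif"), ("biomass", "biomass.tif")):
        fine = raster.read_tiff(outdir / tif)
        coarse = resample_density(fine, change)
        exp = compute_exposure(change, coarse, kind)
        out = outdir / f"exposure_{kind}.nc"
        ds = exp.to_dataset(name=exp.name)
        ds.attrs.update(exp.attrs)
        ds.to_netcdf(out, engine="scipy")
        outputs.append(out)
    return outputs


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "vpd": _stage_vpd,
    "sample": _stage_sample,
    "fit": _stage_fit,
    "bias_correct": _stage_bias_correct,
    "exceedance": _stage_exceedance,
    "exposure": _stage_exposure,
}

_STAGE_OUTPUTS = {
    "simulate": lambda c: ["air_temperature.nc", "dew_point.nc", "fire_events.csv",
                           "fire_history.csv", "vpd_reference.nc", "vpd_model_hist.nc",
                           "vpd_model_future.nc", "population.tif", "biomass.tif"],
    "vpd": lambda c: ["vpd_daily.nc"],
    "sample": lambda c: ["samples.csv"],
    "fit": lambda c: ["thresholds.csv", "fit_summary.json"],
    "bias_correct": lambda c: ["vpd_corrected_hist.nc", "vpd_corrected_future.nc", "quantile_map.csv"],
    "exceedance": lambda c: ["threshold_map.csv", "exceedance_current.nc", "exceedance_hist.nc",
                             "exceedance_future.nc", "exceedance_change.nc"],
    "exposure": lambda c: ["exposure_population.nc", "exposure_biomass.nc"],
}


# --- validation ------------------------------------------------------------

_EVENT_COLUMNS = {"cell_lat_idx", "cell_lon_idx", "date", "stratum"}
_SAMPLE_COLUMNS = {"vpd_kpa", "burned", "year", "stratum"}


def validate_io(path: str | Path, expected_format: str) -> list[str]:
    """Check a file against its expected on-disk convention.

    ``expected_format`` is one of ``netcdf``, ``events_csv``, ``samples_csv``
    or ``tiff``.  Returns a list of human-readable problems; an empty list
    means the file validates.  Malformed files are reported, never coerced.
    """
    path = Path(path)
    problems: list[str] = []
    if not path.exists():
        return [f"{path}: file does not exist"]
    try:
        if expected_format == "netcdf":
            with xr.open_dataset(path, engine="scipy") as ds:
                for name, var in ds.data_vars.items():
                    if "units" not in var.attrs and "units" not in ds.attrs:
                        problems.append(f"{path}: variable {name!r} missing units attribute")
                    for dim in var.dims:
                        if dim not in ("time", "lat", "lon", "y", "x"):
                            problems.append(f"{path}: variable {name!r} has unconventional dim {dim!r}")
        elif expected_format in ("events_csv", "samples_csv"):
            df = pd.read_csv(path)
            needed = _EVENT_COLUMNS if expected_format == "events_csv" else _SAMPLE_COLUMNS
            missing = needed - set(df.columns)
            if missing:
                problems.append(f"{path}: missing columns {sorted(missing)}")
            if expected_format == "samples_csv" and not missing:
                bad = set(df["burned"].unique()) - {0, 1}
                if bad:
                    problems.append(f"{path}: burned labels outside {{0,1}}: {sorted(bad)}")
        elif expected_format == "tiff":
            da = raster.read_tiff(path)
            if da.ndim != 2:
                problems.append(f"{path}: expected a 2-D raster, got {da.ndim}-D")
        else:
            problems.append(f"unknown expected format {expected_format!r}")
    except Exception as exc:  # malformed file: report, never coerce
        problems.append(f"{path}: failed to read as {expected_format}: {exc}")
    return problems
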