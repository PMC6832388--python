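"""End-to-end orchestration: config validation, staged run, manifest.

A single YAML (or dict) config drives the whole analysis: either a
``simulate`` block generating a synthetic world, or an ``inputs`` block of
raster paths.  The run emits, per stage, the artifacts a country-scale
study would table or plot: the city table and size spectrum, state-space
histograms, per-stratum NDVI-bin statistics, NDVI/city percentage curves,
city-vs-land trend comparisons, the regional summary table, and
size-conditioned city statistics, plus a manifest with a config hash and
per-artifact checksums for byte-level reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import numpy.ma as ma
import pandas as pd
import yaml

from . import budyko, cities, greenness, synthetic, trends
from .grid import GridRaster, read_raster, read_time_raster

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "DEFAULTS"]

DEFAULTS = {
    "seed": 0,
    "dn_threshold": 12,
    "connectivity": 8,
    "bin_width": 0.1,
    "spectrum_base_km2": 2.0,
    "trend_interval": [0.0, 1.0],
    "green_ratio_min": 2.0,
    "brown_band": 0.25,
    "state_space_bins": 40,
    "smoothing_bandwidth": 1.0,
}

_REQUIRED = {"out_dir"}
_KNOWN = set(DEFAULTS) | _REQUIRED | {"simulate", "inputs", "regions"}
_SIM_KEYS = {"ny", "nx", "n_years", "n_cities", "zipf_exponent", "regime", "resid_sd"}
_INPUT_KEYS = {"lights", "ndvi", "evap", "sensible", "precip",
               "abundance", "threatened"}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (flat keys plus one source block)."""

    raw: dict

    def __getitem__(self, key):
        return self.raw.get(key, DEFAULTS.get(key))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        report = validate_config(raw)
        if report["errors"]:
            raise ValueError("invalid config: " + "; ".join(report["errors"]))
        return cls(raw)


def validate_config(raw: dict) -> dict:
    """Check a config dict; returns {'errors': [...], 'warnings': [...]}."""
    errors: list[str] = []
    warnings: list[str] = []
    for key in raw:
        if key not in _KNOWN:
            warnings.append(f"unknown key {key!r}")
    for key in _REQUIRED:
        if key not in raw:
            errors.append(f"missing required key {key!r}")
    dn = raw.get("dn_threshold", DEFAULTS["dn_threshold"])
    if not (0 <= dn <= 63):
        errors.append(f"dn_threshold {dn} outside [0, 63]")
    if raw.get("connectivity", DEFAULTS["connectivity"]) not in (4, 8):
        errors.append("connectivity must be 4 or 8")
    bw = raw.get("bin_width", DEFAULTS["bin_width"])
    if not (0 < bw <= 1):
        errors.append(f"bin_width {bw} outside (0, 1]")
    if raw.get("spectrum_base_km2", DEFAULTS["spectrum_base_km2"]) <= 0:
        errors.append("spectrum_base_km2 must be positive")
    has_sim = "simulate" in raw
    has_inputs = "inputs" in raw
    if has_sim == has_inputs:
        errors.append("config needs exactly one of 'simulate' or 'inputs'")
    if has_sim and isinstance(raw["simulate"], dict):
        for key in raw["simulate"]:
            if key not in _SIM_KEYS:
                warnings.append(f"unknown simulate key {key!r}")
    if has_inputs:
        inp = raw["inputs"] or {}
        missing = _INPUT_KEYS - set(inp)
        if missing:
            errors.append(f"inputs missing layers: {sorted(missing)}")
        for name, path in inp.items():
            if not Path(path).exists():
                errors.append(f"input {name!r} not found: {path}")
    return {"errors": errors, "warnings": warnings}


def _load_world(cfg: PipelineConfig) -> dict:
    if "simulate" in cfg.raw:
        sim = dict(cfg.raw["simulate"] or {})
        return synthetic.make_world(seed=cfg["seed"], **sim)
    inp = cfg.raw["inputs"]
    lights = read_raster(inp["lights"], "lights")
    series = read_time_raster(inp["ndvi"], "ndvi")
    clim_vals = series.stack().mean(axis=0)
    ndvi_clim = series.grid.with_values(clim_vals, name="ndvi_clim")
    world = {
        "lights": lights,
        "ndvi_clim": ndvi_clim,
        "ndvi_series": series,
        "evap": read_raster(inp["evap"], "evap"),
        "sensible": read_raster(inp["sensible"], "sensible"),
        "precip": read_raster(inp["precip"], "precip"),
        "abundance": read_raster(inp["abundance"], "abundance"),
        "threatened": read_raster(inp["threatened"], "threatened"),
    }
    from .grid import pixel_area_km2

    world["areas"] = pixel_area_km2(lights)
    dn = ma.filled(ma.masked_invalid(lights.values), 0)
    world["city_mask"] = dn >= cfg["dn_threshold"]
    world["land_mask"] = np.ones(lights.shape, dtype=bool)
    world["truth"] = None
    return world


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run every stage and write all artifacts; returns paths and results."""
    if isinstance(config, dict):
        report = validate_config(config)
        if report["errors"]:
            raise ValueError("invalid config: " + "; ".join(report["errors"]))
        config = PipelineConfig(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    world = _load_world(config)
    artifacts: dict[str, Path] = {}

    def _stage(name):
        def fail(exc):
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return fail

    # -- cities -------------------------------------------------------------
    try:
        table = cities.extract_cities(world["lights"], config["dn_threshold"],
                                      config["connectivity"])
        table = cities.city_size(table, world["areas"])
        spectrum = cities.size_spectrum(table, config["spectrum_base_km2"])
    except Exception as exc:  # noqa: BLE001
        _stage("city_extraction")(exc)
    table.table.to_csv(out_dir / "cities.csv", index=False)
    artifacts["cities"] = out_dir / "cities.csv"
    pd.DataFrame({
        "bin_lo_km2": spectrum.edges_km2[:-1],
        "bin_hi_km2": spectrum.edges_km2[1:],
        "n_cities": spectrum.counts,
    }).to_csv(out_dir / "spectrum.csv", index=False)
    artifacts["spectrum"] = out_dir / "spectrum.csv"

    strata = greenness.StratumMask(city=world["city_mask"],
                                   land=world["land_mask"])

    # -- state space --------------------------------------------------------
    try:
        hist = budyko.embed(world["evap"], world["sensible"],
                            bins=config["state_space_bins"])
        hist_s = budyko.smooth(hist, config["smoothing_bandwidth"])
    except Exception as exc:  # noqa: BLE001
        _stage("state_space")(exc)
    hist.to_frame().to_csv(out_dir / "state_space.csv", index=False)
    hist_s.to_frame().to_csv(out_dir / "state_space_smoothed.csv", index=False)
    artifacts["state_space"] = out_dir / "state_space.csv"
    artifacts["state_space_smoothed"] = out_dir / "state_space_smoothed.csv"

    # -- NDVI-bin statistics ------------------------------------------------
    try:
        cv = greenness.coefficient_of_variability(world["ndvi_series"])
        stats_frames = [
            greenness.bin_stats(world["ndvi_clim"], world["abundance"],
                                world["threatened"], strata.stratum(s),
                                areas=world["areas"], cv=cv,
                                bin_width=config["bin_width"], stratum=s)
            for s in ("land", "city", "non_city")
        ]
        binstats = pd.concat(stats_frames, ignore_index=True)
        ndvi_pct = greenness.ndvi_percentage(world["ndvi_clim"], strata.land,
                                             areas=world["areas"],
                                             bin_width=config["bin_width"])
        city_pct = greenness.city_percentage(world["ndvi_clim"], strata.city,
                                             areas=world["areas"],
                                             bin_width=config["bin_width"])
    except Exception as exc:  # noqa: BLE001
        _stage("greenness_stats")(exc)
    binstats.to_csv(out_dir / "bin_stats.csv", index=False)
    ndvi_pct.to_csv(out_dir / "ndvi_percentage.csv", index=False)
    city_pct.to_csv(out_dir / "city_percentage.csv", index=False)
    artifacts["bin_stats"] = out_dir / "bin_stats.csv"
    artifacts["ndvi_percentage"] = out_dir / "ndvi_percentage.csv"
    artifacts["city_percentage"] = out_dir / "city_percentage.csv"

    # -- trends -------------------------------------------------------------
    try:
        comparison = trends.compare_trends(
            world["ndvi_series"], strata.city, strata.land,
            tuple(config["trend_interval"]), world["ndvi_clim"],
            areas=world["areas"], green_ratio_min=config["green_ratio_min"],
            brown_band=config["brown_band"])
    except Exception as exc:  # noqa: BLE001
        _stage("trend_analysis")(exc)
    comparison.to_frame().to_csv(out_dir / "trends.csv", index=False)
    artifacts["trends"] = out_dir / "trends.csv"

    # -- regional summary ---------------------------------------------------
    try:
        regions = config.raw.get("regions") or {"all": world["land_mask"]}
        taxa = {"vertebrates": (world["abundance"], world["threatened"])}
        summary = greenness.table1_summary(regions, taxa, strata, world["areas"])
        size_stats = greenness.size_conditioned_stats(
            table, spectrum, world["ndvi_clim"], world["abundance"],
            world["threatened"], areas=world["areas"])
    except Exception as exc:  # noqa: BLE001
        _stage("summary_tables")(exc)
    summary.to_csv(out_dir / "table1.csv")
    size_stats.to_csv(out_dir / "size_stats.csv", index=False)
    artifacts["table1"] = out_dir / "table1.csv"
    artifacts["size_stats"] = out_dir / "size_stats.csv"

    # -- manifest -----------------------------------------------------------
    cfg_clean = {k: v for k, v in config.raw.items() if k != "regions"}
    config_hash = hashlib.sha256(
        json.dumps(cfg_clean, sort_keys=True, default=str).encode()).hexdigest()
    checksums = {name: hashlib.sha256(path.read_bytes()).hexdigest()
                 for name, path in sorted(artifacts.items())}
    manifest = {
        "config_hash": config_hash,
        "seed": config["seed"],
        "artifact_checksums": checksums,
        "output_hash": hashlib.sha256(
            json.dumps(checksums, sort_keys=True).encode()).hexdigest(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = out_dir / "manifest.json"
    return {"artifacts": artifacts, "manifest": manifest,
            "comparison": comparison, "spectrum": spectrum,
            "cities": table, "bin_stats": binstats}
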