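"""Run configuration, validation, persistence and experiment composition.

A :class:`RunConfig` bundles the pattern grid, ventilator settings and the
virtual-animal parameters (either a named preset or explicit values), is
loadable from YAML with field-naming validation errors, and drives
:func:`run_experiment`, which executes the optional strength-duration
stage, the pattern sweep and the statistical analysis, writing CSV/JSON
artifacts plus a manifest (seed, config hash, version) that suffices to
reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .analysis import box_table, correlation_table, surface_table
from .evaluation import (
    BaselinePattern,
    GridConfig,
    GridError,
    baseline_stats,
    enumerate_grid,
    run_sweep,
)
from .scheduler import VentilatorSettings, plan_cycle
from .sdcurve import measure_curve
from .virtual_pig import ANIMAL_PRESETS, PigParams
from .waveforms import Direction, WaveformError

logger = logging.getLogger("phrenosweep")


class ConfigError(ValueError):
    """Invalid or out-of-range configuration; the message names the field."""


#: animal-specific defaults applied when a preset is selected
PRESET_OVERRIDES = {
    "animal_I": {
        "vent": {"mandatory_rate_per_min": 13.0, "t_insp_s": 1.4},
        "grid": {"start_voltage": 6.5, "end_voltage": 10.0,
                 "burst_rate_per_min": 13.0,
                 "baseline": {"direction": "ALT"}},
    },
    "animal_II": {
        "vent": {"mandatory_rate_per_min": 12.0, "t_insp_s": 1.5},
        "grid": {"start_voltage": 7.5, "end_voltage": 10.0,
                 "burst_rate_per_min": 12.0,
                 "baseline": {"direction": "BIP"}},
    },
}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated experiment definition."""

    preset: str = "animal_I"
    pig: PigParams = field(default_factory=PigParams)
    vent: VentilatorSettings = field(default_factory=VentilatorSettings)
    grid: GridConfig = field(default_factory=GridConfig)
    seed: int = 0
    breaths_per_pattern: int = 5
    run_sdcurve: bool = False
    sdcurve_widths_ms: tuple = (0.05, 0.10, 0.15, 0.20, 0.30, 0.50, 1.00)
    bip_total_width: bool = True

    def __post_init__(self) -> None:
        if self.breaths_per_pattern < 1:
            raise ConfigError("breaths_per_pattern: must be >= 1")
        if self.seed < 0:
            raise ConfigError("seed: must be >= 0")
        # the full schedule must be feasible before any stage runs
        plan_cycle(self.vent, self.grid.burst_duration_s)

    def to_dict(self) -> dict:
        def unpack(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: unpack(v)
                        for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Direction):
                return obj.value
            if isinstance(obj, (tuple, list)):
                return [unpack(v) for v in obj]
            return obj

        d = {
            "preset": self.preset,
            "pig": unpack(self.pig),
            "vent": unpack(self.vent),
            "grid": unpack(self.grid),
            "seed": self.seed,
            "breaths_per_pattern": self.breaths_per_pattern,
            "run_sdcurve": self.run_sdcurve,
            "sdcurve_widths_ms": list(self.sdcurve_widths_ms),
            "bip_total_width": self.bip_total_width,
        }
        # Direction enums inside grid
        d["grid"]["directions"] = [Direction(x).value for x in self.grid.directions]
        d["grid"]["baseline"]["direction"] = Direction(
            self.grid.baseline.direction
        ).value
        return d

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical JSON form of the configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _build_section(cls, data: dict, section: str):
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigError(f"{section}: {exc}") from exc
    except (GridError, WaveformError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def from_dict(data: dict) -> RunConfig:
    """Build and validate a :class:`RunConfig` from plain dictionaries.

    Preset defaults are applied first and explicit sections override them.
    """
    data = dict(data or {})
    preset = data.pop("preset", "animal_I")
    if preset not in ANIMAL_PRESETS:
        raise ConfigError(
            f"preset: unknown preset {preset!r}; expected one of "
            f"{sorted(ANIMAL_PRESETS)}"
        )
    overrides = PRESET_OVERRIDES[preset]

    pig_data = {**dataclasses.asdict(ANIMAL_PRESETS[preset]),
                **data.pop("pig", {})}
    vent_data = {**overrides["vent"], **data.pop("vent", {})}
    grid_data = {**overrides["grid"], **data.pop("grid", {})}
    baseline_data = grid_data.pop("baseline", {})
    if isinstance(baseline_data, dict):
        baseline_data = dict(baseline_data)
        if "direction" in baseline_data:
            baseline_data["direction"] = Direction(baseline_data["direction"])
        baseline = _build_section(BaselinePattern, baseline_data, "grid.baseline")
    else:
        baseline = baseline_data
    if "directions" in grid_data:
        grid_data["directions"] = tuple(
            Direction(d) for d in grid_data["directions"]
        )
    for key in ("frequencies_hz", "widths_ms", "slope_times_s"):
        if key in grid_data:
            grid_data[key] = tuple(grid_data[key])

    pig = _build_section(PigParams, pig_data, "pig")
    vent = _build_section(VentilatorSettings, vent_data, "vent")
    grid = _build_section(GridConfig, {**grid_data, "baseline": baseline}, "grid")

    known = {"seed", "breaths_per_pattern", "run_sdcurve", "sdcurve_widths_ms",
             "bip_total_width"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
    if "sdcurve_widths_ms" in data:
        data["sdcurve_widths_ms"] = tuple(data["sdcurve_widths_ms"])
    return RunConfig(preset=preset, pig=pig, vent=vent, grid=grid, **data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    return from_dict(raw)


def run_experiment(config: RunConfig, out_dir, seed: Optional[int] = None) -> Path:
    """Execute the configured stages and persist all artifacts.

    Stages: strength-duration measurement (optional), pattern sweep,
    statistical analysis.  Writes under ``out_dir``: ``manifest.json``,
    ``sdcurve.csv``/``sdcurve_fit.json``, ``sweep.csv``,
    ``baseline_stats.json``, ``correlations.csv``, ``boxstats.csv`` and one
    ``surface_<subgroup>.csv`` per subgroup.  Re-running with an identical
    configuration and seed reproduces every CSV byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    manifest = {
        "version": __version__,
        "seed": seed,
        "preset": config.preset,
        "config_sha256": config_hash(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    config.save(out / "config.yaml")

    t_start = time.perf_counter()
    if config.run_sdcurve:
        curve = measure_curve(
            config.sdcurve_widths_ms, config.pig,
            config.grid.baseline.direction, config.vent,
            bip_total_width=config.bip_total_width,
        )
        curve.export(out / "sdcurve.csv", out / "sdcurve_fit.json")
        logger.info("sdcurve stage done in %.1f s", time.perf_counter() - t_start)

    t_stage = time.perf_counter()
    grid = enumerate_grid(config.grid)
    result = run_sweep(grid, config.pig, config.vent, seed,
                       breaths_per_pattern=config.breaths_per_pattern,
                       bip_total_width=config.bip_total_width)
    result.save_csv(out / "sweep.csv")
    baselines = result.baseline_records()
    if len(baselines) >= 2:
        stats = baseline_stats(result)
        stats_doc = {
            "mean_ml_per_kg": stats.mean_ml_per_kg,
            "sd_ml_per_kg": stats.sd_ml_per_kg,
            "trend_r": stats.trend_r,
            "trend_p": stats.trend_p,
            "trend_detected": stats.trend_detected,
        }
    else:  # degenerate run (empty grid): a single baseline, no drift series
        stats_doc = {
            "mean_ml_per_kg": baselines[0].mean_vt,
            "sd_ml_per_kg": None,
            "trend_r": None,
            "trend_p": None,
            "trend_detected": False,
        }
    (out / "baseline_stats.json").write_text(json.dumps(stats_doc, indent=1))
    logger.info("sweep stage done in %.1f s", time.perf_counter() - t_stage)

    t_stage = time.perf_counter()
    df = result.to_frame()
    if len(result.pattern_records()) > 0:
        correlation_table(df).to_csv(out / "correlations.csv", index=False)
        box = box_table(df)
        box.to_csv(out / "boxstats.csv", index=False)
        for subgroup in box["subgroup"]:
            name = subgroup.replace("/", "_").replace(".", "p")
            surface_table(df, subgroup).to_csv(
                out / f"surface_{name}.csv", index=False
            )
    logger.info("analysis stage done in %.1f s", time.perf_counter() - t_stage)
    return out
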