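"""YAML run configuration binding all modules.

One config file describes one run: acoustic medium, sonication protocol,
thermal constants, pipeline settings, optional synthetic-generator block
and file paths.  All values are SI unless the field name says otherwise
(``pixel_pitch_um``, ``roi_fwhm_um``, ``response_fwhm_spatial_um``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .acoustic import Medium, SonicationConfig
from .bioheat import ThermalProperties
from .pipeline import PipelineConfig
from .quench import QuenchCalibration
from .synth import SynthConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "config_to_dict"]


class ConfigError(ValueError):
    """Raised for unknown keys or invalid values in a run configuration."""


@dataclass
class RunConfig:
    sonication: SonicationConfig
    medium: Medium
    thermal: ThermalProperties
    pipeline: PipelineConfig
    synth: Optional[SynthConfig] = None
    calibration: Optional[QuenchCalibration] = None
    movie_path: Optional[str] = None
    calibration_path: Optional[str] = None
    output_dir: Optional[str] = None
    log_level: str = "INFO"


def _build(cls, section: dict[str, Any] | None, name: str):
    section = dict(section or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in config section {name!r}")
    if "focus_position" in section and section["focus_position"] is not None:
        section["focus_position"] = tuple(section["focus_position"])
    for key in ("focus_pixel", "control_roi"):
        if key in section and section[key] is not None:
            section[key] = tuple(section[key])
    try:
        return cls(**section)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid config section {name!r}: {e}") from e


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {
        "sonication", "medium", "thermal", "pipeline", "synth", "calibration",
        "paths", "log_level",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level config key(s) {sorted(unknown)}")
    paths = raw.get("paths") or {}
    cal = None
    if raw.get("calibration"):
        cal = _build(QuenchCalibration, raw["calibration"], "calibration")
    cfg = RunConfig(
        sonication=_build(SonicationConfig, raw.get("sonication"), "sonication"),
        medium=_build(Medium, raw.get("medium"), "medium"),
        thermal=_build(ThermalProperties, raw.get("thermal"), "thermal"),
        pipeline=_build(PipelineConfig, raw.get("pipeline"), "pipeline"),
        synth=_build(SynthConfig, raw["synth"], "synth") if "synth" in raw else None,
        calibration=cal,
        movie_path=paths.get("movie"),
        calibration_path=paths.get("calibration"),
        output_dir=paths.get("output"),
        log_level=str(raw.get("log_level", "INFO")),
    )
    for label, p in (("movie", cfg.movie_path), ("calibration", cfg.calibration_path)):
        if p is not None and not Path(p).exists():
            raise ConfigError(f"paths.{label} does not exist: {p}")
    return cfg


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    """Echo a run configuration as plain nested dicts (JSON/YAML friendly)."""

    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    out: dict[str, Any] = {
        "sonication": enc(cfg.sonication),
        "medium": enc(cfg.medium),
        "thermal": enc(cfg.thermal),
        "pipeline": enc(cfg.pipeline),
        "log_level": cfg.log_level,
        "paths": {
            "movie": cfg.movie_path,
            "calibration": cfg.calibration_path,
            "output": cfg.output_dir,
        },
    }
    if cfg.synth is not None:
        out["synth"] = enc(cfg.synth)
    if cfg.calibration is not None:
        out["calibration"] = enc(cfg.calibration)
    return out
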