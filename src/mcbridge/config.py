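"""Run configuration: TOML loading, validation and the packaged defaults.

The packaged ``device_defaults.toml`` carries the rig's full parameter set
(tube geometry, compliance fit, 120/80 mmHg at 60 bpm operating point,
compression schedule, sweep grids) so the standard scenario is a one-command
run.  Every output artifact embeds ``config_hash`` and the seed, making runs
reproducible from their own metadata.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

from .device_waveforms import CardiacParams, CompressionSchedule
from .tube_mechanics import PressureDiameterFit, TubeGeometry

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config"]


class ConfigError(ValueError):
    """Configuration invalid; message carries the offending field path."""


@dataclass(frozen=True)
class SweepGrids:
    compression_levels: tuple[float, ...] = (0.0, 0.5, 0.8, 1.0)
    q2_grid_mmHg: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    q2_setpoint_mmHg: float = 0.0
    sweep_level: float = 0.0


@dataclass(frozen=True)
class RunSettings:
    duration_s: float = 5.0
    sample_rate_hz: float = 1000.0
    noise_sd_mmHg: float = 0.0
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"


@dataclass(frozen=True)
class RunConfig:
    geometry: TubeGeometry
    fit: PressureDiameterFit
    cardiac: CardiacParams
    schedule: CompressionSchedule
    sweep: SweepGrids = field(default_factory=SweepGrids)
    run: RunSettings = field(default_factory=RunSettings)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        """sha256 over the result-determining parameters (first 16 hex chars).

        The output directory and log level do not influence computed values
        and are excluded, so reruns into different directories hash alike.
        """
        payload = self.to_dict()
        payload["run"].pop("out_dir", None)
        payload["run"].pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_section(cls, section: str, data: dict, allowed: set[str]):
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"{section}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def _from_mapping(raw: dict) -> RunConfig:
    fit_raw = dict(raw.get("fit", {}))
    if "validity_range" in fit_raw:
        fit_raw["validity_range"] = tuple(fit_raw["validity_range"])
    sweep_raw = dict(raw.get("sweep", {}))
    for key in ("compression_levels", "q2_grid_mmHg"):
        if key in sweep_raw:
            sweep_raw[key] = tuple(float(v) for v in sweep_raw[key])
    return RunConfig(
        geometry=_build_section(
            TubeGeometry, "geometry", raw.get("geometry", {}),
            {"R0_mm", "Ri_mm", "lambda_z"},
        ),
        fit=_build_section(
            PressureDiameterFit, "fit", fit_raw,
            {"a", "b", "c", "d", "e", "pressure_unit", "validity_range"},
        ),
        cardiac=_build_section(
            CardiacParams, "cardiac", raw.get("cardiac", {}),
            {"systolic", "diastolic", "heart_rate", "mean_flow_ml_min",
             "viscosity_pa_s", "systole_fraction"},
        ),
        schedule=_build_section(
            CompressionSchedule, "schedule", raw.get("schedule", {}),
            {"level", "onset_phase", "duration_phase", "overshoot_gain",
             "overshoot_damping", "overshoot_freq"},
        ),
        sweep=_build_section(
            SweepGrids, "sweep", sweep_raw,
            {"compression_levels", "q2_grid_mmHg", "q2_setpoint_mmHg", "sweep_level"},
        ),
        run=_build_section(
            RunSettings, "run", raw.get("run", {}),
            {"duration_s", "sample_rate_hz", "noise_sd_mmHg", "seed",
             "out_dir", "log_level"},
        ),
    )


def _default_mapping() -> dict:
    ref = resources.files("mcbridge").joinpath("data/device_defaults.toml")
    return tomllib.loads(ref.read_text(encoding="utf-8"))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration.

    Partial files are allowed: any key not given falls back to the packaged
    default parameter set.
    """
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"{path}: not valid TOML: {exc}") from exc
    merged = _default_mapping()
    for section, values in raw.items():
        if not isinstance(values, dict):
            raise ConfigError(f"{section}: expected a table of keys")
        merged.setdefault(section, {}).update(values)
    return _from_mapping(merged)


def default_config() -> RunConfig:
    """The packaged rig default parameter set."""
    return _from_mapping(_default_mapping())
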