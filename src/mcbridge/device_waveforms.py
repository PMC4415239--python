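"""Synthetic pressure channels emulating the in-vitro bridge-compression rig.

The physical rig pumps a blood-analogue fluid through a silicone vessel held
in a pressurized chamber while motor-driven blocks squeeze the vessel once
per cardiac cycle, in systole.  Pressure transducers at the chamber inlet and
outlet record the proximal and distal internal pressures; the chamber
pressure is the external wall pressure q2.

This module reproduces the *measured channels* of that rig, not its fluid
dynamics: a 120/80 mmHg pulsatile baseline at 60 bpm, a proximal
"water-hammer" overshoot at compression onset whose amplitude scales with
the compression (oppression) level, an unchanged distal wave, and a constant
chamber pressure.  Everything is deterministic given a seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Union

import numpy as np
import pandas as pd

__all__ = [
    "CardiacParams",
    "CompressionSchedule",
    "PressureChannels",
    "ChannelFileError",
    "MalformedHeaderError",
    "MissingColumnError",
    "NonUniformGridError",
    "baseline_wave",
    "synthesize_channels",
    "write_channels",
    "read_channels",
]

ArrayLike = Union[float, np.ndarray]

_MAGIC = "mcbridge-channels v1"
_COLUMNS = ["t_s", "q1_prox_mmHg", "q1_dist_mmHg", "q2_mmHg"]


class ChannelFileError(ValueError):
    """Base class for channel-CSV format errors."""


class MalformedHeaderError(ChannelFileError):
    """Header comment block missing, wrong magic line, or unparseable metadata."""


class MissingColumnError(ChannelFileError):
    """A required channel column is absent."""


class NonUniformGridError(ChannelFileError):
    """Sample times are not a strictly increasing uniform grid."""


@dataclass(frozen=True)
class CardiacParams:
    """Cardiac operating point of the rig.

    ``mean_flow_ml_min`` and ``viscosity_pa_s`` describe the working fluid
    and pump setting; they are carried as metadata and do not enter the
    pressure or stress computations.
    """

    systolic: float = 120.0
    diastolic: float = 80.0
    heart_rate: float = 60.0
    mean_flow_ml_min: float = 205.0
    viscosity_pa_s: float = 3.8e-3
    systole_fraction: float = 0.35

    def __post_init__(self) -> None:
        if not (self.systolic > self.diastolic > 0):
            raise ValueError(
                f"require systolic > diastolic > 0, got "
                f"systolic={self.systolic}, diastolic={self.diastolic}"
            )
        if not self.heart_rate > 0:
            raise ValueError(f"heart_rate must be positive, got {self.heart_rate}")
        if not 0 < self.systole_fraction < 1:
            raise ValueError(
                f"systole_fraction must be in (0, 1), got {self.systole_fraction}"
            )

    @property
    def period_s(self) -> float:
        """Cardiac cycle length in seconds."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class CompressionSchedule:
    """Systole-synchronized bridge compression and its proximal overshoot.

    ``level`` is the oppression degree in [0, 1] (the rig's 0/50/80/100%
    presets are level 0, 0.5, 0.8, 1.0).  The water-hammer overshoot added to
    the proximal channel while the blocks are engaged is a damped rectified
    sinusoid, amplitude linear in level:

        overshoot_gain * level * exp(-overshoot_damping * tau) *
            |sin(2*pi*overshoot_freq * tau)|

    with tau the time since compression onset within the cycle.
    """

    level: float
    onset_phase: float = 0.0
    duration_phase: float = 0.35
    overshoot_gain: float = 35.0
    overshoot_damping: float = 12.0
    overshoot_freq: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"level must lie in [0, 1], got {self.level}")
        if self.onset_phase < 0 or self.duration_phase < 0:
            raise ValueError("onset_phase and duration_phase must be non-negative")
        if self.overshoot_gain < 0 or self.overshoot_damping < 0 or self.overshoot_freq < 0:
            raise ValueError("overshoot parameters must be non-negative")


@dataclass
class PressureChannels:
    """Sampled rig channels on a uniform time grid.

    Attributes
    ----------
    t : ndarray
        Sample times (s), strictly increasing, uniform.
    q1_prox, q1_dist : ndarray
        Internal pressure at the chamber inlet / outlet (mmHg).
    q2 : ndarray
        External chamber pressure (mmHg), non-negative.
    meta : dict
        Generation parameters, seed and period; written to file headers.
    """

    t: np.ndarray
    q1_prox: np.ndarray
    q1_dist: np.ndarray
    q2: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q1_prox = np.asarray(self.q1_prox, dtype=float)
        self.q1_dist = np.asarray(self.q1_dist, dtype=float)
        self.q2 = np.asarray(self.q2, dtype=float)
        n = self.t.size
        if not (self.q1_prox.size == self.q1_dist.size == self.q2.size == n):
            raise ValueError("all channels must have the same length as t")
        _check_uniform_grid(self.t)
        if np.any(self.q2 < 0):
            raise ValueError("external chamber pressure q2 must be non-negative")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "q1_prox_mmHg": self.q1_prox,
                "q1_dist_mmHg": self.q1_dist,
                "q2_mmHg": self.q2,
            }
        )


def _check_uniform_grid(t: np.ndarray) -> None:
    if t.size < 2:
        raise NonUniformGridError("need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise NonUniformGridError("sample times must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise NonUniformGridError("sample times must form a uniform grid")


def baseline_wave(params: CardiacParams, t: ArrayLike) -> ArrayLike:
    """Periodic arterial-style pressure wave hitting systolic/diastolic exactly.

    Within each cycle the systolic fraction carries a half-sine pulse rising
    from diastolic to systolic and back; the remainder of the cycle relaxes
    exponentially toward diastolic from the end-systolic value.  Because the
    half-sine returns exactly to diastolic at end-systole, the relaxation
    segment equals the diastolic pressure, keeping the wave continuous and
    its extrema exact.
    """
    t = np.asarray(t, dtype=float)
    period = params.period_s
    t_sys = params.systole_fraction * period
    phase = np.mod(t, period)
    pulse = params.diastolic + (params.systolic - params.diastolic) * np.sin(
        np.pi * phase / t_sys
    )
    wave = np.where(phase < t_sys, pulse, params.diastolic)
    return wave if wave.ndim else float(wave)


def _overshoot_wave(
    params: CardiacParams, schedule: CompressionSchedule, t: np.ndarray
) -> np.ndarray:
    """Proximal water-hammer term, active while the blocks are engaged."""
    period = params.period_s
    if schedule.onset_phase + schedule.duration_phase > params.systole_fraction + 1e-9:
        raise ValueError(
            "compression must fall within systole: onset_phase + duration_phase "
            f"({schedule.onset_phase + schedule.duration_phase:.4g}) exceeds "
            f"systole_fraction ({params.systole_fraction})"
        )
    tau = np.mod(t, period) - schedule.onset_phase * period
    # float-mod jitter (~1e-16 * t) must not flip boundary samples in and out
    # of the gate between cycles
    eps = 1e-9 * period
    active = (tau >= -eps) & (tau <= schedule.duration_phase * period + eps)
    ring = (
        schedule.overshoot_gain
        * schedule.level
        * np.exp(-schedule.overshoot_damping * tau)
        * np.abs(np.sin(2.0 * np.pi * schedule.overshoot_freq * tau))
    )
    return np.where(active, ring, 0.0)


def synthesize_channels(
    params: CardiacParams,
    schedule: CompressionSchedule,
    q2_setpoint: float = 0.0,
    duration: float = 5.0,
    sample_rate: float = 1000.0,
    seed: int | None = 0,
    noise_sd: float = 0.0,
) -> PressureChannels:
    """Generate the rig's three pressure channels for one run.

    The distal channel is the undisturbed baseline wave (compression leaves
    it unchanged); the proximal channel adds the water-hammer overshoot
    during compression; q2 is the constant chamber setpoint.  Gaussian
    measurement noise of standard deviation ``noise_sd`` (mmHg) is drawn
    independently per internal channel from ``numpy.random.default_rng(seed)``,
    so identical arguments give bitwise-identical output.

    Raises
    ------
    ValueError
        If duration spans fewer than two cardiac cycles, sample_rate is
        below 100 Hz, noise_sd is negative, or q2_setpoint is negative.
    """
    if duration < 2.0 * params.period_s:
        raise ValueError(
            f"duration {duration} s must cover at least two cycles "
            f"({2 * params.period_s} s)"
        )
    if sample_rate < 100.0:
        raise ValueError(f"sample_rate must be >= 100 Hz, got {sample_rate}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if q2_setpoint < 0:
        raise ValueError(f"q2_setpoint must be non-negative, got {q2_setpoint}")

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    base = baseline_wave(params, t)
    q1_dist = base.copy()
    q1_prox = base + _overshoot_wave(params, schedule, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q1_prox = q1_prox + rng.normal(0.0, noise_sd, n)
        q1_dist = q1_dist + rng.normal(0.0, noise_sd, n)
    q2 = np.full(n, float(q2_setpoint))

    meta = {
        "generator": "mcbridge.device_waveforms.synthesize_channels",
        "version": 1,
        "seed": seed,
        "noise_sd_mmHg": noise_sd,
        "q2_setpoint_mmHg": q2_setpoint,
        "duration_s": duration,
        "sample_rate_hz": sample_rate,
        "period_s": params.period_s,
        "cardiac": {
            "systolic": params.systolic,
            "diastolic": params.diastolic,
            "heart_rate": params.heart_rate,
            "mean_flow_ml_min": params.mean_flow_ml_min,
            "viscosity_pa_s": params.viscosity_pa_s,
            "systole_fraction": params.systole_fraction,
        },
        "schedule": {
            "level": schedule.level,
            "onset_phase": schedule.onset_phase,
            "duration_phase": schedule.duration_phase,
            "overshoot_gain": schedule.overshoot_gain,
            "overshoot_damping": schedule.overshoot_damping,
            "overshoot_freq": schedule.overshoot_freq,
        },
    }
    return PressureChannels(t=t, q1_prox=q1_prox, q1_dist=q1_dist, q2=q2, meta=meta)


def write_channels(channels: PressureChannels, path) -> None:
    """Write channels as CSV with a '#'-prefixed JSON metadata header.

    Layout: a magic line, one JSON metadata line, then the four columns
    ``t_s,q1_prox_mmHg,q1_dist_mmHg,q2_mmHg``.  Floats are written with
    shortest round-trip repr, so read_channels recovers them exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {_MAGIC}\n")
        fh.write("# " + json.dumps(channels.meta, sort_keys=True) + "\n")
        channels.to_frame().to_csv(fh, index=False)


def read_channels(path) -> PressureChannels:
    """Read a channel CSV written by :func:`write_channels`.

    Raises
    ------
    MalformedHeaderError
        Missing/garbled magic line or metadata JSON.
    MissingColumnError
        Any of the four required columns absent.
    NonUniformGridError
        Time grid not strictly increasing and uniform.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines or lines[0].strip() != f"# {_MAGIC}":
        raise MalformedHeaderError(
            f"first line must be '# {_MAGIC}'"
        )
    meta_lines = []
    body_start = 1
    for i, line in enumerate(lines[1:], start=1):
        if line.startswith("#"):
            meta_lines.append(line[1:].strip())
            body_start = i + 1
        else:
            break
    if not meta_lines:
        raise MalformedHeaderError("metadata comment line missing after magic line")
    try:
        meta = json.loads("\n".join(meta_lines))
    except json.JSONDecodeError as exc:
        raise MalformedHeaderError(f"metadata is not valid JSON: {exc}") from exc

    body = "\n".join(lines[body_start:])
    try:
        frame = pd.read_csv(io.StringIO(body))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ChannelFileError(f"could not parse CSV body: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise MissingColumnError(f"missing required column(s): {', '.join(missing)}")
    t = frame["t_s"].to_numpy(dtype=float)
    _check_uniform_grid(t)
    return PressureChannels(
        t=t,
        q1_prox=frame["q1_prox_mmHg"].to_numpy(dtype=float),
        q1_dist=frame["q1_dist_mmHg"].to_numpy(dtype=float),
        q2=frame["q2_mmHg"].to_numpy(dtype=float),
        meta=meta,
    )
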