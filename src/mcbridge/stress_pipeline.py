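"""Pressure channels -> inner-wall hoop stress -> summaries and sweeps.

Per sample the chain is: transmural pressure p = q1 - q2, loaded external
diameter from the compliance quartic, then the inner-wall Lamé stress.  Each
measuring site uses its own internal pressure (proximal: chamber inlet,
distal: chamber outlet) against the common chamber pressure q2.

Summaries follow the rig's reporting convention: the arithmetic mean and the
oscillatory value (maximum minus minimum) of the stress over a window of
complete cardiac cycles taken from the end of the record, discarding the
startup portion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .device_waveforms import (
    CardiacParams,
    CompressionSchedule,
    PressureChannels,
    synthesize_channels,
)
from .tube_mechanics import (
    DEFAULT_FIT,
    DEFAULT_GEOMETRY,
    CollapsedWallError,
    PressureDiameterFit,
    PressurePair,
    TubeGeometry,
    external_diameter,
    hoop_stress_inner,
)

__all__ = [
    "SITES",
    "HoopStressSeries",
    "StressSummary",
    "SweepResult",
    "stress_series",
    "summarize",
    "compression_sweep",
    "external_pressure_sweep",
    "write_sweep",
]

SITES = ("proximal", "distal")

#: Complete cardiac cycles summarized, taken from the end of the record.
DEFAULT_WINDOW_CYCLES = 2

#: Repeats averaged per condition when measurement noise is enabled.
NOISY_SWEEP_REPEATS = 5


@dataclass
class HoopStressSeries:
    """Inner-wall hoop stress over time at one measuring site."""

    t: np.ndarray
    sigma: np.ndarray
    site: str
    period_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.t.size != self.sigma.size:
            raise ValueError("t and sigma must have the same length")
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError("hoop stress series contains non-finite values")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")


@dataclass(frozen=True)
class StressSummary:
    """Mean and oscillatory (max - min) hoop stress for one condition and site."""

    site: str
    condition: float
    mean: float
    oscillatory: float
    sigma_min: float
    sigma_max: float

    def __post_init__(self) -> None:
        if self.oscillatory < 0:
            raise ValueError("oscillatory value cannot be negative")
        if not self.sigma_min - 1e-9 <= self.mean <= self.sigma_max + 1e-9:
            raise ValueError("mean must lie between series min and max")


@dataclass
class SweepResult:
    """Per-condition summaries plus named boolean trend verdicts.

    ``verdicts`` values are True/False, or None when a trend is not
    evaluable (fewer than two conditions).
    """

    mode: str
    conditions: list[float]
    summaries: list[StressSummary]
    verdicts: dict[str, bool | None]
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": [s.condition for s in self.summaries],
                "site": [s.site for s in self.summaries],
                "mean_mmHg": [s.mean for s in self.summaries],
                "oscillatory_mmHg": [s.oscillatory for s in self.summaries],
            }
        )

    def summary(self, site: str, condition: float) -> StressSummary:
        for s in self.summaries:
            if s.site == site and s.condition == condition:
                return s
        raise KeyError(f"no summary for site={site!r}, condition={condition}")

    @property
    def all_verdicts_pass(self) -> bool:
        return all(v is True for v in self.verdicts.values())


def stress_series(
    channels: PressureChannels,
    site: str,
    fit: PressureDiameterFit = DEFAULT_FIT,
    geometry: TubeGeometry = DEFAULT_GEOMETRY,
) -> HoopStressSeries:
    """Inner-wall hoop stress time series for one measuring site.

    Per sample: p = q1 - q2 -> d0 from the compliance fit -> r0 = d0/2 ->
    inner-wall Lamé stress.  Domain failures (collapsed wall) are re-raised
    with the index of the first failing sample.
    """
    if site not in SITES:
        raise ValueError(f"site must be one of {SITES}, got {site!r}")
    q1 = channels.q1_prox if site == "proximal" else channels.q1_dist
    q2 = channels.q2
    p = q1 - q2
    r0 = np.asarray(external_diameter(p, fit), dtype=float) / 2.0
    bad = np.flatnonzero(r0**2 <= geometry.k_mm2)
    if bad.size:
        raise CollapsedWallError(
            f"wall collapse at sample index {bad[0]} (t={channels.t[bad[0]]:.6g} s): "
            f"r0={r0[bad[0]]:.6g} mm"
        )
    sigma = hoop_stress_inner(r0, PressurePair(q1, q2), geometry)
    return HoopStressSeries(
        t=channels.t,
        sigma=np.asarray(sigma, dtype=float),
        site=site,
        period_s=channels.meta.get("period_s"),
        meta=dict(channels.meta),
    )


def summarize(series: HoopStressSeries, window: int = DEFAULT_WINDOW_CYCLES) -> StressSummary:
    """Mean and oscillatory value over the last ``window`` complete cycles.

    Restricting to trailing whole cycles discards the startup transient and
    makes the statistics phase-invariant for periodic input.

    Raises
    ------
    ValueError
        If the series has no known period or spans fewer than ``window``
        complete cycles.
    """
    if window < 1:
        raise ValueError("window must be at least one cycle")
    if series.period_s is None:
        raise ValueError("series period unknown; cannot delimit complete cycles")
    dt = series.t[1] - series.t[0]
    n_per_cycle = int(round(series.period_s / dt))
    n_needed = window * n_per_cycle
    if n_needed > series.sigma.size:
        raise ValueError(
            f"series has {series.sigma.size} samples, fewer than the "
            f"{n_needed} required for {window} complete cycles"
        )
    tail = series.sigma[-n_needed:]
    smin = float(np.min(tail))
    smax = float(np.max(tail))
    return StressSummary(
        site=series.site,
        condition=float(series.meta.get("condition", np.nan)),
        mean=float(np.mean(tail)),
        oscillatory=smax - smin,
        sigma_min=smin,
        sigma_max=smax,
    )


def _strictly_increasing(x: Sequence[float]) -> bool | None:
    if len(x) < 2:
        return None
    return bool(np.all(np.diff(x) > 0))


def _strictly_decreasing(x: Sequence[float]) -> bool | None:
    if len(x) < 2:
        return None
    return bool(np.all(np.diff(x) < 0))


def _condition_summaries(
    conditions: Sequence[float],
    make_channels,
    fit: PressureDiameterFit,
    geometry: TubeGeometry,
    window: int,
    noise_sd: float,
    seed: int,
) -> list[StressSummary]:
    """One averaged StressSummary per condition and site.

    Noise-free runs are single-shot; with noise, means/oscillatory values are
    averaged over NOISY_SWEEP_REPEATS independent seeds per condition so that
    trend verdicts compare per-condition expectations rather than single draws.
    """
    repeats = NOISY_SWEEP_REPEATS if noise_sd > 0 else 1
    out: list[StressSummary] = []
    for j, cond in enumerate(conditions):
        per_site: dict[str, list[StressSummary]] = {s: [] for s in SITES}
        for rep in range(repeats):
            ch = make_channels(cond, seed + 1000 * j + rep)
            ch.meta["condition"] = float(cond)
            for site in SITES:
                per_site[site].append(summarize(stress_series(ch, site, fit, geometry), window))
        for site in SITES:
            group = per_site[site]
            out.append(
                StressSummary(
                    site=site,
                    condition=float(cond),
                    mean=float(np.mean([s.mean for s in group])),
                    oscillatory=float(np.mean([s.oscillatory for s in group])),
                    sigma_min=float(np.mean([s.sigma_min for s in group])),
                    sigma_max=float(np.mean([s.sigma_max for s in group])),
                )
            )
    return out


def compression_sweep(
    levels: Sequence[float] = (0.0, 0.5, 0.8, 1.0),
    params: CardiacParams = CardiacParams(),
    fit: PressureDiameterFit = DEFAULT_FIT,
    geometry: TubeGeometry = DEFAULT_GEOMETRY,
    q2_setpoint: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    schedule_template: CompressionSchedule | None = None,
    duration: float = 5.0,
    sample_rate: float = 1000.0,
    window: int = DEFAULT_WINDOW_CYCLES,
) -> SweepResult:
    """Sweep the bridge-compression level and judge the proximal/distal trends.

    Verdicts
    --------
    proximal_mean_increasing
        Mean proximal stress strictly increases with level.
    distal_mean_stable
        Mean distal stress varies by less than 2% across levels.
    proximal_oscillatory_increasing
        Proximal oscillatory value strictly increases with level.
    proximal_exceeds_distal_oscillatory
        Proximal oscillatory value exceeds the distal one at every
        nonzero level.
    """
    levels = [float(v) for v in levels]
    if len(levels) < 1:
        raise ValueError("need at least one compression level")
    tmpl = schedule_template or CompressionSchedule(level=0.0)

    def make(level: float, run_seed: int) -> PressureChannels:
        sched = CompressionSchedule(
            level=level,
            onset_phase=tmpl.onset_phase,
            duration_phase=tmpl.duration_phase,
            overshoot_gain=tmpl.overshoot_gain,
            overshoot_damping=tmpl.overshoot_damping,
            overshoot_freq=tmpl.overshoot_freq,
        )
        return synthesize_channels(
            params, sched, q2_setpoint, duration, sample_rate, run_seed, noise_sd
        )

    summaries = _condition_summaries(levels, make, fit, geometry, window, noise_sd, seed)
    prox = [s for s in summaries if s.site == "proximal"]
    dist = [s for s in summaries if s.site == "distal"]

    dist_means = np.array([s.mean for s in dist])
    if len(dist_means) >= 2:
        ref = np.mean(np.abs(dist_means))
        spread = float(np.max(dist_means) - np.min(dist_means))
        distal_stable: bool | None = bool(spread < 0.02 * ref)
    else:
        distal_stable = None
    nonzero = [(p, d) for p, d, lv in zip(prox, dist, levels) if lv > 0]
    prox_gt_dist: bool | None
    if nonzero:
        prox_gt_dist = all(p.oscillatory > d.oscillatory for p, d in nonzero)
    else:
        prox_gt_dist = None

    verdicts = {
        "proximal_mean_increasing": _strictly_increasing([s.mean for s in prox]),
        "distal_mean_stable": distal_stable,
        "proximal_oscillatory_increasing": _strictly_increasing(
            [s.oscillatory for s in prox]
        ),
        "proximal_exceeds_distal_oscillatory": prox_gt_dist,
    }
    meta = {
        "mode": "compression",
        "levels": levels,
        "q2_setpoint_mmHg": q2_setpoint,
        "seed": seed,
        "noise_sd_mmHg": noise_sd,
        "duration_s": duration,
        "sample_rate_hz": sample_rate,
        "window_cycles": window,
    }
    return SweepResult("compression", levels, summaries, verdicts, meta)


def external_pressure_sweep(
    q2_values: Sequence[float] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    params: CardiacParams = CardiacParams(),
    fit: PressureDiameterFit = DEFAULT_FIT,
    geometry: TubeGeometry = DEFAULT_GEOMETRY,
    level: float = 0.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    schedule_template: CompressionSchedule | None = None,
    duration: float = 5.0,
    sample_rate: float = 1000.0,
    window: int = DEFAULT_WINDOW_CYCLES,
) -> SweepResult:
    """Sweep the chamber (external) pressure setpoint at fixed compression.

    Verdicts: mean inner-wall stress strictly decreasing in q2 at each site
    (``proximal_mean_decreasing``, ``distal_mean_decreasing``); None when a
    single setpoint makes the trend non-evaluable.

    Raises
    ------
    ValueError
        If the q2 grid is not strictly increasing.
    """
    q2_values = [float(v) for v in q2_values]
    if len(q2_values) < 1:
        raise ValueError("need at least one q2 setpoint")
    if len(q2_values) >= 2 and not np.all(np.diff(q2_values) > 0):
        raise ValueError("q2 setpoints must be strictly increasing")
    tmpl = schedule_template or CompressionSchedule(level=0.0)
    sched = CompressionSchedule(
        level=level,
        onset_phase=tmpl.onset_phase,
        duration_phase=tmpl.duration_phase,
        overshoot_gain=tmpl.overshoot_gain,
        overshoot_damping=tmpl.overshoot_damping,
        overshoot_freq=tmpl.overshoot_freq,
    )

    def make(q2: float, run_seed: int) -> PressureChannels:
        return synthesize_channels(
            params, sched, q2, duration, sample_rate, run_seed, noise_sd
        )

    summaries = _condition_summaries(q2_values, make, fit, geometry, window, noise_sd, seed)
    prox = [s for s in summaries if s.site == "proximal"]
    dist = [s for s in summaries if s.site == "distal"]
    verdicts = {
        "proximal_mean_decreasing": _strictly_decreasing([s.mean for s in prox]),
        "distal_mean_decreasing": _strictly_decreasing([s.mean for s in dist]),
    }
    meta = {
        "mode": "external-pressure",
        "q2_values_mmHg": q2_values,
        "level": level,
        "seed": seed,
        "noise_sd_mmHg": noise_sd,
        "duration_s": duration,
        "sample_rate_hz": sample_rate,
        "window_cycles": window,
    }
    return SweepResult("external-pressure", q2_values, summaries, verdicts, meta)


def write_sweep(result: SweepResult, out_dir, stem: str | None = None) -> tuple[Path, Path]:
    """Write a sweep as summary CSV plus verdict/metadata JSON.

    Returns the (csv_path, json_path) pair.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"sweep_{result.mode.replace('-', '_')}"
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"
    result.to_frame().to_csv(csv_path, index=False)
    payload = {
        "mode": result.mode,
        "conditions": result.conditions,
        "verdicts": result.verdicts,
        "meta": result.meta,
    }
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return csv_path, json_path
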