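"""Static figures: pressure channels and sweep trend plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt

from .device_waveforms import PressureChannels
from .stress_pipeline import SweepResult

__all__ = ["plot_channels", "plot_sweep"]


def plot_channels(channels: PressureChannels, ax=None):
    """Proximal/distal internal pressures and chamber pressure vs time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.plot(channels.t, channels.q1_prox, label="proximal q1", lw=1)
    ax.plot(channels.t, channels.q1_dist, label="distal q1", lw=1)
    ax.plot(channels.t, channels.q2, label="chamber q2", lw=1, ls="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("pressure (mmHg)")
    ax.legend(loc="upper right")
    return ax


def plot_sweep(result: SweepResult, axes=None):
    """Mean and oscillatory hoop stress vs sweep condition, per site."""
    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(10, 4))
    frame = result.to_frame()
    xlabel = (
        "oppression degree" if result.mode == "compression" else "external pressure q2 (mmHg)"
    )
    for site, group in frame.groupby("site"):
        axes[0].plot(group["condition"], group["mean_mmHg"], "o-", label=site)
        axes[1].plot(group["condition"], group["oscillatory_mmHg"], "o-", label=site)
    axes[0].set_ylabel("mean hoop stress (mmHg)")
    axes[1].set_ylabel("oscillatory hoop stress (mmHg)")
    for ax in axes:
        ax.set_xlabel(xlabel)
        ax.legend()
    return axes
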