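"""Plots: averaged tumor trajectories per RFC arm and agent snapshots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .experiments import SweepResult

__all__ = ["plot_sweep", "plot_snapshot"]

_KIND_STYLE = {
    "APC_OFF": dict(marker="o", color="red", s=12),
    "APC_M": dict(marker="o", color="blue", s=12),
    "T_INACTIVE": dict(marker="x", color="black", s=12),
    "T_ACTIVE": dict(marker="+", color="green", s=16),
    "TIL": dict(marker="+", color="darkgreen", s=16),
}


def plot_sweep(result: SweepResult, path=None):
    """Averaged radius trajectories (left) and day-30 size per arm (right)."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for rfc, arm in sorted(result.arms.items()):
        ax1.plot(arm.times_min / 1440.0, arm.mean_radius,
                 label=f"{rfc} RFC")
    ax1.set_xlabel("time (days)")
    ax1.set_ylabel("tumor radius (µm)")
    ax1.legend(fontsize=8)
    ax1.set_title(f"mean of {result.replicates} runs")

    arms = sorted(result.arms)
    ax2.bar([str(a) for a in arms],
            [result.arms[a].final_radius for a in arms], color="gray")
    ax2.set_xlabel("RFC count")
    ax2.set_ylabel("tumor radius at day 30 (µm)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_snapshot(snapshot, tumor_radius: float, rfc_pos=None, field=None,
                  path=None):
    """Spatial snapshot of agents, the tumor disc, and optionally the field.

    ``field`` is rendered max-normalized in gray (visualization only).
    """
    fig, ax = plt.subplots(figsize=(6, 6))
    if field is not None:
        x, y, c = field[:, 0], field[:, 1], field[:, 2]
        if c.max() > 0:
            c = c / c.max()
        ax.tripcolor(x, y, c, cmap="Greys", alpha=0.6)
    circle = plt.Circle((0, 0), tumor_radius, color="gold", alpha=0.7)
    ax.add_patch(circle)
    for kind, style in _KIND_STYLE.items():
        sub = snapshot[snapshot["kind"] == kind]
        if len(sub):
            ax.scatter(sub["x"], sub["y"], label=kind, **style)
    if rfc_pos is not None and len(rfc_pos):
        rfc_pos = np.asarray(rfc_pos)
        ax.scatter(rfc_pos[:, 0], rfc_pos[:, 1], marker="*", color="red",
                   s=40, label="RFC")
    ax.set_aspect("equal")
    ax.legend(fontsize=7, loc="upper right")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
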