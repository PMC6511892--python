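"""Plots: SODP scatter with quadrant shading and the 3-D quadrant-proportion
trajectory used to separate stress states."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .pipeline import Trajectory3D
from .sodp import SODP

__all__ = ["plot_sodp", "plot_trajectory"]

_QUAD_COLORS = {"Q1": "tab:green", "Q2": "tab:orange", "Q3": "tab:red",
                "Q4": "tab:blue", "BOUNDARY": "grey"}


def plot_sodp(s: SODP, ax=None):
    """Scatter of (d(n), d(n+1)) coloured by quadrant."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for label, color in _QUAD_COLORS.items():
        m = s.quadrants == label
        if m.any():
            ax.scatter(s.points[m, 0], s.points[m, 1], s=12, c=color, label=label)
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    ax.set_xlabel("d(n)")
    ax.set_ylabel("d(n+1)")
    ax.legend(fontsize=7)
    ax.set_aspect("equal", adjustable="datalim")
    return ax


def plot_trajectory(traj: Trajectory3D, ax=None):
    """3-D line of (PQ2,4, PQ3, PQ1) block averages, coloured by time."""
    if ax is None:
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
    p = ax.scatter(traj.pq24, traj.pq3, traj.pq1, c=traj.times, cmap="viridis", s=14)
    ax.plot(traj.pq24, traj.pq3, traj.pq1, lw=0.6, color="grey")
    ax.set_xlabel("PQ2,4")
    ax.set_ylabel("PQ3")
    ax.set_zlabel("PQ1")
    plt.colorbar(p, ax=ax, label="time (s)", shrink=0.6)
    return ax
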