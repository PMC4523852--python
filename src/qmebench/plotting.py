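"""Optional plotting conveniences (not part of the tested surface)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_populations(trajectories, labels=None, ax=None):
    """Overlay ρ₊₊(t) (solid) and |ρ₋₊(t)| (dashed) for several trajectories."""
    if ax is None:
        _, ax = plt.subplots()
    for i, traj in enumerate(trajectories):
        label = labels[i] if labels else traj.metadata.get("solver", f"traj{i}")
        ax.plot(traj.times, traj.population(0), "-", label=f"{label} ρ₊₊")
        ax.plot(traj.times, traj.coherence_abs(), "--", label=f"{label} |ρ₋₊|")
    ax.set_xlabel("t (fs)")
    ax.set_ylabel("population / coherence")
    ax.legend(fontsize=8)
    return ax


def plot_concurrence(extended_trajectories, labels=None, ax=None):
    """Concurrence vs time for one or more Choi-extended trajectories."""
    from .nonmarkov import concurrence_series

    if ax is None:
        _, ax = plt.subplots()
    for i, ext in enumerate(extended_trajectories):
        series, _ = concurrence_series(ext)
        label = labels[i] if labels else f"map{i}"
        ax.plot(ext.times, series, label=label)
    ax.set_xlabel("t (fs)")
    ax.set_ylabel("concurrence")
    ax.legend(fontsize=8)
    return ax
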