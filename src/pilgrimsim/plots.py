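"""Plotting helpers for visual inspection of trajectories and dynamics.

Decoration only: these panels are for eyeballing runs, not analysis, and
carry no tests.
"""

from __future__ import annotations

import pandas as pd


def plot_round(trajectory: pd.DataFrame, m_fraction: float = 1.0 / 3.0, ax=None):
    """One round's adoption curve with threshold-cleared turns marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    for turn in trajectory.loc[trajectory["threshold_cleared"], "turn"]:
        ax.axvline(turn, color="0.8", lw=0.5, zorder=0)
    ax.plot(trajectory["turn"], trajectory["prop_social"], color="seagreen")
    ax.axhline(m_fraction, ls=":", color="k", lw=1)
    ax.set(xlabel="turn", ylabel="proportion social", ylim=(-0.02, 1.02))
    return ax


def plot_sweep_panels(summary: pd.DataFrame):
    """Grid of mean-adoption curves: variance in columns, group size in rows."""
    import matplotlib.pyplot as plt

    pvs = sorted(summary["pv"].unique())
    ns = sorted(summary["n_agents"].unique())
    fig, axes = plt.subplots(
        len(ns), len(pvs), figsize=(2.2 * len(pvs), 2.0 * len(ns)), sharex=True, sharey=True
    )
    axes = axes.reshape(len(ns), len(pvs))
    for i, n in enumerate(ns):
        for j, pv in enumerate(pvs):
            cell = summary[(summary["n_agents"] == n) & (summary["pv"] == pv)]
            for p0, grp in cell.groupby("p0"):
                axes[i, j].plot(grp["turn"], grp["mean_prop_social"], label=f"p0={p0:g}")
            axes[i, j].set_title(f"PV={pv:g}, N={n}", fontsize=8)
    axes[0, 0].legend(fontsize=7)
    fig.supxlabel("turn")
    fig.supylabel("mean proportion social")
    fig.tight_layout()
    return fig
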