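"""Matplotlib helpers for waveform summaries.

All plots share the ERP display conventions: time in ms on the x axis,
voltage in µV on the y axis with negative plotted upward, one panel per
electrode, and a shaded ribbon of mean ± ci_multiplier * se around each
trace.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless; figures are written to files

import matplotlib.pyplot as plt

from .epochs import WaveformSummary


def plot_waveforms(summary: WaveformSummary, title: str = "",
                   ci_multiplier: float = 1.96, invert_y: bool = True,
                   electrodes=None):
    """One figure with a panel per electrode and a trace per group."""
    data = summary.data
    if electrodes is None:
        electrodes = list(dict.fromkeys(data["electrode"]))
    group_cols = list(summary.group_by)
    fig, axes = plt.subplots(1, len(electrodes), figsize=(4.2 * len(electrodes), 3.4),
                             sharey=True, squeeze=False)
    for ax, el in zip(axes[0], electrodes):
        sub = data[data["electrode"] == el]
        if group_cols:
            groups = sub.groupby(group_cols, sort=True, observed=True)
        else:
            groups = [((), sub)]
        for gkey, g in groups:
            gkey = gkey if isinstance(gkey, tuple) else (gkey,)
            label = ", ".join(str(v) for v in gkey) if gkey else "mean"
            g = g.sort_values("time_ms")
            ax.plot(g["time_ms"], g["mean_uv"], label=label, linewidth=1.2)
            ax.fill_between(
                g["time_ms"],
                g["mean_uv"] - ci_multiplier * g["se_uv"],
                g["mean_uv"] + ci_multiplier * g["se_uv"],
                alpha=0.25, linewidth=0,
            )
        ax.axvline(0.0, color="0.6", linewidth=0.7)
        ax.axhline(0.0, color="0.6", linewidth=0.7)
        ax.set_title(el)
        ax.set_xlabel("time (ms)")
        if invert_y:
            ax.invert_yaxis()
    axes[0][0].set_ylabel("µV")
    axes[0][-1].legend(fontsize=8, frameon=False)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def save_figure(fig, path) -> None:
    fig.savefig(path, dpi=110)
    plt.close(fig)
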