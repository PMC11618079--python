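"""Matplotlib figures for smooths and ledgers."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .models import EventCentredSmoothResults

STRATEGY_COLOURS = {"migrant": "#d95f02", "resident": "#1b9e77"}


def plot_smooth(
    results: EventCentredSmoothResults,
    ylabel: str = "",
    xlabel: str = "day",
    path: str | None = None,
):
    """Per-strategy smooth with 95% bands; CI non-overlap windows shaded."""
    frame = results.predict_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    for strategy, sub in frame.groupby("strategy"):
        colour = STRATEGY_COLOURS.get(str(strategy), None)
        ax.plot(sub["x"], sub["fit"], label=str(strategy), color=colour)
        ax.fill_between(sub["x"], sub["lo"], sub["hi"], alpha=0.25, color=colour)
    for lo, hi in results.significant_windows():
        ax.axvspan(lo, hi, color="red", alpha=0.08)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
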