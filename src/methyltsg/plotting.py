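"""Plot helpers (matplotlib Agg; all functions return the Axes)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_metaplot(metaplot: pd.DataFrame, ax=None, label: str | None = None):
    """Mean methylation frequency around the TSS (the canonical dip plot)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(metaplot["bin_center"], metaplot["mean_frequency"], label=label)
    ax.axvline(0, ls=":", lw=0.8, color="grey")
    ax.set_xlabel("distance to TSS (bp)")
    ax.set_ylabel("mean methylation frequency")
    ax.set_ylim(0, 1)
    if label:
        ax.legend(frameon=False)
    return ax


def plot_funnel(funnel: dict[str, int], ax=None):
    """Stage counts of the candidate cascade as a bar chart."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3))
    stages = list(funnel)
    ax.bar(stages, [funnel[s] for s in stages], color="#4878a8")
    for i, s in enumerate(stages):
        ax.text(i, funnel[s], str(funnel[s]), ha="center", va="bottom", fontsize=9)
    ax.set_ylabel("genes")
    ax.tick_params(axis="x", rotation=30)
    return ax
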