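"""Simple figure utilities: forest plots (dot + CI, outcomes ordered by
ascending mean IISD) and correlation heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_plot(
    table: pd.DataFrame,
    value_col: str,
    ci_low_col: str | None = None,
    ci_high_col: str | None = None,
    order: list[str] | None = None,
    title: str = "",
    xlabel: str = "",
    path: str | None = None,
):
    """Dot-and-CI plot, one row per outcome; ``order`` puts the
    lowest-IISD outcome at the top (ascending downward)."""
    data = table.loc[order] if order is not None else table
    y = np.arange(len(data))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(data) + 1.5))
    ax.scatter(data[value_col], y, color="tab:blue", zorder=3, s=18)
    if ci_low_col and ci_high_col:
        ax.hlines(y, data[ci_low_col], data[ci_high_col],
                  color="tab:blue", lw=1.2)
    ax.set_yticks(y)
    ax.set_yticklabels(data.index)
    ax.axvline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel(xlabel or value_col)
    ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def correlation_heatmap(corr: pd.DataFrame, title: str = "",
                        path: str | None = None):
    """Heatmap with darker shading for correlations closer to 1."""
    fig, ax = plt.subplots(figsize=(0.35 * len(corr) + 2,) * 2)
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="Greys")
    ax.set_xticks(range(len(corr)))
    ax.set_xticklabels(corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr)))
    ax.set_yticklabels(corr.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title(title)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
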