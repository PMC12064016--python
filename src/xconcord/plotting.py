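"""Convenience plots for ordination, difference distributions and
correlation heatmaps.  Only the TSV/JSON outputs are contract-bearing;
these figures are qualitative aids."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .concordance import DiffProfile
from .ordination import OrdinationResult


def plot_ordination(
    res: OrdinationResult,
    color_by: pd.Series | None = None,
    marker_by: pd.Series | None = None,
    components: tuple[int, int] = (1, 2),
    ax=None,
):
    """Scatter of two ordination components, colored by a sample factor."""
    i, j = components
    cols = res.scores.columns
    x, y = res.scores[cols[i - 1]], res.scores[cols[j - 1]]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    markers = ["o", "^", "s", "D", "v", "P", "X"]
    color_by = color_by.reindex(res.scores.index) if color_by is not None else None
    marker_by = marker_by.reindex(res.scores.index) if marker_by is not None else None
    if color_by is None:
        ax.scatter(x, y)
    else:
        levels = sorted(color_by.unique())
        cmap = plt.get_cmap("tab20")
        for k, lev in enumerate(levels):
            sel = color_by == lev
            if marker_by is None:
                ax.scatter(x[sel], y[sel], color=cmap(k % 20), label=str(lev), s=30)
            else:
                for mi, mlev in enumerate(sorted(marker_by.unique())):
                    ssel = sel & (marker_by == mlev)
                    ax.scatter(
                        x[ssel], y[ssel], color=cmap(k % 20),
                        marker=markers[mi % len(markers)], s=30,
                        label=str(lev) if mi == 0 else None,
                    )
        ax.legend(fontsize=7, ncol=2)
    frac = res.variance_fraction
    ax.set_xlabel(f"{cols[i - 1]} ({100 * frac[i - 1]:.1f}%)")
    ax.set_ylabel(f"{cols[j - 1]} ({100 * frac[j - 1]:.1f}%)")
    return ax


def plot_diff_boxplots(dp: DiffProfile, ax=None):
    """Per-cell-line boxplots of the cross-platform log2 differences,
    ordered from narrowest to widest IQR."""
    order = dp.cell_lines_by_iqr()
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.3 * len(order)), 4))
    ax.boxplot(
        [dp.delta[c].to_numpy() for c in order],
        tick_labels=list(order),
        showfliers=False,
    )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("log2(EPM+1) difference (targeted - reference)")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    return ax


def plot_correlation_heatmap(corr: pd.DataFrame, ax=None):
    """Heatmap of a sample-by-sample Pearson correlation matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.columns)))
    ax.set_xticklabels(corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.index)))
    ax.set_yticklabels(corr.index, fontsize=6)
    plt.colorbar(im, ax=ax, label="Pearson r")
    return ax
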