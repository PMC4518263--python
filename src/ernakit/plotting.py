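"""Optional matplotlib figures mirroring the pipeline's main readouts."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .crosstissue import least_rectangles_line

__all__ = ["plot_correlation_bars", "plot_paired_means", "plot_class_scatter"]


def plot_correlation_bars(correlations: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of Pearson r per region class, one panel per tissue."""
    tissues = sorted(correlations["tissue"].unique())
    fig, axes = plt.subplots(
        1, len(tissues), figsize=(3 * len(tissues), 3), squeeze=False, sharey=True
    )
    for ax, tissue in zip(axes[0], tissues):
        sub = correlations[correlations["tissue"] == tissue]
        ax.bar(sub["label"], sub["r"], color="firebrick")
        ax.set_title(tissue)
        ax.tick_params(axis="x", rotation=90)
    axes[0][0].set_ylabel("Pearson r")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_paired_means(paired_means: pd.DataFrame, path: str | Path) -> None:
    """Scatter of grouped mean z-scores with least-rectangles and diagonal."""
    x = paired_means["mean_z_no_eRNA"].to_numpy()
    y = paired_means["mean_z_eRNA"].to_numpy()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=10, alpha=0.6)
    lim = 3 * max(x.std(), y.std(), 0.1)
    grid = np.linspace(-lim, lim, 2)
    ax.plot(grid, grid, color="grey", lw=1, label="diagonal")
    if x.size >= 2 and x.std() > 0 and y.std() > 0:
        slope, intercept = least_rectangles_line(x, y)
        ax.plot(grid, slope * grid + intercept, color="red", lw=1.5,
                label="least rectangles")
    ax.set_xlabel("mean z (no-eRNA)")
    ax.set_ylabel("mean z (eRNA)")
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_class_scatter(points: pd.DataFrame, path: str | Path) -> None:
    """miRNA vs other family hit-ratio scatter with per-class trend lines."""
    fig, ax = plt.subplots(figsize=(4, 4))
    styles = {"miRNA": ("o", "red"), "other": ("^", "blue")}
    for cls, (marker, color) in styles.items():
        sub = points[points["family_class"] == cls].dropna()
        if not len(sub):
            continue
        ax.scatter(sub["control_ratio"], sub["real_ratio"], marker=marker,
                   color=color, label=cls, alpha=0.7)
        if len(sub) >= 2 and sub["control_ratio"].std() > 0 and sub["real_ratio"].std() > 0:
            slope, intercept = least_rectangles_line(
                sub["control_ratio"], sub["real_ratio"]
            )
            grid = np.linspace(0, max(0.35, sub["control_ratio"].max()), 2)
            ax.plot(grid, slope * grid + intercept, color=color, lw=1)
    ax.set_xlabel("control hit ratio")
    ax.set_ylabel("eRNA hit ratio")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
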