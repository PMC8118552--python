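"""Publication-style plots for trajectory summaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pseudospace import TrajectorySummary

__all__ = ["plot_trajectory", "plot_phase_heatmap"]


def plot_trajectory(summary: TrajectorySummary, genes=None, out_path=None,
                    zscore: bool = False, ax=None):
    """Mean curves with shaded 95% confidence bands along the axis."""
    genes = list(genes) if genes is not None else summary.gene_ids[:8]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for g in genes:
        if zscore and summary.zscored is not None:
            ax.plot(summary.axis, summary.zscored[g], label=g)
        else:
            ax.plot(summary.axis, summary.mean[g], label=g)
            ax.fill_between(summary.axis, summary.lower[g], summary.upper[g], alpha=0.25)
    ax.set_xlabel("trajectory coordinate (source → target)")
    ax.set_ylabel("z-scored expression" if zscore else "expression (log2 TPM+1)")
    ax.legend(fontsize=8)
    if out_path:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_phase_heatmap(summary: TrajectorySummary, gene_order, out_path=None):
    """Heatmap of z-scored curves with genes grouped by phase."""
    curves = summary.zscored if summary.zscored is not None else summary.mean
    data = curves[list(gene_order)].to_numpy().T
    fig, ax = plt.subplots(figsize=(6, max(2, 0.06 * len(gene_order))))
    im = ax.imshow(data, aspect="auto", cmap="RdBu_r",
                   extent=(0, 1, len(gene_order), 0),
                   vmin=-np.nanmax(np.abs(data)), vmax=np.nanmax(np.abs(data)))
    ax.set_xlabel("trajectory coordinate")
    ax.set_ylabel("genes (grouped by phase)")
    fig.colorbar(im, ax=ax, label="z-score")
    if out_path:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
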