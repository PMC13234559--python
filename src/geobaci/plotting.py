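"""Diagnostic plots: Love plot and covariate-overlap histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["love_plot", "overlap_plot", "correlation_plot"]


def correlation_plot(corr, path=None):
    """Heatmap of the continuous-covariate correlation matrix."""
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(corr), 1 + 0.6 * len(corr)))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(corr)), corr.index)
    for i in range(len(corr)):
        for j in range(len(corr)):
            ax.text(j, i, f"{corr.iat[i, j]:.2f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def love_plot(balance, path=None, threshold: float = 0.1):
    """Standardised mean differences before/after matching per covariate.

    The dashed band at +-threshold marks the conventional balance goal.
    """
    smd = balance.smd
    y = np.arange(len(smd))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(smd) + 1.5))
    ax.scatter(smd["smd_before"], y, label="before matching", color="tab:red", zorder=3)
    ax.scatter(smd["smd_after"], y, label="after matching", color="tab:blue", zorder=3)
    for yy, (b, a) in zip(y, smd[["smd_before", "smd_after"]].to_numpy()):
        ax.plot([b, a], [yy, yy], color="0.7", lw=1, zorder=2)
    ax.axvline(0, color="0.3", lw=1)
    for t in (-threshold, threshold):
        ax.axvline(t, color="0.5", lw=1, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(smd.index)
    ax.set_xlabel("standardised mean difference")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def overlap_plot(balance, variable: str, path=None):
    """Covariate distribution overlap of impact vs control, before/after."""
    data = balance.overlap[variable]
    edges = data["edges"]
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = np.diff(edges)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, data["impact"], width=width, alpha=0.45, label="impact")
    ax.bar(centers, data["control_before"], width=width, alpha=0.45, label="control (all)")
    ax.step(
        centers, data["control_after"], where="mid", color="k", lw=1.5,
        label="control (matched)",
    )
    ax.set_xlabel(variable)
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
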