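"""Optional plotting conveniences (no analysis lives here).

Figures are side products; every number they display comes from the
tables the analysis modules emit, and nothing downstream depends on
them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .ordination import GroupEllipse  # noqa: E402

__all__ = ["score_plot", "heatmap", "degree_histogram_plot"]


def score_plot(
    scores: pd.DataFrame,
    labels: pd.Series,
    ellipses: list[GroupEllipse] | None = None,
    path=None,
):
    """2-D score scatter coloured by group, with optional confidence ellipses."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, idx in labels.groupby(labels).groups.items():
        pts = scores.loc[idx]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], label=str(group), s=18)
    for e in ellipses or []:
        theta = np.linspace(0, 2 * np.pi, 200)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        rot = np.array(
            [[np.cos(e.angle), -np.sin(e.angle)],
             [np.sin(e.angle), np.cos(e.angle)]]
        )
        xy = rot @ (circle * e.semi_axes[:, None]) + e.center[:, None]
        ax.plot(xy[0], xy[1], lw=1, alpha=0.7)
    ax.set_xlabel(scores.columns[0])
    ax.set_ylabel(scores.columns[1])
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def heatmap(matrix: pd.DataFrame, path=None):
    """Group-mean heatmap (rows metabolites, columns groups)."""
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def degree_histogram_plot(hist: pd.DataFrame, path=None):
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(hist.iloc[:, 0], hist["count"], width=0.9)
    ax.set_xlabel("node degree")
    ax.set_ylabel("metabolites")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
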