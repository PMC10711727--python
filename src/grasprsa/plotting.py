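"""Plotting helpers: RDM heatmaps, bar charts, dendrograms, MDS, edge diagrams.

All functions draw onto a provided matplotlib Axes (created if omitted) and
return it, so they compose into figure grids. These are reporting niceties;
every quantity plotted is available from the result tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt
from scipy.cluster import hierarchy

__all__ = [
    "plot_rdm",
    "plot_matrix",
    "plot_first_order_bars",
    "plot_dendrogram",
    "plot_mds",
    "plot_edges",
]


def _axes(ax):
    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_rdm(rdm, ax=None, cmap="viridis", title=None):
    """Heatmap of one RDM with condition labels."""
    ax = _axes(ax)
    im = ax.imshow(rdm.matrix, cmap=cmap)
    ax.set_xticks(range(len(rdm.labels)), rdm.labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(rdm.labels)), rdm.labels, fontsize=6)
    if title:
        ax.set_title(title, fontsize=8)
    plt.colorbar(im, ax=ax, fraction=0.046)
    return ax


def plot_matrix(matrix: pd.DataFrame, mask: pd.DataFrame | None = None, ax=None,
                cmap="RdBu_r", vmin=-1, vmax=1, title=None):
    """ROI × ROI correlation heatmap with significance asterisks."""
    ax = _axes(ax)
    im = ax.imshow(matrix.to_numpy(), cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    if mask is not None:
        for i in range(len(matrix.index)):
            for j in range(len(matrix.columns)):
                if mask.to_numpy()[i, j]:
                    ax.text(j, i, "*", ha="center", va="center", color="white")
    if title:
        ax.set_title(title, fontsize=9)
    plt.colorbar(im, ax=ax, fraction=0.046)
    return ax


def plot_first_order_bars(table: pd.DataFrame, model: str, phase: str, ax=None):
    """Mean model correlation per ROI with the noise ceiling band."""
    ax = _axes(ax)
    sub = table[(table["model"] == model) & (table["phase"] == phase)]
    x = np.arange(len(sub))
    colors = ["tab:blue" if s else "lightsteelblue" for s in sub["significant"]]
    ax.bar(x, sub["mean_r"], color=colors)
    for i, (_, row) in enumerate(sub.iterrows()):
        if np.isfinite(row["ceiling_lower"]):
            ax.fill_between([i - 0.4, i + 0.4], row["ceiling_lower"],
                            row["ceiling_upper"], color="gray", alpha=0.4, lw=0)
    ax.set_xticks(x, sub["roi"], rotation=45, fontsize=7)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("mean r")
    ax.set_title(f"{model} / {phase}", fontsize=9)
    return ax


def plot_dendrogram(linkage: np.ndarray, labels, ax=None, title=None):
    ax = _axes(ax)
    hierarchy.dendrogram(linkage, labels=list(labels), ax=ax, leaf_font_size=7)
    if title:
        ax.set_title(title, fontsize=9)
    return ax


def plot_mds(embedding: pd.DataFrame, ax=None, title=None):
    ax = _axes(ax)
    ax.scatter(embedding["x"], embedding["y"])
    for _, row in embedding.iterrows():
        ax.annotate(row["roi"], (row["x"], row["y"]), fontsize=7,
                    textcoords="offset points", xytext=(3, 3))
    ax.set_aspect("equal")
    if title:
        ax.set_title(title, fontsize=9)
    return ax


def plot_edges(edge_list: pd.DataFrame, rois, ax=None, title=None):
    """Significant inter-ROI correlations on a circular layout, line darkness ∝ r."""
    ax = _axes(ax)
    rois = list(rois)
    theta = 2 * np.pi * np.arange(len(rois)) / len(rois)
    pos = {roi: (np.cos(t), np.sin(t)) for roi, t in zip(rois, theta)}
    sig = edge_list[edge_list["significant"]]
    rmax = max(sig["r"].abs().max(), 1e-9) if len(sig) else 1.0
    for _, e in sig.iterrows():
        (x0, y0), (x1, y1) = pos[e["roi_a"]], pos[e["roi_b"]]
        ax.plot([x0, x1], [y0, y1], color="k", alpha=min(1.0, abs(e["r"]) / rmax), lw=1.5)
    for roi, (x, y) in pos.items():
        ax.plot(x, y, "o", color="tab:blue")
        ax.annotate(roi, (x, y), fontsize=7, textcoords="offset points", xytext=(4, 4))
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title, fontsize=9)
    return ax
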