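"""Figure output: graph layouts, incidence plots, box plots, fit scatters.

All functions save straight to file and return the path; figures are
artifacts for inspection, not analysis surfaces — every reported number
comes from the tables.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import ReturnPoint, node_time_table
from .mapper import MapperGraph

__all__ = [
    "plot_graph_layout",
    "plot_node_incidence",
    "plot_paired_box",
    "plot_fit_scatter",
]


def plot_graph_layout(graph: MapperGraph, path: str | Path) -> Path:
    """Conventional Mapper layout: node area proportional to member count."""
    g = graph.to_networkx()
    pos = nx.spring_layout(g, seed=0)
    sizes = [40 * g.nodes[n]["size"] for n in g]
    colors = [g.nodes[n]["interval"] for n in g]
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx(
        g, pos, ax=ax, node_size=sizes, node_color=colors, cmap="viridis",
        with_labels=False, edge_color="gray",
    )
    ax.set_axis_off()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_node_incidence(
    graph: MapperGraph,
    path: str | Path,
    return_point: Optional[ReturnPoint] = None,
) -> Path:
    """Incidence-style view: nodes on the y axis, time on the x axis.

    Each marker is one (node, time point) membership; when a return point is
    present it is drawn as a vertical rule.
    """
    table = node_time_table(graph)
    order = {nid: i for i, nid in enumerate(table["node_id"].unique())}
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.scatter(
        table["time_index"],
        table["node_id"].map(order),
        c=table["interval"],
        cmap="viridis",
        s=12,
    )
    if return_point is not None and return_point.value is not None:
        ax.axvline(return_point.value, color="black", lw=1.5)
    ax.set_xlabel("time point")
    ax.set_ylabel("node (by interval, first member)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_paired_box(table: pd.DataFrame, path: str | Path) -> Path:
    """Box plots of the 0B and 2B return points."""
    fig, ax = plt.subplots(figsize=(4, 5))
    ax.boxplot(
        [table["Mapper0B"], table["Mapper2B"]], tick_labels=["0-back", "2-back"]
    )
    ax.set_ylabel("return point (samples)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_fit_scatter(
    x: np.ndarray, y: np.ndarray, xlabel: str, ylabel: str, path: str | Path
) -> Path:
    """Scatter with the simple-regression line overlaid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=15)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, intercept + slope * xs, color="tab:blue")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
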