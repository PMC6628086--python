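"""Markers extracted from a Mapper graph of a brain-state trajectory.

The central marker is the *return point*: the first time point during the
stimulus at which the trajectory re-visits the neighborhood of the early
(baseline / stimulus-onset) states, after having first left it. "Re-visits"
is read through the Mapper graph: a time point touches the early window when
some node contains both that point and an early point, i.e. the clustering
put them in the same cluster of some cover bin.

The cluster-size profile tracks, per time point, the largest node containing
it — big mid-stimulus nodes indicate a stretch of highly similar whole-brain
configurations (high engagement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .mapper import GridPoint, MapperGraph

__all__ = [
    "DEFAULT_EARLY_WINDOW_END",
    "ReturnPoint",
    "detect_return_point",
    "cluster_size_profile",
    "node_time_table",
]

#: 30 baseline samples plus 2 initial stimulus samples
DEFAULT_EARLY_WINDOW_END = 32


@dataclass(frozen=True)
class ReturnPoint:
    """Detected return time (1-based sample index), or None when missing."""

    value: Optional[int]
    early_window_end: int
    condition: Optional[str] = None
    grid_point: Optional[GridPoint] = None

    @property
    def missing(self) -> bool:
        return self.value is None


def detect_return_point(
    graph: MapperGraph,
    early_window_end: int = DEFAULT_EARLY_WINDOW_END,
    condition: Optional[str] = None,
    grid_point: Optional[GridPoint] = None,
) -> ReturnPoint:
    """First post-excursion time point sharing a node with the early window.

    Let W = {1..early_window_end}. A time point t *touches* W when some node
    contains both t and a member of W. The return point is the smallest
    t > early_window_end such that t touches W and some earlier
    t' (early_window_end < t' < t) does **not** touch W — the trajectory must
    first leave the early neighborhood before a re-visit counts. Without
    that requirement the cover overlap would chain the first stimulus sample
    to the baseline and trivially report an immediate return.

    Returns a ReturnPoint with ``value=None`` when the trajectory never
    leaves, or leaves and never comes back.
    """
    t_max = graph.n_timepoints
    touches = np.zeros(t_max + 1, dtype=bool)  # index 0 unused
    for node in graph.nodes:
        members = np.asarray(node.members)
        if (members <= early_window_end).any():
            touches[members] = True
    left = False
    for t in range(early_window_end + 1, t_max + 1):
        if not touches[t]:
            left = True
        elif left:
            return ReturnPoint(t, early_window_end, condition, grid_point)
    return ReturnPoint(None, early_window_end, condition, grid_point)


def cluster_size_profile(graph: MapperGraph) -> np.ndarray:
    """Per time point, the size of the largest node containing it.

    Returns an array of length T; entry ``t - 1`` corresponds to time point t.
    """
    profile = np.zeros(graph.n_timepoints, dtype=int)
    for node in graph.nodes:
        idx = np.asarray(node.members) - 1
        profile[idx] = np.maximum(profile[idx], node.size)
    return profile


def node_time_table(graph: MapperGraph) -> pd.DataFrame:
    """Exhaustive (node, time point) incidence listing.

    One row per node membership, nodes ordered by (interval index, smallest
    member); this is the flat table behind the incidence-style visualization
    with nodes on one axis, time on the other, and the return point drawn as
    a vertical rule.
    """
    ordered = sorted(graph.nodes, key=lambda n: (n.interval, min(n.members)))
    rows = [
        {"node_id": n.id, "interval": n.interval, "time_index": t}
        for n in ordered
        for t in n.members
    ]
    return pd.DataFrame(rows, columns=["node_id", "interval", "time_index"])
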