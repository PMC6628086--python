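"""Mapper graph construction for brain-state time series.

A recording is a point cloud in "time space": each time point is a vector of
channel readings (one brain state). The lens (filter) is the Euclidean
distance of each state to a reference state, the mean of the pre-stimulus
baseline. The filter range is covered with overlapping closed intervals of
equal length; each interval's preimage (bin) is clustered with single-linkage
under the Euclidean metric, cut at the first-empty-histogram-bin height; each
cluster becomes a graph node and nodes sharing time points are joined by an
edge.

Time-point indices are 1-based everywhere in the public API, matching the
convention of reporting a return at, e.g., t = 63 out of 91 samples.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "StateSeries",
    "Cover",
    "ClusterParams",
    "GridPoint",
    "MapperNode",
    "MapperGraph",
    "reference_state",
    "compute_filter",
    "build_cover",
    "assign_bins",
    "single_linkage_heights",
    "first_empty_bin_cutoff",
    "cluster_bin",
    "build_graph",
    "run_mapper",
]

#: relative tolerance for closed-interval membership at bin boundaries
_BOUNDARY_RTOL = 1e-9


class GridPoint(NamedTuple):
    """One (Int, Ovr, Bin) Mapper parameter combination.

    ``n_intervals`` is the number of cover intervals (Int), ``overlap_pct``
    the percentage overlap of consecutive intervals (Ovr), and
    ``n_cluster_bins`` the histogram-bin count of the clustering cutoff
    heuristic (Bin). The conventional label is "Int-Ovr-Bin", e.g. "5-60-5".
    """

    n_intervals: int
    overlap_pct: float
    n_cluster_bins: int

    @property
    def label(self) -> str:
        ovr = self.overlap_pct
        ovr_s = str(int(ovr)) if float(ovr) == int(ovr) else str(ovr)
        return f"{self.n_intervals}-{ovr_s}-{self.n_cluster_bins}"

    @classmethod
    def from_label(cls, label: str) -> "GridPoint":
        parts = label.split("-")
        if len(parts) != 3:
            raise ValueError(f"grid-point label must be 'Int-Ovr-Bin', got {label!r}")
        return cls(int(parts[0]), float(parts[1]), int(parts[2]))


@dataclass(frozen=True)
class ClusterParams:
    """Parameters of the single-linkage cutoff heuristic."""

    n_cluster_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_cluster_bins < 2:
            raise ValueError("n_cluster_bins must be >= 2")


@dataclass(frozen=True)
class StateSeries:
    """One subject/condition recording: a T x V matrix of brain states.

    Rows are time points, columns channels (parcels). The first
    ``baseline_end`` rows are the pre-stimulus baseline.
    """

    values: np.ndarray
    baseline_end: int = 30
    subject: str = "S000"
    condition: str = "0B"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (time x channels) matrix")
        object.__setattr__(self, "values", values)
        t, v = values.shape
        if v < 1:
            raise ValueError("need at least one channel")
        if self.baseline_end < 1:
            raise ValueError("baseline_end must be >= 1")
        if t < self.baseline_end + 2:
            raise ValueError(
                f"need at least baseline_end + 2 = {self.baseline_end + 2} "
                f"time points, got {t}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("all state values must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Cover:
    """Uniform overlapping cover of the filter range by closed intervals."""

    n_intervals: int
    overlap_pct: float
    intervals: np.ndarray  # (n_intervals, 2) array of [a_i, b_i]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))


@dataclass(frozen=True)
class MapperNode:
    """A cluster of time points within one cover interval."""

    id: str
    interval: int
    members: tuple[int, ...]  # sorted, 1-based time-point indices

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MapperGraph:
    """Mapper output: clusters as nodes, shared time points as edges."""

    nodes: tuple[MapperNode, ...]
    edges: tuple[tuple[str, str], ...]
    n_timepoints: int

    def node(self, node_id: str) -> MapperNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def member_sets(self) -> dict[str, frozenset[int]]:
        return {n.id: frozenset(n.members) for n in self.nodes}

    def to_networkx(self):
        """Export as a networkx Graph with member/interval node attributes."""
        import networkx as nx

        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.id, interval=n.interval, members=list(n.members), size=n.size)
        g.add_edges_from(self.edges)
        return g


def reference_state(series: StateSeries) -> np.ndarray:
    """Mean baseline brain state: average of the first ``baseline_end`` rows."""
    if series.baseline_end > series.n_timepoints:
        raise IndexError("baseline_end exceeds the number of time points")
    return series.values[: series.baseline_end].mean(axis=0)


def compute_filter(series: StateSeries, ref: np.ndarray) -> np.ndarray:
    """Lens values: Euclidean distance of every state to the reference state."""
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (series.n_channels,):
        raise ValueError(
            f"reference state has {ref.shape} channels, series has "
            f"{series.n_channels}"
        )
    return np.linalg.norm(series.values - ref[None, :], axis=1)


def build_cover(
    filter_values: np.ndarray, n_intervals: int, overlap_pct: float
) -> Cover:
    """Cover [min f, max f] with ``n_intervals`` equal closed intervals.

    Consecutive intervals overlap by ``overlap_pct`` percent of their length:
    with range R and overlap fraction g, the length is
    L = R / (Int - (Int - 1) * g) and interval i starts at min + i * L * (1 - g).
    The first interval is anchored at the minimum and the last ends at the
    maximum. A degenerate range (R = 0) yields the single interval [min, min].
    """
    f = np.asarray(filter_values, dtype=float)
    if f.size == 0:
        raise ValueError("filter values are empty")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if not (0.0 < overlap_pct < 100.0):
        raise ValueError("overlap_pct must lie strictly between 0 and 100")
    lo, hi = float(f.min()), float(f.max())
    r = hi - lo
    if r == 0.0 or n_intervals == 1:
        if n_intervals == 1:
            return Cover(1, overlap_pct, np.array([[lo, hi]]))
        return Cover(1, overlap_pct, np.array([[lo, lo]]))
    g = overlap_pct / 100.0
    length = r / (n_intervals - (n_intervals - 1) * g)
    step = length * (1.0 - g)
    starts = lo + step * np.arange(n_intervals)
    intervals = np.column_stack([starts, starts + length])
    intervals[-1, 1] = hi  # guard against round-off at the top end
    return Cover(n_intervals, overlap_pct, intervals)


def assign_bins(filter_values: np.ndarray, cover: Cover) -> list[np.ndarray]:
    """Distribute time points into the cover's bins by filter value.

    Intervals are closed on both ends; a point whose filter value sits on a
    shared boundary belongs to every touching interval. Returns one sorted
    array of 1-based time indices per interval (empty bins allowed).
    """
    f = np.asarray(filter_values, dtype=float)
    r = float(f.max() - f.min())
    tol = _BOUNDARY_RTOL * r if r > 0 else _BOUNDARY_RTOL
    bins: list[np.ndarray] = []
    for a, b in cover.intervals:
        inside = (f >= a - tol) & (f <= b + tol)
        bins.append(np.flatnonzero(inside) + 1)
    return bins


def single_linkage_heights(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Merge heights of the single-linkage dendrogram and the set diameter.

    ``points`` is an (n, d) array. Returns the n-1 merge distances in
    ascending order and the maximum pairwise Euclidean distance. A single
    point yields empty heights and diameter 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n <= 1:
        return np.empty(0), 0.0
    dists = pdist(pts)
    z = linkage(dists, method="single")
    heights = np.sort(z[:, 2])
    return heights, float(dists.max())


def first_empty_bin_cutoff(
    heights: np.ndarray, diameter: float, n_cluster_bins: int
) -> float:
    """Single-linkage cut height from the first-empty-histogram-bin heuristic.

    The interval [min height, diameter] is split into ``n_cluster_bins``
    equal-width histogram bins; observations are the merge heights plus the
    diameter itself. The cutoff is the midpoint of the lowest-index empty
    bin. If there is no empty bin, or the histogram range is degenerate
    (no heights, or min height equals the diameter), the cutoff is +inf and
    the bin forms a single cluster.
    """
    if n_cluster_bins < 2:
        raise ValueError("n_cluster_bins must be >= 2")
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        return np.inf
    lo = float(h[0])
    if not diameter > lo:
        return np.inf
    obs = np.append(h, diameter)
    counts, edges = np.histogram(obs, bins=n_cluster_bins, range=(lo, diameter))
    empty = np.flatnonzero(counts == 0)
    if empty.size == 0:
        return np.inf
    i = int(empty[0])
    return 0.5 * (edges[i] + edges[i + 1])


def cluster_bin(
    bin_members: Sequence[int], series: StateSeries, params: ClusterParams
) -> list[tuple[int, ...]]:
    """Partition one bin's time points by thresholded single linkage.

    Applies every single-linkage merge whose height falls strictly below the
    first-empty-bin cutoff; equivalently, the clusters are the connected
    components of the graph joining member pairs at Euclidean distance below
    the cutoff. Clusters are returned sorted by their smallest member.
    """
    members = np.asarray(sorted(bin_members), dtype=int)
    if members.size == 0:
        return []
    if members.size == 1:
        return [(int(members[0]),)]
    pts = series.values[members - 1]
    heights, diameter = single_linkage_heights(pts)
    cutoff = first_empty_bin_cutoff(heights, diameter, params.n_cluster_bins)
    if not np.isfinite(cutoff):
        return [tuple(int(m) for m in members)]
    adj = squareform(pdist(pts)) < cutoff
    _, labels = connected_components(adj, directed=False)
    clusters: dict[int, list[int]] = {}
    for m, lab in zip(members, labels):
        clusters.setdefault(int(lab), []).append(int(m))
    return sorted((tuple(sorted(c)) for c in clusters.values()), key=lambda c: c[0])


def build_graph(
    partitions: Sequence[Sequence[tuple[int, ...]]], n_timepoints: int
) -> MapperGraph:
    """Assemble the Mapper graph from per-interval partitions.

    One node per cluster, tagged with its interval index; an edge joins two
    nodes exactly when their member sets intersect. Node ids are
    ``"i<interval>_c<cluster>"``.
    """
    nodes: list[MapperNode] = []
    for i, clusters in enumerate(partitions):
        for c, members in enumerate(clusters):
            nodes.append(MapperNode(f"i{i}_c{c}", i, tuple(sorted(members))))
    sets = [frozenset(n.members) for n in nodes]
    edges = tuple(
        (nodes[a].id, nodes[b].id)
        for a, b in itertools.combinations(range(len(nodes)), 2)
        if sets[a] & sets[b]
    )
    return MapperGraph(tuple(nodes), edges, n_timepoints)


def run_mapper(series: StateSeries, grid_point: GridPoint) -> MapperGraph:
    """Full Mapper pipeline for one recording at one parameter triple.

    reference state -> lens -> cover -> bin assignment -> per-bin single
    linkage -> graph. Deterministic: no randomness at any stage.
    """
    gp = GridPoint(*grid_point)
    ref = reference_state(series)
    f = compute_filter(series, ref)
    cover = build_cover(f, gp.n_intervals, gp.overlap_pct)
    bins = assign_bins(f, cover)
    params = ClusterParams(gp.n_cluster_bins)
    partitions = [cluster_bin(b, series, params) for b in bins]
    return build_graph(partitions, series.n_timepoints)
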