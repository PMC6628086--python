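"""File round-tripping: state matrices, tables, graphs, run configuration.

Matrices are plain delimited text with rows = time points and columns =
channels (a --transpose escape hatch handles the other orientation). Graphs
serialize to GraphML (member lists as comma-joined strings, since GraphML
attributes are scalar) and to node-link JSON. All numeric CSV output is
written at full precision so downstream recomputation is stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .mapper import GridPoint, MapperGraph, MapperNode, StateSeries

__all__ = [
    "RunConfig",
    "read_state_matrix",
    "write_state_matrix",
    "read_mat_matrix",
    "graph_to_graphml",
    "graph_from_graphml",
    "graph_to_node_link_json",
    "graph_from_node_link_json",
    "write_table",
]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or on-disk cohort).

    Exactly one of ``data_dir`` (a directory produced by ``statemapper
    simulate`` or laid out the same way) or ``synthetic=True`` drives a run.
    """

    data_dir: Optional[str] = None
    synthetic: bool = False
    n_subjects: int = 70
    n_channels: int = 20
    missing_rate: float = 0.0
    int_set: Sequence[int] = (5, 6, 7)
    ovr_set: Sequence[float] = (50, 60, 70)
    bin_set: Sequence[int] = (5, 10)
    baseline_end: int = 30
    early_window_end: int = 32
    selection_mode: str = "pooled"
    out_dir: str = "statemapper_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def read_state_matrix(
    path: str | Path,
    baseline_end: int = 30,
    subject: str = "S000",
    condition: str = "0B",
    transpose: bool = False,
    delimiter: str = ",",
) -> StateSeries:
    """Read a delimited text matrix as a StateSeries.

    Raises a ValueError naming the file and offending row on ragged or
    non-numeric input.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(tok) for tok in line.split(delimiter)])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value on row {lineno}") from exc
            if len(rows) > 1 and len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}: ragged row {lineno} "
                    f"({len(rows[-1])} values, expected {len(rows[0])})"
                )
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    values = np.asarray(rows, dtype=float)
    if transpose:
        values = values.T
    return StateSeries(values, baseline_end, subject=subject, condition=condition)


def write_state_matrix(path: str | Path, series: StateSeries) -> None:
    np.savetxt(path, series.values, delimiter=",", fmt="%.17g")


def read_mat_matrix(path: str | Path, variable: str) -> np.ndarray:
    """Extract a 2-D numeric array by variable name from a MAT-file.

    Handles both classic (scipy.io) and v7.3 (HDF5) MAT containers; v7.3
    arrays are transposed back to MATLAB's row-major view.
    """
    path = Path(path)
    try:
        from scipy.io import loadmat

        data = loadmat(path, variable_names=[variable])
        if variable not in data:
            raise KeyError(variable)
        arr = np.asarray(data[variable], dtype=float)
    except NotImplementedError:  # v7.3: HDF5-backed
        import h5py

        with h5py.File(path, "r") as fh:
            if variable not in fh:
                raise KeyError(variable)
            arr = np.asarray(fh[variable], dtype=float).T
    if arr.ndim != 2:
        raise ValueError(f"{path}:{variable} is not a 2-D array")
    return arr


def graph_to_graphml(graph: MapperGraph, path: str | Path) -> None:
    g = nx.Graph(n_timepoints=graph.n_timepoints)
    for n in graph.nodes:
        g.add_node(
            n.id,
            interval=n.interval,
            size=n.size,
            members=",".join(str(m) for m in n.members),
        )
    g.add_edges_from(graph.edges)
    nx.write_graphml(g, path)


def graph_from_graphml(path: str | Path) -> MapperGraph:
    g = nx.read_graphml(path)
    nodes = tuple(
        MapperNode(
            nid,
            int(data["interval"]),
            tuple(int(m) for m in str(data["members"]).split(",")),
        )
        for nid, data in sorted(g.nodes(data=True))
    )
    edges = tuple(tuple(sorted(e)) for e in sorted(g.edges()))
    return MapperGraph(nodes, edges, int(g.graph["n_timepoints"]))


def graph_to_node_link_json(graph: MapperGraph, path: str | Path) -> None:
    data = {
        "n_timepoints": graph.n_timepoints,
        "nodes": [
            {
                "id": n.id,
                "interval": n.interval,
                "size": n.size,
                "members": list(n.members),
            }
            for n in graph.nodes
        ],
        "links": [{"source": a, "target": b} for a, b in graph.edges],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def graph_from_node_link_json(path: str | Path) -> MapperGraph:
    with open(path) as fh:
        data = json.load(fh)
    nodes = tuple(
        MapperNode(n["id"], int(n["interval"]), tuple(int(m) for m in n["members"]))
        for n in data["nodes"]
    )
    edges = tuple((l["source"], l["target"]) for l in data["links"])
    return MapperGraph(nodes, edges, int(data["n_timepoints"]))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """CSV at full float precision (repr round-trip)."""
    df.to_csv(path, index=index, float_format="%.17g")
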