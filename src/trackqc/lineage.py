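"""Lineage graphs over tracked objects.

Each segmented object observation is a node identified by
``(image_index, object_index)``; each relationship row is a directed edge
from parent (the tracked predecessor) to child.  Because edges always point
strictly forward in time the graph is a DAG.  A link closing a temporal gap
(the object was undetected for one or more frames) is a single edge whose
``frame_gap`` attribute exceeds 1 — no phantom nodes are interpolated.

The unit of "track" for length statistics is the weakly connected
component: splits and merges make root-to-leaf path enumeration
combinatorial, while components match how lineage trees group cells.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .schema_io import TrackingDataset, IntegrityError

NodeID = tuple  # (image_index, object_index)


@dataclass(frozen=True)
class Trajectory:
    """A directed path of object observations, strictly forward in time.

    ``branch_free`` marks maximal unbranched segments: every interior node
    has in-degree = out-degree = 1."""

    nodes: tuple
    branch_free: bool = False

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class TrackComponent:
    """One weakly connected component of the lineage graph."""

    nodes: frozenset
    span_frames: int  # number of distinct occupied timepoints
    root_nodes: tuple  # in-degree-0 members, sorted

    def __len__(self) -> int:
        return len(self.nodes)


def _sort_key(g: nx.DiGraph):
    def key(n):
        return (g.nodes[n]["timepoint"], n[0], n[1])

    return key


def build_graph(ds: TrackingDataset) -> nx.DiGraph:
    """Construct the directed lineage graph from a dataset.

    One node per object row (unlinked objects included), one edge per
    relationship row.  Node attributes: ``timepoint``, ``group_index``,
    ``x``, ``y`` and ``features`` (name → value).  Edge attribute:
    ``frame_gap`` = child timepoint − parent timepoint.  Edges joining
    different groups (fields of view) are rejected.
    """
    g = nx.DiGraph()
    tp = ds.timepoint_map()
    gr = ds.group_map()
    feats = ds.feature_names
    for row in ds.objects.itertuples(index=False):
        node = (int(row.image_index), int(row.object_index))
        g.add_node(
            node,
            timepoint=tp[node[0]],
            group_index=gr[node[0]],
            x=float(row.x),
            y=float(row.y),
            features={f: float(getattr(row, f)) for f in feats},
        )
    for row in ds.relationships.astype(int).itertuples(index=False):
        parent = (row.parent_image_index, row.parent_object_index)
        child = (row.child_image_index, row.child_object_index)
        if gr[parent[0]] != gr[child[0]]:
            raise IntegrityError(
                f"relationship crosses groups: {parent} (group {gr[parent[0]]}) -> "
                f"{child} (group {gr[child[0]]})"
            )
        g.add_edge(parent, child, frame_gap=tp[child[0]] - tp[parent[0]])
    return g


def components(g: nx.DiGraph) -> list:
    """Weakly connected components in deterministic order (by smallest
    (timepoint, image_index, object_index) member)."""
    key = _sort_key(g)
    out = []
    for comp in nx.weakly_connected_components(g):
        span = len({g.nodes[n]["timepoint"] for n in comp})
        roots = tuple(sorted((n for n in comp if g.in_degree(n) == 0), key=key))
        out.append(TrackComponent(frozenset(comp), span, roots))
    out.sort(key=lambda c: min(key(n) for n in c.nodes))
    return out


def node_degrees(g: nx.DiGraph) -> dict:
    """NodeID → (in_degree, out_degree)."""
    return {n: (g.in_degree(n), g.out_degree(n)) for n in g.nodes}


def branch_free_segments(g: nx.DiGraph) -> list:
    """Decompose the graph into maximal unbranched directed paths.

    Every edge belongs to exactly one segment; split/merge nodes terminate
    segments and appear in each incident segment.  Isolated nodes yield
    single-node segments.
    """
    key = _sort_key(g)

    def is_interior(n):
        return g.in_degree(n) == 1 and g.out_degree(n) == 1

    segments = []
    # segments start at every edge leaving a non-interior node
    for u in sorted(g.nodes, key=key):
        if is_interior(u):
            continue
        for v in sorted(g.successors(u), key=key):
            path = [u, v]
            while is_interior(path[-1]):
                path.append(next(iter(g.successors(path[-1]))))
            segments.append(Trajectory(tuple(path), branch_free=True))
    # isolated nodes (no incident edges at all)
    for n in sorted(g.nodes, key=key):
        if g.degree(n) == 0:
            segments.append(Trajectory((n,), branch_free=True))
    segments.sort(key=lambda s: key(s.nodes[0]))
    return segments


# ---------------------------------------------------------------------------
# export


def _flat_node_attrs(g: nx.DiGraph, n) -> dict:
    a = g.nodes[n]
    flat = {k: a[k] for k in ("timepoint", "group_index", "x", "y")}
    for fname, val in a.get("features", {}).items():
        flat[f"feature_{fname}"] = val
    return flat


def to_graphml(g: nx.DiGraph, path) -> None:
    """Write GraphML with feature attributes flattened to ``feature_<name>``
    keys (GraphML has no mapping-valued attributes)."""
    h = nx.DiGraph()
    for n in g.nodes:
        h.add_node(f"{n[0]}-{n[1]}", image_index=n[0], object_index=n[1],
                   **_flat_node_attrs(g, n))
    for u, v, d in g.edges(data=True):
        h.add_edge(f"{u[0]}-{u[1]}", f"{v[0]}-{v[1]}", frame_gap=d["frame_gap"])
    nx.write_graphml(h, path)


def to_json(g: nx.DiGraph, path=None) -> str:
    """Serialize to a stable JSON lineage document.

    Nodes and edges are sorted by (timepoint, image_index, object_index);
    keys are sorted, so identical graphs give byte-identical output.
    """
    key = _sort_key(g)
    doc = {
        "format": "trackqc-lineage",
        "version": 1,
        "nodes": [
            {"image_index": n[0], "object_index": n[1], **_flat_node_attrs(g, n)}
            for n in sorted(g.nodes, key=key)
        ],
        "edges": [
            {
                "parent": [u[0], u[1]],
                "child": [v[0], v[1]],
                "frame_gap": d["frame_gap"],
            }
            for u, v, d in sorted(g.edges(data=True), key=lambda e: (key(e[0]), key(e[1])))
        ],
    }
    text = json.dumps(doc, sort_keys=True, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text
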