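"""Shared fixtures: a hand-built toy database and graph-building helpers."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from trackqc.schema_io import TrackingDataset


def make_toy_dataset() -> TrackingDataset:
    """3 images, 6 objects, 4 relationships: one dividing track (obj 1 at
    t=0 splits into two children) plus one isolated object at t=2."""
    images = pd.DataFrame(
        {"image_index": [1, 2, 3], "group_index": [0, 0, 0], "timepoint": [0, 1, 2]}
    )
    objects = pd.DataFrame(
        {
            "image_index": [1, 2, 2, 3, 3, 3],
            "object_index": [1, 1, 2, 1, 2, 3],
            "x": [10.0, 8.0, 12.0, 7.0, 13.0, 50.0],
            "y": [10.0, 9.0, 11.0, 8.0, 12.0, 50.0],
            "area": [100.0, 55.0, 52.0, 54.0, 51.0, 20.0],
        }
    )
    relationships = pd.DataFrame(
        {
            "child_image_index": [2, 2, 3, 3],
            "child_object_index": [1, 2, 1, 2],
            "parent_image_index": [1, 1, 2, 2],
            "parent_object_index": [1, 1, 1, 2],
        }
    )
    return TrackingDataset(images, objects, relationships, ["area"])


@pytest.fixture
def toy_dataset() -> TrackingDataset:
    return make_toy_dataset()


def graph_from(edges, timepoints, isolated=()):
    """Build a lineage-style DiGraph from integer node labels.

    ``edges`` is a list of (u, v) pairs, ``timepoints`` maps label ->
    timepoint.  Labels become (timepoint, label) NodeIDs so ordering
    semantics match real graphs.
    """
    g = nx.DiGraph()

    def node(n):
        return (timepoints[n], n)

    for n, t in timepoints.items():
        g.add_node(node(n), timepoint=t, group_index=0, x=float(n), y=float(t), features={})
    for u, v in edges:
        g.add_edge(node(u), node(v), frame_gap=timepoints[v] - timepoints[u])
    for n in isolated:
        g.add_node(node(n), timepoint=timepoints[n], group_index=0,
                   x=float(n), y=float(timepoints[n]), features={})
    return g


def random_lineage_dag(rng: np.random.Generator, max_nodes: int = 60) -> nx.DiGraph:
    """Random layered DAG with splits, merges, gaps and isolated nodes —
    the topology space the detectors must handle."""
    n_layers = int(rng.integers(4, 9))
    layer_sizes = rng.integers(1, max(2, max_nodes // n_layers), size=n_layers)
    g = nx.DiGraph()
    layers = []
    label = 0
    for t, size in enumerate(layer_sizes):
        layer = []
        for _ in range(int(size)):
            node = (t, label)
            g.add_node(node, timepoint=t, group_index=0,
                       x=float(label), y=float(t), features={})
            layer.append(node)
            label += 1
        layers.append(layer)
    for t in range(n_layers - 1):
        for u in layers[t]:
            n_out = int(rng.choice([0, 1, 1, 1, 2], p=[0.15, 0.25, 0.25, 0.2, 0.15]))
            for _ in range(n_out):
                # mostly next layer, sometimes a gap of one layer
                dt = 2 if (t + 2 < n_layers and rng.random() < 0.15) else 1
                target_layer = layers[t + dt]
                v = target_layer[int(rng.integers(len(target_layer)))]
                g.add_edge(u, v, frame_gap=dt)
    return g


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive implementations)


def _simple_paths(g: nx.DiGraph, u, v, path=None):
    """All simple directed paths u -> v by plain recursion."""
    path = [u] if path is None else path
    if u == v:
        yield tuple(path)
        return
    for w in g.successors(u):
        if w not in path:
            yield from _simple_paths(g, w, v, path + [w])


def brute_force_loops(g: nx.DiGraph):
    """Earliest reconvergence per split via exhaustive path enumeration."""
    found = set()
    for u in g.nodes:
        if g.out_degree(u) < 2:
            continue
        best = None
        for v in g.nodes:
            if v == u or g.in_degree(v) < 2:
                continue
            paths = list(_simple_paths(g, u, v))
            disjoint = any(
                not (set(p[1:-1]) & set(q[1:-1]))
                for i, p in enumerate(paths)
                for q in paths[i + 1:]
            )
            if disjoint:
                key = (g.nodes[v]["timepoint"], v)
                if best is None or key < best[0]:
                    best = (key, v)
        if best is not None:
            found.add((u, best[1]))
    return found


def brute_force_crossings(g: nx.DiGraph):
    """Enumerate all (merge, split) pairs and test the unbranched-chain
    condition on explicitly enumerated simple paths."""
    merges = [n for n in g.nodes if g.in_degree(n) >= 2]
    splits = {n for n in g.nodes if g.out_degree(n) >= 2}
    found = set()
    for m in merges:
        if m in splits:
            found.add((m, m))  # degenerate merge-and-split node
            continue
        if g.out_degree(m) != 1:
            continue
        for s in splits:
            if any(
                all(g.in_degree(w) == 1 and g.out_degree(w) == 1 for w in path[1:-1])
                for path in _simple_paths(g, m, s)
            ):
                found.add((m, s))
    return found


def brute_force_components(g: nx.DiGraph):
    """Flood fill over the undirected view."""
    seen = set()
    comps = []
    for start in g.nodes:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            n = stack.pop()
            if n in comp:
                continue
            comp.add(n)
            stack.extend(g.successors(n))
            stack.extend(g.predecessors(n))
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)
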