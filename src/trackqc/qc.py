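"""Graph-topology quality control for tracking data.

Cells exhibit a limited range of dynamic behavior, so lineage graphs are
expected to assume only certain topologies: chains, division trees, and
(rarely, e.g. syncytia or cell fusion) merges.  Three deviations from the
expected topologies are flagged as likely segmentation/tracking artifacts:

* **loop** — a split whose branches re-merge downstream: a transient,
  incorrect split of one object into two detections that later rejoin.
  Formally, a split node whose out-branches reconverge at a common
  descendant via node-disjoint directed paths; the earliest reconvergence
  is reported per split.
* **crossing** — a merge followed by a split: two neighboring objects
  transiently fused into one detection, then re-separated.  Formally, a
  merge node connected to a downstream split node through an unbranched
  chain (the degenerate case is a single node with in-degree ≥ 2 and
  out-degree ≥ 2).
* **singleton** — a track (weakly connected component) whose temporal span
  falls at or below a researcher-chosen length; often a spurious detection.
  Span counts distinct occupied timepoints; frames skipped by gap closure
  do not count.

Detection only highlights suspect nodes — the absence of flags does not
guarantee correct tracking.  Singletons can additionally be pruned into a
derived graph.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .lineage import NodeID, components, TrackComponent


@dataclass(frozen=True)
class Loop:
    """A split that re-merges: ≥2 node-disjoint paths split → merge."""

    split_node: NodeID
    merge_node: NodeID
    branches: tuple  # tuple of node tuples, sharing only endpoints
    duration_frames: int


@dataclass(frozen=True)
class Crossing:
    """A merge followed (through an unbranched chain) by a split."""

    merge_node: NodeID
    split_node: NodeID
    chain: tuple  # directed path merge → split inclusive
    duration_frames: int


@dataclass(frozen=True)
class SingletonFlag:
    component: TrackComponent
    length_frames: int


@dataclass(frozen=True)
class TrackLengthStats:
    """Distribution summary of track lengths (component time spans)."""

    n_tracks: int
    median: float
    p10: float
    p90: float
    histogram: dict  # length -> count


@dataclass(frozen=True)
class QCReport:
    loops: tuple
    crossings: tuple
    singletons: tuple
    stats: TrackLengthStats
    flagged_nodes: frozenset

    def to_json(self, path=None) -> str:
        """Stable JSON serialization (sorted keys, deterministic order)."""
        doc = {
            "format": "trackqc-report",
            "version": 1,
            "loops": [
                {
                    "split_node": list(l.split_node),
                    "merge_node": list(l.merge_node),
                    "branches": [[list(n) for n in b] for b in l.branches],
                    "duration_frames": l.duration_frames,
                }
                for l in self.loops
            ],
            "crossings": [
                {
                    "merge_node": list(c.merge_node),
                    "split_node": list(c.split_node),
                    "chain": [list(n) for n in c.chain],
                    "duration_frames": c.duration_frames,
                }
                for c in self.crossings
            ],
            "singletons": [
                {
                    "nodes": sorted([list(n) for n in s.component.nodes]),
                    "length_frames": s.length_frames,
                }
                for s in self.singletons
            ],
            "stats": {
                "n_tracks": self.stats.n_tracks,
                "median": self.stats.median,
                "p10": self.stats.p10,
                "p90": self.stats.p90,
                "histogram": {str(k): v for k, v in sorted(self.stats.histogram.items())},
            },
            "flagged_nodes": sorted([list(n) for n in self.flagged_nodes]),
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _tp(g: nx.DiGraph, n) -> int:
    return g.nodes[n]["timepoint"]


def find_loops(g: nx.DiGraph, max_duration: int | None = None) -> list:
    """Detect splits whose branches reconverge (transient incorrect splits).

    For every split node the earliest reconvergence — the merge node with
    smallest (timepoint, NodeID) admitting ≥2 node-disjoint directed paths
    from the split — is reported.  ``max_duration`` keeps only loops whose
    merge − split time difference does not exceed it.
    """
    out = []
    for u in g.nodes:
        if g.out_degree(u) < 2:
            continue
        candidates = sorted(
            (v for v in nx.descendants(g, u) if g.in_degree(v) >= 2),
            key=lambda v: (_tp(g, v), v),
        )
        for v in candidates:
            try:
                paths = list(nx.node_disjoint_paths(g, u, v))
            except nx.NetworkXNoPath:
                continue
            if len(paths) >= 2:
                duration = _tp(g, v) - _tp(g, u)
                if max_duration is None or duration <= max_duration:
                    out.append(
                        Loop(u, v, tuple(tuple(p) for p in sorted(paths)), duration)
                    )
                break  # earliest reconvergence only
    out.sort(key=lambda l: (_tp(g, l.split_node), l.split_node))
    return out


def find_crossings(g: nx.DiGraph, max_duration: int | None = None) -> list:
    """Detect merge-then-split events (transiently fused objects).

    From each merge node (in-degree ≥ 2) the unique outgoing chain is
    followed through nodes with in-degree = out-degree = 1; if it reaches a
    node with out-degree ≥ 2 before branching in, a crossing is reported.
    A single node with in-degree ≥ 2 and out-degree ≥ 2 is the degenerate
    crossing of duration 0.
    """
    out = []
    for m in g.nodes:
        if g.in_degree(m) < 2:
            continue
        chain = [m]
        found = None
        if g.out_degree(m) >= 2:
            found = m
        elif g.out_degree(m) == 1:
            node = next(iter(g.successors(m)))
            while True:
                chain.append(node)
                if g.out_degree(node) >= 2:
                    found = node
                    break
                if g.in_degree(node) == 1 and g.out_degree(node) == 1:
                    node = next(iter(g.successors(node)))
                else:
                    break
        if found is not None:
            duration = _tp(g, found) - _tp(g, m)
            if max_duration is None or duration <= max_duration:
                out.append(Crossing(m, found, tuple(chain[: chain.index(found) + 1]), duration))
    out.sort(key=lambda c: (_tp(g, c.merge_node), c.merge_node))
    return out


def find_singletons(g: nx.DiGraph, max_length: int = 1) -> list:
    """Flag components spanning at most ``max_length`` occupied timepoints."""
    if max_length < 1:
        raise ValueError(f"max_length must be >= 1, got {max_length}")
    return [
        SingletonFlag(c, c.span_frames)
        for c in components(g)
        if c.span_frames <= max_length
    ]


def track_length_stats(g: nx.DiGraph) -> TrackLengthStats:
    """Total track count plus median / 10th / 90th percentile of track
    lengths (component spans).  Percentiles use linear interpolation
    between closest order statistics (inclusive rule)."""
    comps = components(g)
    if not comps:
        raise ValueError("cannot compute track statistics on an empty graph")
    lengths = np.array(sorted(c.span_frames for c in comps), dtype=float)
    hist: dict[int, int] = {}
    for L in lengths.astype(int):
        hist[int(L)] = hist.get(int(L), 0) + 1
    p10, med, p90 = np.percentile(lengths, [10, 50, 90], method="linear")
    return TrackLengthStats(len(lengths), float(med), float(p10), float(p90), hist)


def prune_singletons(g: nx.DiGraph, max_length: int = 1):
    """Remove all singleton components, returning ``(pruned_graph, removed)``.

    The input graph is not modified.  Pruning is idempotent and never
    touches a component spanning more than ``max_length`` timepoints.
    """
    flags = find_singletons(g, max_length)
    removed = set()
    for f in flags:
        removed.update(f.component.nodes)
    pruned = g.copy()
    pruned.remove_nodes_from(removed)
    return pruned, removed


def qc_report(
    g: nx.DiGraph,
    singleton_max_length: int = 1,
    max_duration: int | None = None,
) -> QCReport:
    """Run all three detectors plus track statistics in one pass."""
    loops = tuple(find_loops(g, max_duration))
    crossings = tuple(find_crossings(g, max_duration))
    singletons = tuple(find_singletons(g, singleton_max_length))
    stats = track_length_stats(g)
    flagged: set = set()
    for l in loops:
        for branch in l.branches:
            flagged.update(branch)
    for c in crossings:
        flagged.update(c.chain)
    for s in singletons:
        flagged.update(s.component.nodes)
    return QCReport(loops, crossings, singletons, stats, frozenset(flagged))
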