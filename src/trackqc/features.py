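"""Per-timepoint feature summaries and node color mappings.

The population-level heatmap averages each object measurement over all
objects present at each timepoint, giving a timepoints × features matrix.
For display the matrix is min-max normalized per feature to [0, 1]; a
constant (zero-range) feature normalizes to 0 ("no signal").  Timepoints
with no objects stay as missing cells — interpolating would hide exactly
the dropouts (e.g. an out-of-focus frame) the heatmap exists to reveal.

Color maps assign each graph node a value in [0, 1] from a chosen feature,
either over the global min-max range or a percentile range with tail
clipping (robust to outliers).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .schema_io import TrackingDataset


@dataclass(frozen=True)
class HeatmapMatrix:
    """Timepoints × features matrix of per-timepoint means.

    ``values`` is a DataFrame indexed by timepoint with one column per
    feature; missing cells are NaN.
    """

    values: pd.DataFrame
    normalized: bool = False

    @property
    def timepoints(self) -> list:
        return [int(t) for t in self.values.index]

    @property
    def feature_names(self) -> list:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="timepoint")


@dataclass(frozen=True)
class ColorMap:
    feature_name: str
    node_values: dict  # NodeID -> value in [0, 1]
    scale: tuple  # (min, max) used
    missing_nodes: frozenset = frozenset()  # rendered neutrally

    def to_json(self, path=None) -> str:
        doc = {
            "feature_name": self.feature_name,
            "scale": list(self.scale),
            "node_values": {f"{n[0]}-{n[1]}": v for n, v in sorted(self.node_values.items())},
            "missing_nodes": sorted(f"{n[0]}-{n[1]}" for n in self.missing_nodes),
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def timepoint_feature_matrix(
    ds: TrackingDataset,
    features: list | None = None,
    per_group: bool = False,
) -> HeatmapMatrix:
    """Mean of each feature over all objects at each timepoint (unnormalized).

    All groups are pooled by default; with ``per_group`` the result index
    becomes (group_index, timepoint).  Timepoints present in the image
    table but holding no objects appear as all-NaN rows.
    """
    if features is None:
        features = list(ds.feature_names)
    unknown = [f for f in features if f not in ds.feature_names]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    tp = ds.timepoint_map()
    obj = ds.objects.copy()
    obj["timepoint"] = obj["image_index"].map(tp)
    if per_group:
        gr = ds.group_map()
        obj["group_index"] = obj["image_index"].map(gr)
        grouped = obj.groupby(["group_index", "timepoint"])[features].mean()
        full_index = pd.MultiIndex.from_frame(
            ds.images[["group_index", "timepoint"]].drop_duplicates().sort_values(
                ["group_index", "timepoint"]
            )
        )
    else:
        grouped = obj.groupby("timepoint")[features].mean()
        full_index = pd.Index(sorted(set(tp.values())), name="timepoint")
    values = grouped.reindex(full_index)[features]
    return HeatmapMatrix(values, normalized=False)


def minmax_normalize(m: HeatmapMatrix) -> HeatmapMatrix:
    """Normalize each feature column to [0, 1] over its finite cells.

    Zero-range columns map to 0; missing cells stay missing.  Idempotent on
    already-normalized matrices with nonzero range.
    """
    values = m.values.copy()
    for col in values.columns:
        v = values[col].to_numpy(dtype=float)
        finite = np.isfinite(v)
        if not finite.any():
            continue
        lo, hi = np.nanmin(v[finite]), np.nanmax(v[finite])
        if hi > lo:
            values[col] = (v - lo) / (hi - lo)
        else:
            out = np.full_like(v, np.nan)
            out[finite] = 0.0
            values[col] = out
    return HeatmapMatrix(values, normalized=True)


def feature_colormap(
    g: nx.DiGraph,
    feature: str,
    scale: str = "global-minmax",
    percentiles: tuple = (2.0, 98.0),
) -> ColorMap:
    """Map a per-node feature to [0, 1] color values.

    ``scale`` is ``"global-minmax"`` or ``"percentile"`` (the latter maps
    the [p_lo, p_hi] percentile range to [0, 1] and clips the tails).
    Nodes lacking the feature are excluded from the scale and flagged for
    neutral rendering.  All-equal values map to 0 (zero-range convention).
    """
    raw, missing = {}, set()
    for n, attrs in g.nodes(data=True):
        val = attrs.get("features", {}).get(feature)
        if val is None or not np.isfinite(val):
            missing.add(n)
        else:
            raw[n] = float(val)
    if not raw:
        raise ValueError(f"feature {feature!r} has no finite values on any node")
    vals = np.array(list(raw.values()))
    if scale == "global-minmax":
        lo, hi = float(vals.min()), float(vals.max())
    elif scale == "percentile":
        p_lo, p_hi = percentiles
        lo, hi = (float(q) for q in np.percentile(vals, [p_lo, p_hi]))
    else:
        raise ValueError(f"unknown scale: {scale!r}")
    if hi > lo:
        node_values = {n: float(np.clip((v - lo) / (hi - lo), 0.0, 1.0)) for n, v in raw.items()}
    else:
        node_values = {n: 0.0 for n in raw}
    return ColorMap(feature, node_values, (lo, hi), frozenset(missing))
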