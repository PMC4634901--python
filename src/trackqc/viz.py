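"""Static renderers for the four tracking-QC views.

* **XYT plot** — 3-D polylines of object centroids versus time, one per
  branch-free trajectory segment, optionally color-coded by a feature.
  Exported as a static image or as a standalone HTML file with mouse-drag
  rotation.
* **Lineage tree** — time on the x axis, one node per object observation,
  edges to tracked predecessors/successors; QC-flagged nodes are outlined
  (crossing style takes precedence over loop over singleton).  Gap-closing
  edges are drawn dashed.
* **Synchrogram** — a filmstrip of fixed-size patches cropped around one
  object's centroid in every frame of its trajectory, so the cell stays
  centered and tracking errors pop out; gap frames appear as labeled
  blanks.
* **Heatmap** — the per-timepoint feature-mean matrix, missing cells drawn
  distinctly (never as 0).

Every renderer writes a sidecar ``<out>.manifest.json`` with deterministic
glyph/segment/patch counts and color ranges so pipelines (and tests) never
need to parse pixels.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless

import matplotlib.pyplot as plt  # noqa: E402
import networkx as nx  # noqa: E402
import numpy as np  # noqa: E402
import tifffile  # noqa: E402

from .lineage import Trajectory, branch_free_segments, components
from .features import ColorMap
from .qc import QCReport
from .schema_io import TrackingDataset

# flag styling precedence when a node belongs to several deviations
FLAG_PRECEDENCE = ("crossing", "loop", "singleton")
FLAG_COLORS = {"crossing": "#d62728", "loop": "#ff7f0e", "singleton": "#9467bd"}
DEFAULT_PATCH_SIZE = (61, 61)


def _write_manifest(out, data: dict) -> dict:
    path = Path(str(out) + ".manifest.json")
    path.write_text(json.dumps(data, sort_keys=True, indent=1))
    return data


def _savefig(fig, out) -> None:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    meta = {"Date": None} if out.suffix == ".svg" else None
    fig.savefig(out, metadata=meta)
    plt.close(fig)


# ---------------------------------------------------------------------------
# lineage layout


@dataclass(frozen=True)
class LineageLayout:
    """Node positions for the lineage tree: x = timepoint, y = row."""

    positions: dict  # NodeID -> (x, y)
    component_offsets: dict  # smallest NodeID of component -> y origin


def layout_lineage(g: nx.DiGraph) -> LineageLayout:
    """Assign (timepoint, row) positions.

    Within a component, leaves get consecutive integer rows in DFS order
    (children visited by ascending object index); every internal node sits
    at the mean row of its children (resolved child-side first, so merge
    nodes follow their children too).  Components are stacked with one
    blank row between them; no two nodes share a position.
    """
    positions: dict = {}
    offsets: dict = {}
    y_origin = 0.0
    for comp in components(g):
        comp_key = min(comp.nodes)
        offsets[comp_key] = y_origin
        sub_nodes = comp.nodes
        # leaf rows by DFS from roots, children ordered by (object, image) index
        next_row = 0
        rows: dict = {}
        visited = set()
        roots = sorted(comp.root_nodes) or [min(sub_nodes)]
        for root in roots:
            stack = [root]
            while stack:
                n = stack.pop()
                if n in visited:
                    continue
                visited.add(n)
                succ = sorted(g.successors(n), key=lambda m: (m[1], m[0]))
                if not succ:
                    rows[n] = float(next_row)
                    next_row += 1
                else:
                    stack.extend(reversed(succ))
        # internal rows: mean of children, reverse topological order
        sub = g.subgraph(sub_nodes)
        for n in reversed(list(nx.topological_sort(sub))):
            if n not in rows:
                rows[n] = float(np.mean([rows[c] for c in sub.successors(n)]))
        for n in sub_nodes:
            positions[n] = (float(g.nodes[n]["timepoint"]), rows[n] + y_origin)
        y_origin += max(next_row, 1) + 1  # 1-row gap between components
    # enforce injectivity: deterministic epsilon nudge on exact collisions
    seen: dict = {}
    for n in sorted(positions):
        pos = positions[n]
        k = seen.get(pos, 0)
        seen[pos] = k + 1
        if k:
            positions[n] = (pos[0], pos[1] + 0.001 * k)
    return LineageLayout(positions, offsets)


def _flag_styles(flags: QCReport | None) -> dict:
    """NodeID -> flag kind, applying the styling precedence."""
    if flags is None:
        return {}
    styled: dict = {}
    for s in flags.singletons:
        for n in s.component.nodes:
            styled[n] = "singleton"
    for l in flags.loops:
        for branch in l.branches:
            for n in branch:
                styled[n] = "loop"
    for c in flags.crossings:
        for n in c.chain:
            styled[n] = "crossing"
    return styled


def render_lineage(
    g: nx.DiGraph,
    layout: LineageLayout | None = None,
    colormap: ColorMap | None = None,
    flags: QCReport | None = None,
    out="lineage.png",
) -> dict:
    """Draw the lineage tree; returns the manifest dict."""
    if layout is None:
        layout = layout_lineage(g)
    fig, ax = plt.subplots(figsize=(10, 6))
    cmap = plt.get_cmap("viridis")
    for u, v, d in g.edges(data=True):
        (x0, y0), (x1, y1) = layout.positions[u], layout.positions[v]
        ax.plot([x0, x1], [y0, y1], "-" if d["frame_gap"] == 1 else "--",
                color="0.6", lw=0.8, zorder=1)
    styled = _flag_styles(flags)
    nodes = sorted(g.nodes)
    xs = [layout.positions[n][0] for n in nodes]
    ys = [layout.positions[n][1] for n in nodes]
    if colormap is not None:
        colors = [cmap(colormap.node_values.get(n, 0.0)) if n not in colormap.missing_nodes
                  else (0.7, 0.7, 0.7, 1.0) for n in nodes]
    else:
        colors = ["#1f77b4"] * len(nodes)
    edgecolors = [FLAG_COLORS.get(styled.get(n), "none") for n in nodes]
    lws = [1.8 if n in styled else 0.0 for n in nodes]
    ax.scatter(xs, ys, c=colors, edgecolors=edgecolors, linewidths=lws, s=28, zorder=2)
    ax.set_xlabel("timepoint")
    ax.set_yticks([])
    ax.invert_yaxis()
    _savefig(fig, out)
    flag_counts = {kind: sum(1 for k in styled.values() if k == kind)
                   for kind in FLAG_PRECEDENCE}
    return _write_manifest(out, {
        "view": "lineage",
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_gap_edges": sum(1 for *_, d in g.edges(data=True) if d["frame_gap"] > 1),
        "n_flagged": len(styled),
        "flag_counts": flag_counts,
        "flagged_nodes": sorted([list(n) for n in styled]),
        "color_feature": colormap.feature_name if colormap else None,
        "color_range": list(colormap.scale) if colormap else None,
        "file": Path(out).name,
    })


# ---------------------------------------------------------------------------
# XYT plot


def _segment_polylines(g: nx.DiGraph, colormap: ColorMap | None):
    segs = branch_free_segments(g)
    polylines = []
    for s in segs:
        pts = [(g.nodes[n]["x"], g.nodes[n]["y"], g.nodes[n]["timepoint"]) for n in s.nodes]
        cols = [colormap.node_values.get(n, 0.0) if colormap else
                g.nodes[n]["timepoint"] for n in s.nodes]
        polylines.append((s, pts, cols))
    return polylines


def render_xyt(g: nx.DiGraph, colormap: ColorMap | None = None, out="xyt.png") -> dict:
    """3-D centroid-versus-time plot, one polyline per branch-free segment.

    ``out`` ending in ``.html`` produces a standalone rotatable HTML export;
    any other suffix a static matplotlib 3-D image.  Per-vertex color comes
    from the colormap (frame number when none is given).
    """
    polylines = _segment_polylines(g, colormap)
    out = Path(out)
    if out.suffix == ".html":
        _render_xyt_html(polylines, colormap, out)
    else:
        fig = plt.figure(figsize=(8, 7))
        ax = fig.add_subplot(projection="3d")
        cmap = plt.get_cmap("viridis")
        tmax = max((g.nodes[n]["timepoint"] for n in g.nodes), default=1) or 1
        for _, pts, cols in polylines:
            xs, ys, ts = zip(*pts)
            norm = [c if colormap else c / tmax for c in cols]
            ax.plot(xs, ys, ts, color="0.75", lw=0.6)
            ax.scatter(xs, ys, ts, c=[cmap(v) for v in norm], s=6)
        ax.set_xlabel("x (px)")
        ax.set_ylabel("y (px)")
        ax.set_zlabel("t (frame)")
        _savefig(fig, out)
    color_values = [v for _, _, cols in polylines for v in cols] or [0.0]
    return _write_manifest(out, {
        "view": "xyt",
        "n_segments": len(polylines),
        "n_vertices": sum(len(pts) for _, pts, _ in polylines),
        "color_feature": colormap.feature_name if colormap else "timepoint",
        "color_min": min(color_values),
        "color_max": max(color_values),
        "file": out.name,
    })


_XYT_HTML = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>XYT plot</title>
<style>body{{margin:0;background:#111;color:#ddd;font:13px sans-serif}}
#hud{{position:fixed;top:8px;left:8px}}</style></head>
<body><div id="hud">drag to rotate &mdash; {n} trajectory segments</div>
<canvas id="c"></canvas>
<script>
const SEGS = {segments_json};
const cv = document.getElementById('c'), ctx = cv.getContext('2d');
let ax = -1.0, az = 0.6, drag = null;
function viridis(t) {{
  t = Math.min(1, Math.max(0, t));
  const r = Math.round(255*(0.267+t*(0.005+t*(2.5-1.78*t))*0.38));
  const g = Math.round(255*(0.005+1.39*t-0.4*t*t));
  const b = Math.round(255*(0.329+t*(1.8-t*(3.6-1.9*t))*0.55));
  return `rgb(${{r}},${{g}},${{b}})`;
}}
function draw() {{
  cv.width = innerWidth; cv.height = innerHeight;
  ctx.fillStyle = '#111'; ctx.fillRect(0, 0, cv.width, cv.height);
  const ca = Math.cos(ax), sa = Math.sin(ax), cz = Math.cos(az), sz = Math.sin(az);
  const s = Math.min(cv.width, cv.height) * 0.4;
  for (const seg of SEGS) {{
    let prev = null;
    for (let i = 0; i < seg.p.length; i++) {{
      const [x, y, t] = seg.p[i];
      const x1 = x*cz - y*sz, y1 = x*sz + y*cz;
      const y2 = y1*ca - t*sa, z2 = y1*sa + t*ca;
      const px = cv.width/2 + x1*s, py = cv.height/2 - z2*s;
      if (prev) {{
        ctx.strokeStyle = viridis(seg.c[i]); ctx.lineWidth = 1.2;
        ctx.beginPath(); ctx.moveTo(prev[0], prev[1]); ctx.lineTo(px, py); ctx.stroke();
      }}
      prev = [px, py];
    }}
  }}
}}
cv.onmousedown = e => drag = [e.clientX, e.clientY];
window.onmouseup = () => drag = null;
window.onmousemove = e => {{
  if (!drag) return;
  az += (e.clientX - drag[0]) * 0.01; ax += (e.clientY - drag[1]) * 0.01;
  drag = [e.clientX, e.clientY]; draw();
}};
window.onresize = draw;
draw();
</script></body></html>
"""


def _render_xyt_html(polylines, colormap, out: Path) -> None:
    # normalize coordinates to [-0.5, 0.5] cube; colors to [0, 1]
    allpts = np.array([p for _, pts, _ in polylines for p in pts], dtype=float)
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    allcols = [c for _, _, cols in polylines for c in cols]
    cmin, cmax = min(allcols), max(allcols)
    crange = (cmax - cmin) or 1.0
    segments = []
    for _, pts, cols in polylines:
        norm = ((np.array(pts) - lo) / span - 0.5).round(4)
        segments.append({
            "p": [[float(a), float(b), float(c)] for a, b, c in norm],
            "c": [round((c - cmin) / crange, 4) for c in cols],
        })
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(_XYT_HTML.format(n=len(segments),
                                    segments_json=json.dumps(segments, sort_keys=True)))


# ---------------------------------------------------------------------------
# synchrogram


@dataclass(frozen=True)
class Synchrogram:
    """Ordered stack of patches centered on one object through time."""

    node_sequence: Trajectory
    patches: tuple  # 2-D arrays, all W x H
    frame_labels: tuple  # timepoints, including gap frames
    missing_frames: frozenset = frozenset()


class ImageFileProvider:
    """Resolve movie frames from the image table's ``image_path`` column.

    Supports TIFF (via tifffile) and PNG (via matplotlib); multichannel
    images are reduced to their first channel.
    """

    def __init__(self, ds: TrackingDataset, base_dir=None):
        if "image_path" not in ds.images.columns:
            raise ValueError("image table has no image_path column")
        self._paths = dict(zip(ds.images["image_index"].astype(int), ds.images["image_path"]))
        self._base = Path(base_dir) if base_dir else None

    def __getitem__(self, image_index: int) -> np.ndarray:
        try:
            p = Path(self._paths[int(image_index)])
        except KeyError:
            raise IOError(f"no frame registered for image_index {image_index}")
        if self._base and not p.is_absolute():
            p = self._base / p
        if not p.exists():
            raise IOError(f"frame file not found: {p}")
        if p.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(p)
        else:
            arr = plt.imread(p)
        if arr.ndim == 3:
            arr = arr[..., 0]
        return np.asarray(arr)


def _crop_centered(frame: np.ndarray, x: float, y: float, w: int, h: int) -> np.ndarray:
    """W×H window of ``frame`` centered at the rounded centroid (x = column,
    y = row, numpy round-half-to-even), zero-padded at the borders."""
    col, row = int(np.rint(x)), int(np.rint(y))
    patch = np.zeros((h, w), dtype=frame.dtype)
    r0, c0 = row - h // 2, col - w // 2
    sr0, sc0 = max(r0, 0), max(c0, 0)
    sr1, sc1 = min(r0 + h, frame.shape[0]), min(c0 + w, frame.shape[1])
    if sr1 > sr0 and sc1 > sc0:
        patch[sr0 - r0:sr1 - r0, sc0 - c0:sc1 - c0] = frame[sr0:sr1, sc0:sc1]
    return patch


def extract_synchrogram(
    ds: TrackingDataset,
    frames,
    traj: Trajectory,
    patch: tuple = DEFAULT_PATCH_SIZE,
) -> Synchrogram:
    """Crop a patch around the object's centroid in each trajectory frame.

    ``frames`` maps image_index → 2-D array (a dict or an
    :class:`ImageFileProvider`).  ``patch`` is (W, H) in pixels, both odd so
    the centroid pixel is the exact patch center.  Timepoints skipped by
    gap-closing links yield blank placeholder patches listed in
    ``missing_frames``.
    """
    w, h = patch
    if w < 1 or h < 1 or w % 2 == 0 or h % 2 == 0:
        raise ValueError(f"patch dimensions must be odd positive integers, got {patch}")
    tp = ds.timepoint_map()
    obj = ds.objects.set_index(["image_index", "object_index"])
    patches, labels, missing = [], [], set()
    prev_t = None
    for node in traj.nodes:
        t = tp[node[0]]
        if prev_t is not None:
            for gap_t in range(prev_t + 1, t):  # gap placeholders
                patches.append(np.zeros((h, w)))
                labels.append(gap_t)
                missing.add(gap_t)
        row = obj.loc[node]
        frame = frames[node[0]]
        patches.append(_crop_centered(np.asarray(frame), float(row["x"]), float(row["y"]), w, h))
        labels.append(t)
        prev_t = t
    return Synchrogram(traj, tuple(patches), tuple(labels), frozenset(missing))


def render_synchrogram(sync: Synchrogram, out="synchrogram.png") -> dict:
    """Draw the patch filmstrip; gap frames appear as crossed-out blanks."""
    n = len(sync.patches)
    fig, axes = plt.subplots(1, n, figsize=(max(1.2 * n, 2), 1.8), squeeze=False)
    finite = [p for t, p in zip(sync.frame_labels, sync.patches)
              if t not in sync.missing_frames]
    vmax = max((float(np.max(p)) for p in finite), default=1.0) or 1.0
    for ax, patch_arr, t in zip(axes[0], sync.patches, sync.frame_labels):
        if t in sync.missing_frames:
            ax.imshow(np.zeros_like(patch_arr, dtype=float), cmap="gray", vmin=0, vmax=1)
            ax.plot([0, patch_arr.shape[1] - 1], [0, patch_arr.shape[0] - 1], "r-", lw=0.8)
            ax.set_title(f"t={t} (gap)", fontsize=6)
        else:
            ax.imshow(patch_arr, cmap="gray", vmin=0, vmax=vmax)
            ax.set_title(f"t={t}", fontsize=6)
        ax.set_xticks([]), ax.set_yticks([])
    _savefig(fig, out)
    return _write_manifest(out, {
        "view": "synchrogram",
        "n_patches": n,
        "n_missing": len(sync.missing_frames),
        "patch_shape": list(sync.patches[0].shape) if n else None,
        "frame_labels": list(sync.frame_labels),
        "file": Path(out).name,
    })


# ---------------------------------------------------------------------------
# heatmap


def render_heatmap(m, out="heatmap.png") -> dict:
    """Render a normalized timepoints × features heatmap.

    Missing cells are drawn in a distinct hatch color, never as 0."""
    if not m.normalized:
        raise ValueError("heatmap expects a normalized matrix (minmax_normalize first)")
    values = m.values.to_numpy(dtype=float).T  # features on rows
    masked = np.ma.masked_invalid(values)
    fig, ax = plt.subplots(figsize=(10, max(2, 0.3 * values.shape[0])))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("lightgray")
    im = ax.imshow(masked, aspect="auto", cmap=cmap, vmin=0, vmax=1,
                   interpolation="nearest")
    ax.set_xlabel("timepoint")
    ax.set_yticks(range(values.shape[0]))
    ax.set_yticklabels(m.feature_names, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    _savefig(fig, out)
    return _write_manifest(out, {
        "view": "heatmap",
        "n_timepoints": int(values.shape[1]),
        "n_features": int(values.shape[0]),
        "n_missing_cells": int(np.isnan(values).sum()),
        "value_min": float(np.nanmin(values)) if np.isfinite(values).any() else None,
        "value_max": float(np.nanmax(values)) if np.isfinite(values).any() else None,
        "features": list(m.feature_names),
        "file": Path(out).name,
    })
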