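"""Ground-truthed synthetic time-lapse tracking data.

Emulates a movie of tracked nuclei at toy scale: objects perform reflected
Gaussian random walks inside the frame, divide into two children, and may
transiently disappear for one frame (gap-closed links).  On top of the
clean movie, the three tracking-artifact topologies can be injected in
known, topologically isolated locations so that detector counts are exact
rather than statistical:

* **loop** — a spurious extra detection q between frames t and t+2 of one
  track, wired a_t → q and q → a_(t+2): a transient incorrect split.
* **crossing** — two tracks fused for two frames: the observations of track
  B at t+1 and t+2 are deleted and replaced by links b_t → a_(t+1) and
  a_(t+2) → b_(t+3): a merge followed by a split.
* **singleton** — an isolated spurious detection in a single random frame.

Artifact host tracks are kept free of divisions and gaps, and each artifact
gets its own host(s), so no two artifacts interact.  Features are smooth
sinusoidal per-track signals plus Gaussian noise; one column
(``frame_ramp``) deterministically equals the timepoint, which normalizes
to an exact linear ramp in the heatmap.  Everything is reproducible from
the integer seed (numpy PCG64).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import schema_io
from .schema_io import TrackingDataset

RAMP_FEATURE = "frame_ramp"


class SimulationError(ValueError):
    """Requested artifact counts cannot fit the movie size."""


@dataclass(frozen=True)
class SimParams:
    """Movie-generation parameters.

    Defaults emulate a modest single-site nuclear-tracking movie: 10
    starting nuclei followed for 30 frames in a 256×256 px field, ~2 px/frame
    Brownian motion, occasional divisions and one-frame detection dropouts.
    """

    n_initial: int = 10
    n_frames: int = 30
    frame_size: tuple = (256, 256)  # (W, H) pixels
    motion_sigma: float = 2.0  # px per frame
    division_prob: float = 0.02  # per object per frame
    gap_prob: float = 0.02  # per interior link
    n_loops: int = 0
    n_crossings: int = 0
    n_singletons: int = 0
    n_features: int = 3
    synchronized_divisions: bool = False  # all tracks divide at shared frames
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise SimulationError("n_frames must be >= 2")
        if not (0 <= self.division_prob <= 1 and 0 <= self.gap_prob <= 1):
            raise SimulationError("probabilities must lie in [0, 1]")
        if min(self.n_initial, self.n_features, self.n_loops,
               self.n_crossings, self.n_singletons) < 0 or self.n_initial == 0:
            raise SimulationError("counts must be non-negative (n_initial >= 1)")
        n_hosts = self.n_loops + 2 * self.n_crossings
        if n_hosts > self.n_initial:
            raise SimulationError(
                f"{self.n_loops} loops + {self.n_crossings} crossings need "
                f"{n_hosts} host tracks but n_initial={self.n_initial}; "
                "increase n_initial"
            )
        if self.n_loops and self.n_frames < 5:
            raise SimulationError("loops need n_frames >= 5; increase n_frames")
        if self.n_crossings and self.n_frames < 7:
            raise SimulationError("crossings need n_frames >= 7; increase n_frames")


@dataclass(frozen=True)
class GroundTruth:
    """What was injected, as final (image_index, object_index) node ids."""

    injected_loops: tuple = ()  # ((split, merge), ...)
    injected_crossings: tuple = ()  # ((merge, split), ...)
    injected_singletons: tuple = ()
    division_events: tuple = ()  # parent nodes

    def to_json(self, path=None) -> str:
        doc = {
            "injected_loops": [[list(a), list(b)] for a, b in self.injected_loops],
            "injected_crossings": [[list(a), list(b)] for a, b in self.injected_crossings],
            "injected_singletons": [list(n) for n in self.injected_singletons],
            "division_events": [list(n) for n in self.division_events],
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        pair = lambda p: (tuple(p[0]), tuple(p[1]))  # noqa: E731
        return cls(
            tuple(pair(p) for p in doc["injected_loops"]),
            tuple(pair(p) for p in doc["injected_crossings"]),
            tuple(tuple(n) for n in doc["injected_singletons"]),
            tuple(tuple(n) for n in doc["division_events"]),
        )


class _Track:
    __slots__ = ("tid", "protected", "obs", "sig_base", "sig_amp", "sig_period", "sig_phase")

    def __init__(self, tid, protected, rng, n_features):
        self.tid = tid
        self.protected = protected
        self.obs = []  # obs ids in frame order
        self.sig_base = rng.uniform(0.3, 0.7, n_features)
        self.sig_amp = rng.uniform(0.1, 0.4, n_features)
        self.sig_period = rng.uniform(8.0, 20.0, n_features)
        self.sig_phase = rng.uniform(0.0, 1.0, n_features)


def _grid_positions(n, w, h, rng):
    """Jittered grid start positions, keeping objects well separated."""
    cols = int(np.ceil(np.sqrt(n)))
    rowsn = int(np.ceil(n / cols))
    xs = np.linspace(w * 0.1, w * 0.9, cols)
    ys = np.linspace(h * 0.1, h * 0.9, rowsn)
    pts = [(x, y) for y in ys for x in xs][:n]
    jitter = rng.normal(0, min(w, h) * 0.01, (n, 2))
    return [(float(np.clip(x + jx, 0, w - 1)), float(np.clip(y + jy, 0, h - 1)))
            for (x, y), (jx, jy) in zip(pts, jitter)]


def _reflect(v, lo, hi):
    while v < lo or v > hi:
        v = 2 * lo - v if v < lo else 2 * hi - v
    return v


def simulate(params: SimParams):
    """Generate a movie; returns ``(TrackingDataset, GroundTruth)``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    w, h = params.frame_size
    nF = params.n_frames

    obs_frame, obs_x, obs_y, obs_track = {}, {}, {}, {}
    edges = []  # (parent_obs, child_obs)
    next_obs = [0]
    division_parents = []

    def add_obs(frame, x, y, track):
        oid = next_obs[0]
        next_obs[0] += 1
        obs_frame[oid], obs_x[oid], obs_y[oid], obs_track[oid] = frame, float(x), float(y), track
        track.obs.append(oid)
        return oid

    n_protected = params.n_loops + 2 * params.n_crossings
    tracks = [
        _Track(i, i < n_protected, rng, params.n_features) for i in range(params.n_initial)
    ]
    positions = dict(zip(range(params.n_initial), _grid_positions(params.n_initial, w, h, rng)))
    active = {t.tid: t for t in tracks}
    next_tid = params.n_initial
    sync_frames = ({nF // 3, (2 * nF) // 3} if params.synchronized_divisions else set())

    for frame in range(nF):
        for tid in sorted(active):
            track = active[tid]
            x, y = positions[tid]
            if track.obs:  # already born: take a random step
                x = _reflect(x + rng.normal(0, params.motion_sigma), 0, w - 1)
                y = _reflect(y + rng.normal(0, params.motion_sigma), 0, h - 1)
                positions[tid] = (x, y)
            add_obs(frame, x, y, track)
        # division decisions (children must span >= 2 frames)
        if frame <= nF - 3:
            for tid in sorted(active):
                track = active[tid]
                if track.protected:
                    continue
                divide = (frame in sync_frames) if params.synchronized_divisions else (
                    rng.random() < params.division_prob
                )
                if divide:
                    division_parents.append(track.obs[-1])
                    px, py = positions[tid]
                    del active[tid]
                    for dx in (-3.0, 3.0):
                        child = _Track(next_tid, False, rng, params.n_features)
                        tracks.append(child)
                        positions[next_tid] = (
                            _reflect(px + dx + rng.normal(0, 1), 0, w - 1),
                            _reflect(py + rng.normal(0, 1), 0, h - 1),
                        )
                        active[next_tid] = child
                        edges.append((track.obs[-1], "BIRTH", next_tid))
                        next_tid += 1

    # gaps: drop one interior observation per selected link position
    removed = set()
    for track in tracks:
        if track.protected or params.gap_prob == 0 or len(track.obs) < 4:
            continue
        prev_dropped = True  # protects the first obs
        for oid in track.obs[1:-1]:
            if not prev_dropped and rng.random() < params.gap_prob:
                removed.add(oid)
                prev_dropped = True
            else:
                prev_dropped = False

    # ---- artifact injection on protected hosts -----------------------------
    gt_loops, gt_crossings, gt_singletons = [], [], []
    forbidden_links = set()  # chain links suppressed by crossing rewiring
    host_iter = iter(range(n_protected))
    for _ in range(params.n_loops):
        track = tracks[next(host_iter)]
        t = int(rng.integers(1, nF - 3 + 1))
        a_t, a_t1, a_t2 = track.obs[t], track.obs[t + 1], track.obs[t + 2]
        q = next_obs[0]
        next_obs[0] += 1
        obs_frame[q] = t + 1
        obs_x[q] = float(np.clip(obs_x[a_t1] + 5.0, 0, w - 1))
        obs_y[q] = float(np.clip(obs_y[a_t1] + 5.0, 0, h - 1))
        obs_track[q] = track
        edges.append((a_t, q))
        edges.append((q, a_t2))
        gt_loops.append((a_t, a_t2))
    for _ in range(params.n_crossings):
        ta, tb = tracks[next(host_iter)], tracks[next(host_iter)]
        t = int(rng.integers(1, nF - 4 + 1))
        removed.add(tb.obs[t + 1])
        removed.add(tb.obs[t + 2])
        edges.append((tb.obs[t], ta.obs[t + 1]))
        edges.append((ta.obs[t + 2], tb.obs[t + 3]))
        forbidden_links.add((tb.obs[t], tb.obs[t + 3]))
        gt_crossings.append((ta.obs[t + 1], ta.obs[t + 2]))
    for _ in range(params.n_singletons):
        frame = int(rng.integers(0, nF))
        track = _Track(next_tid, True, rng, params.n_features)
        next_tid += 1
        oid = next_obs[0]
        next_obs[0] += 1
        obs_frame[oid] = frame
        obs_x[oid] = float(rng.uniform(0, w - 1))
        obs_y[oid] = float(rng.uniform(0, h - 1))
        obs_track[oid] = track
        track.obs.append(oid)
        gt_singletons.append(oid)

    # ---- resolve edges -----------------------------------------------------
    final_edges = []
    for track in tracks:
        surviving = [o for o in track.obs if o not in removed]
        final_edges.extend(
            pair for pair in zip(surviving, surviving[1:]) if pair not in forbidden_links
        )
    birth_of = {}  # tid -> first obs
    for track in tracks:
        surviving = [o for o in track.obs if o not in removed]
        if surviving:
            birth_of[track.tid] = surviving[0]
    for e in edges:
        if len(e) == 3:  # division: parent obs -> first obs of child track
            parent, _, child_tid = e
            if parent not in removed and child_tid in birth_of:
                final_edges.append((parent, birth_of[child_tid]))
        else:
            parent, child = e
            if parent not in removed and child not in removed:
                final_edges.append((parent, child))

    # ---- assemble tables ---------------------------------------------------
    images = pd.DataFrame(
        {
            "image_index": np.arange(1, nF + 1, dtype=int),
            "group_index": 0,
            "timepoint": np.arange(nF, dtype=int),
        }
    )
    all_obs = sorted(o for o in obs_frame if o not in removed)
    node_of = {}
    counters = {f: 0 for f in range(nF)}
    rows = []
    noise = rng.normal(0.0, 0.02, (len(all_obs), params.n_features))
    for i, oid in enumerate(sorted(all_obs, key=lambda o: (obs_frame[o], o))):
        f = obs_frame[oid]
        counters[f] += 1
        node = (f + 1, counters[f])
        node_of[oid] = node
        track = obs_track[oid]
        sig = track.sig_base + track.sig_amp * np.sin(
            2 * np.pi * (f / track.sig_period + track.sig_phase)
        )
        row = {
            "image_index": node[0],
            "object_index": node[1],
            "x": obs_x[oid],
            "y": obs_y[oid],
            RAMP_FEATURE: float(f),
        }
        for j in range(params.n_features):
            row[f"feat_{j:02d}"] = float(sig[j] + noise[i, j])
        rows.append(row)
    feature_names = [RAMP_FEATURE] + [f"feat_{j:02d}" for j in range(params.n_features)]
    objects = pd.DataFrame(rows, columns=["image_index", "object_index", "x", "y"] + feature_names)

    rel_rows = sorted(
        (node_of[c][0], node_of[c][1], node_of[p][0], node_of[p][1]) for p, c in final_edges
    )
    relationships = pd.DataFrame(
        rel_rows, columns=schema_io.RELATIONSHIP_COLUMNS
    ).astype(int) if rel_rows else pd.DataFrame(
        {c: pd.Series([], dtype=int) for c in schema_io.RELATIONSHIP_COLUMNS}
    )

    ds = TrackingDataset(images, objects, relationships, feature_names)
    gt = GroundTruth(
        tuple((node_of[a], node_of[b]) for a, b in gt_loops),
        tuple((node_of[a], node_of[b]) for a, b in gt_crossings),
        tuple(node_of[o] for o in gt_singletons),
        tuple(node_of[o] for o in division_parents if o not in removed),
    )
    return ds, gt


def render_frames(ds: TrackingDataset, out_dir, blob_sigma: float = 2.0) -> list:
    """Render one grayscale TIFF per frame, objects as Gaussian blobs whose
    peak sits exactly at the rounded centroid pixel.  Filenames are written
    back into the image table's ``image_path`` column; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # frame size from centroid extent (round up to a margin)
    w = int(np.ceil(ds.objects["x"].max())) + 16 if len(ds.objects) else 64
    h = int(np.ceil(ds.objects["y"].max())) + 16 if len(ds.objects) else 64
    reach = int(np.ceil(4 * blob_sigma))
    paths = []
    by_image = dict(tuple(ds.objects.groupby("image_index")))
    for row in ds.images.itertuples(index=False):
        img = np.zeros((h, w), dtype=np.float64)
        for obj in by_image.get(row.image_index, pd.DataFrame()).itertuples(index=False):
            c0, r0 = int(np.rint(obj.x)), int(np.rint(obj.y))
            rr = np.arange(max(r0 - reach, 0), min(r0 + reach + 1, h))
            cc = np.arange(max(c0 - reach, 0), min(c0 + reach + 1, w))
            if not len(rr) or not len(cc):
                continue
            blob = np.exp(
                -((rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2) / (2 * blob_sigma**2)
            )
            img[np.ix_(rr, cc)] = np.maximum(img[np.ix_(rr, cc)], blob)
        fname = f"frame_{int(row.timepoint):04d}.tif"
        tifffile.imwrite(out_dir / fname, (img * 65535).astype(np.uint16))
        paths.append(out_dir / fname)
    ds.images["image_path"] = [p.name for p in paths]
    return paths


def write_fixture(params: SimParams, path, dialect: str = "sqlite", render: bool = False):
    """simulate + persist + ground-truth JSON sidecar; returns (ds, gt)."""
    ds, gt = simulate(params)
    if render:
        render_frames(ds, Path(path).parent / (Path(path).name + "_frames"))
    schema_io.write_dataset(ds, path, dialect)
    gt.to_json(str(path) + "_ground_truth.json")
    params_doc = asdict(params)
    params_doc["frame_size"] = list(params_doc["frame_size"])
    Path(str(path) + "_params.json").write_text(json.dumps(params_doc, sort_keys=True, indent=1))
    ds.source = (str(path), dialect)
    return ds, gt
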