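# Methods

## Data model

`trackqc` operates on the minimal three-table schema that high-content
tracking exporters write:

* **image table** — one row per acquired frame. Required: an integer
  `image_index` unique across the table. Optional: `group_index` (field of
  view / site, default 0), `timepoint` (frame ordinal within the group;
  when absent it is derived as the 0-based rank of `image_index` within its
  group, matching how exporters number frames), `image_path`, and arbitrary
  pass-through metadata columns.
* **object table** — one row per detection, keyed by
  `(image_index, object_index)`, with centroid columns `x`, `y`. Every
  remaining *numeric* column is treated as a feature; non-numeric columns
  are ignored with a logged warning, because the feature set is open-ended
  and tool-specific.
* **relationship table** — one parent→child link per row, both endpoints
  referencing the object table, parent strictly earlier in time.

Column names are resolved case-insensitively through configurable alias
lists (`Location_Center_X`-style names work out of the box); table names
are remappable. Coordinates are 0-based pixels, x = column, y = row,
origin top-left — this convention must (and does) match the synchrogram
cropping code. Storage dialects: a single SQLite file, or a CSV triplet
`<prefix>_image.csv` / `<prefix>_object.csv` / `<prefix>_relationships.csv`
(UTF-8, header row). CSV floats are written by `repr` and re-read with the
round-trip parser, so both dialects reproduce datasets bit-identically.
A MySQL backend is deliberately out of scope; the schema contract is
identical, so one could be added without API changes.

Validation reports (never raises) one violation per broken invariant —
duplicate keys, non-finite centroids, dangling references, non-increasing
timepoints, parent-not-before-child ordering, duplicate links — each with a
rule id and the offending keys; reading raises unless explicitly asked to
load broken data for inspection.

## Lineage graph

One node per detection, one edge per link, edge attribute
`frame_gap` = Δtimepoint ≥ 1. Gap-closed links are single edges with
`frame_gap` > 1; no phantom nodes are interpolated, since the schema stores
only observed objects. Edges joining different groups are rejected. The
graph is a DAG by construction (time strictly increases along edges).

Two decompositions serve different purposes:

* **Weakly connected components** are the unit of "track" for length
  statistics and singleton detection. Splits and merges make root-to-leaf
  path enumeration combinatorial, whereas components match how lineage
  trees group cells. A component's *span* is its number of distinct
  occupied timepoints — frames skipped by gap closure do not count.
* **Branch-free segments** (maximal unbranched directed paths; interior
  nodes have in-degree = out-degree = 1) are the drawing unit for XYT
  polylines and synchrograms. Every edge belongs to exactly one segment;
  split/merge nodes appear in each incident segment. Whether a trajectory's
  identity "continues" through a merge is intentionally left undefined —
  segments end there.

All orderings are deterministic (sorted by node id), so exports and reports
are byte-identical run to run.

## Topology deviations

* **Loop**: split node `u` whose out-branches reconverge at a common
  descendant via ≥ 2 node-disjoint directed paths. For each split only the
  earliest reconvergence (smallest (timepoint, node id)) is reported, which
  captures the transient-incorrect-split pattern while bounding output
  size. Candidate merges are tested with a max-flow-based node-disjoint
  path computation; the test suite checks exact agreement against an
  independent exhaustive path-pair enumerator on random DAGs.
* **Crossing**: merge node followed by a split node through an unbranched
  chain, including the degenerate single node with in-degree ≥ 2 and
  out-degree ≥ 2 (duration 0). The chain requirement prevents double
  counting with loops. Loops and crossings are detected independently; a
  node may belong to both.
* **Singleton**: component with span ≤ `max_length`. The default threshold
  is 1 frame and is researcher-adjustable; counting *occupied timepoints*
  (rather than node count) was chosen so gap-closed tracks are not
  penalized for missed detections. Pruning removes flagged components
  wholesale, never touches longer components, is idempotent, and the
  surviving relationship rows can be persisted as a named derived table
  (`relationship__<name>`) next to the untouched originals.

"Transient" is operationalized as an optional `max_duration` filter on
loop/crossing duration (merge−split time difference, regardless of branch
shape); the default reports all events, since no principled universal
cutoff exists.

Percentiles of track lengths use linear interpolation between closest order
statistics (numpy's default `linear` method), pinned by tests so the exact
rule is part of the contract.

Detection is advisory: flags mark *suspect* nodes; their absence does not
establish correct tracking, and no automatic correction of loops or
crossings is attempted (only singleton pruning, which is safe).

## Feature summaries

The heatmap matrix holds, for each timepoint, the arithmetic mean of each
feature over all objects present at that timepoint (groups pooled by
default; a per-group switch exists). Raw values are averaged first and the
matrix normalized afterwards, per feature, to [0, 1] over its finite cells.
Conventions chosen where several were defensible:

* zero-range (constant) features normalize to 0 — a constant is "no
  signal", and mapping to 0 keeps the output inside [0, 1];
* timepoints with no objects stay as missing cells and are rendered
  distinctly, never interpolated and never drawn as 0 — the heatmap exists
  to *reveal* dropouts (e.g. a transiently out-of-focus frame), so filling
  them would defeat its purpose.

Node color maps support a global min-max scale and a percentile scale
(default 2nd–98th) with tail clipping for heavy-tailed features; values are
clipped to [0, 1], missing values are flagged for neutral rendering.

## Visualization

* **Lineage layout**: x = timepoint. Within a component, leaves receive
  consecutive integer rows in depth-first order (children visited by
  ascending object index); every internal node sits at the mean row of its
  children, computed in reverse topological order so merge nodes also
  follow their children (child-side resolution). Components stack with a
  one-row gap. Exact position collisions (possible in pathological
  topologies) are broken by a deterministic 0.001-row nudge, preserving
  injectivity. Gap-closing edges are drawn dashed. When a node carries
  several flags, crossing styling wins over loop over singleton (a fixed,
  documented precedence).
* **XYT**: one 3-D polyline per branch-free segment through (x, y, t);
  static matplotlib PNG, or a standalone HTML export with a small embedded
  canvas renderer for mouse-drag rotation (keeps the library headless — no
  GUI toolkit dependency).
* **Synchrogram**: per trajectory node, a W×H window (default 61×61, both
  odd so the centroid pixel is the exact center) cropped around the
  rounded centroid (nearest integer, ties to even), zero-padded at frame
  borders; timepoints skipped by gap closure yield labeled blank
  placeholders. Frames are resolved from the image table's `image_path`
  (TIFF or PNG).
* **Heatmap**: features × timepoints image, missing cells in a distinct
  color, requires a normalized matrix.

Every renderer writes a deterministic sidecar manifest JSON (counts, color
ranges, file name) so downstream checks never parse pixels.

## Synthetic data generator

The simulator emulates a single-site nuclear-tracking movie at toy scale:
`n_initial` objects start on a jittered grid (well separated), perform
reflected Gaussian random walks (`motion_sigma`, default 2 px/frame —
subpixel-to-few-pixel per-frame motion typical of imaging intervals chosen
for trackability), divide with per-object per-frame probability
`division_prob` (default 0.02; divisions are barred in the last two frames
so children exist for ≥ 2 frames) and drop single-frame detections with
per-link probability `gap_prob` (default 0.02, producing `frame_gap` = 2
links). A synchronized-division mode makes all tracks divide at two shared
frames, emulating syncytial embryos for heatmap demonstrations. Features
are per-track sinusoids (base, amplitude, period, phase drawn per track)
plus N(0, 0.02) noise, and one column (`frame_ramp`) deterministically
equals the timepoint — after normalization it must be an exact linear ramp,
a built-in end-to-end check of the heatmap path.

Artifacts are injected by rewiring relationship rows on dedicated host
tracks that are kept free of divisions and gaps; each artifact uses its own
host(s), so artifacts are topologically isolated from each other and from
natural splits, and detector counts are exact rather than statistical:

* loop: spurious extra detection `q` at t+1 with links a_t→q and q→a_(t+2)
  on one host chain;
* crossing: two host chains A, B; B's detections at t+1, t+2 are deleted
  and replaced by links b_t→a_(t+1) and a_(t+2)→b_(t+3);
* singleton: an isolated detection at a uniformly random frame/position.

Requested counts that cannot fit (`n_loops + 2·n_crossings > n_initial`,
or too few frames for the rewiring windows) raise an error advising larger
`n_initial`/`n_frames`. All randomness flows through one numpy PCG64
generator seeded by `seed`, so identical parameters give identical tables
across platforms. `render_frames` draws each detection as a Gaussian blob
(default σ = 2 px) whose peak sits exactly on the rounded centroid pixel —
the property the synchrogram centering tests rely on.

**What the simulator does not emulate:** photorealistic microscopy (noise
floors, uneven illumination, blur), object appearance/disappearance at
frame borders, cell death, densities high enough for frequent occlusion,
3-D stacks, or tracker-specific failure modes beyond the three injected
topologies. Passing tests therefore demonstrate that the detectors,
statistics and renderers implement their definitions exactly — not that
any particular tracker's output is error-free.

## Problem sizes and numerical choices

The test and acceptance workloads use movies of 3–20 initial objects over
8–30 frames, random DAGs of ≤ 200 nodes for oracle comparisons, and a
{0,2,4}³ artifact grid × 20 seeds for exact-recovery checks — sizes at
which the brute-force oracles (exhaustive path enumeration, flood fill)
remain tractable while covering all interacting code paths. Means are exact
to 1e−12 against a naive loop; percentile and normalization checks are
exact by construction. Byte-level stability of SQLite round-trips holds
because writes go through a single deterministic code path into a fresh
file.

## Known limitations

* Loop detection is quadratic in (splits × merges) with a max-flow call per
  pair — fine for QC-scale movies (thousands of nodes), not tuned for
  millions.
* The image-index key is assumed globally unique; exporters that number
  images per site would need a composite (group, image) key variant.
* Only 2-D centroids are supported (a 2-D projection of 3-D data works);
  no manual track editing; no automatic correction beyond singleton
  pruning.
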