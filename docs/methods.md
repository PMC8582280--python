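# Methods

## Scene model

A scene is the minimal content a VR viewer needs: per-cell 3-D positions,
annotation tracks, feature tracks, an optional trajectory graph and an
optional velocity layer, plus a manifest indexing all of it. Scene units
are dimensionless; physical sizing (how large the point cloud appears in a
headset) is the viewer's concern.

**Normalization.** Coordinates are centered on their arithmetic centroid
and divided by the maximum Euclidean norm after centering, so every cell
lies in the closed unit ball and (non-degenerately) at least one cell lies
on the unit sphere. The transform `{centroid, scale}` is stored in the
manifest, making the mapping invertible: `original = scene · scale +
centroid`. The normalization is deliberately isotropic (unit ball, not unit
cube): per-axis scaling would distort the relative distances the embedding
encodes. A single cell, or coincident cells, normalize to the origin with
scale 1. 2-D embeddings are lifted into the z = 0 plane before
normalization and flagged `source_dims = 2`.

**Angles.** Camera poses carry yaw (about the vertical axis), pitch (about
the lateral axis) and roll (about the view axis), applied yaw → pitch →
roll, each canonically wrapped into (−180°, 180°]. This rotation-order
convention is this package's own documented choice; the angle names alone
do not determine it.

**Edge widths.** Trajectory edges render with width `0.1 + 0.9·w` for
connectivity weight `w ∈ [0, 1]` — strictly increasing in `w`, bounded by
1.0 scene units, with a 0.1 floor so retained low-confidence edges remain
visible.

**Validation.** `validate_scene` checks every invariant (uniqueness,
counts, finiteness, unit-ball containment, range bracketing, graph
topology, polyline–node coincidence, width monotonicity, manifest
consistency) and reports violations as entries rather than raising, so a
single pass enumerates all problems. Two numerical tolerances exist
because packaged floats are stored at 6 significant digits: unit-ball
containment allows 1e−5 slack (a point exactly on the sphere may round
outward by ~3e−8), and edge weights closer than 1e−6 are treated as ties
in the width-monotonicity check (distinct weights can collapse to one
stored value). Values held in memory are produced exactly; the slack only
admits storage quantization.

## Ingest

`.h5ad` containers are read with anndata. Embeddings are taken from
`obsm` (the conventional `X_` prefix is stripped), embedded velocity from
`obsm["velocity_<embedding>"]`, and cluster-level connectivities from the
standard partition-based graph-abstraction slot in `uns`, whose `groups`
entry names the grouping column. Loom files are read directly with h5py
(the loom layout is plain HDF5: `matrix` genes × cells, `col_attrs` per
cell, `row_attrs` per gene, `layers`); 2-D column attributes become
embeddings, 1-D ones become per-cell columns.

Tool-native R (`.rds`) and pickle (`.pkl`) serializations are deliberately
not parsed — deserializing arbitrary foreign objects is unsafe and
version-fragile. The delimited-text bundle (coordinates TSV + annotation
TSV + feature TSV + JSON graph sidecar) is the neutral exchange path those
ecosystems can emit with a few lines of export code. Joins between the
tables are strict: any unmatched or duplicate cell id is an error naming
the id, because silent row dropping would corrupt per-cell alignment.

Embeddings with more than 3 columns are truncated to their first three
components rather than re-reduced: the leading components of an ordered
reduction are the conventional choice, and recomputing a 3-D reduction
would silently change published coordinates.

Principal curves are resampled to `k_samples` points (default 30) uniform
in cumulative arc length, by linear interpolation along the input
polyline; consecutive duplicate points are dropped first and a curve that
collapses to a single point is an error. 30 points keeps a branch smooth
at VR scale while bounding polyline payloads. Abstract-graph edges below
`weight_floor = 0.05` are dropped as visual noise (configurable).

Velocity vectors are displacements per unit latent time, so the
normalization translation does not apply to them; they are divided by the
isotropic scale only, and 2-D vectors are lifted with a zero third
component. A dataset without embedded velocity raises a typed signal and
the scene is simply built without the layer. Projecting high-dimensional
velocity into an embedding is out of scope — precomputed embedded vectors
are required.

## Downsampling

Disabled by default (`max_cells = None`): silently dropping cells would
misrepresent an experiment, and the package format comfortably holds 10⁵
cells. When enabled, sampling is uniform without replacement; with a
stratification key, per-category quotas are proportional with
largest-remainder rounding (computed in exact integer arithmetic) and a
minimum of one cell per nonempty category, the deficit taken from the
largest quota. The selection is a pure function of `(n, max_cells, seed,
labels)`.

## Colors

Categorical tracks use a fixed 20-color palette cycled in lexicographic
label order, so the label→color map depends only on the label set.
Continuous tracks store raw values plus their range; display positions
`u ∈ [0, 1]` come from min/max scaling, or percentile clipping
`clamp((v − q_lo)/(q_hi − q_lo), 0, 1)` when configured. Clipping defaults
to off — pseudotime and score tracks must keep their true endpoints — and
`[1, 99]` is the suggested setting for long-tailed expression features.
Constant tracks map to u = 0 with a "degenerate range" warning. The
continuous colormap is a literal 9-anchor control-point table
(dark-violet → teal → yellow, linear RGB between anchors) so packaged hex
colors are identical across platforms with no plotting-library dependency.

## Velocity visualization

Two modes, matching how viewers display small and large datasets: per-cell
arrows with tip = x + t·v, and a lattice field for crowded scenes. The
lattice estimator is a Gaussian-kernel weighted mean (Nadaraya–Watson):
on an r×r×r lattice (default r = 8) over the positions' bounding box
expanded by 5% per side, each lattice point g gets weights
wᵢ = exp(−‖xᵢ−g‖²/2σ²), mass m(g) = Σwᵢ and field V(g) = Σwᵢvᵢ/m(g).
σ defaults to the mean lattice spacing — smoothing then adapts to the
chosen resolution — and is tunable. Lattice points with mass below 1% of
the maximum are discarded so arrows never float in empty space. Because
weights are nonnegative and normalized, every V(g) lies in the convex hull
of the cell vectors, and the estimator is exactly linear: for v = A·x the
field satisfies V(g) = A·m̄(g) with m̄ the weighted mean position (used as
an exact test oracle). The grid is computed on normalized coordinates so
the defaults are dataset-independent.

Animation is linear in the latent-time scale t: packaged scenes store raw
vectors and `t_default`, never pre-baked frames, so a viewer can rescale
displacement on the fly. Whether a viewer should instead re-integrate a
path is its own choice; linear displacement is this package's documented
semantics. A preview scale (longest grid arrow = half the lattice spacing)
is provided as metadata only.

**Statistical behaviour of the angular-recovery check.** On a synthetic
rotational field (n cells uniform in a ball, v = (−y, x, 0)), the lattice
columns nearest the rotation axis sit at ‖g_xy‖ ≈ 0.5σ, where the angular
sampling noise of the kernel-weighted mean position is ≈ 8° at n = 1000.
A hard 10° bound on the maximum angle over all lattice points with mass ≥
10% of the maximum is therefore exceeded for roughly half of random
samples at n = 1000 — not due to estimator error (the estimator matches a
brute-force oracle to 1e−12) but to sampling noise; varying σ between
0.3× and 2× the spacing does not change this, because widening the kernel
shrinks the tangential signal faster than the noise. At n = 5000 the same
bound holds with ~2° margin across seeds. The unit suite asserts the bound
in that stable regime; the acceptance measurement also reports the
n = 1000 value.

## Scene package format

`name.zip` → `index.json`, `scatter.json`,
`annotations/<key>.json`, `features/<id>.json`, optional `graph.json`,
optional `velocity.json`. One JSON member per feature lets a viewer fetch
features lazily. Serialization is canonical: sorted keys, no insignificant
whitespace, floats at 6 significant digits (sub-pixel at VR scale, ~2.5×
smaller packages than full precision), fixed member order, fixed zip
timestamps and attributes. Canonical form makes byte identity meaningful:
identical scenes ⇒ identical archives, and write → read → write is a
byte-level fixed point (6-digit formatting is idempotent under reparse).
Track keys are percent-encoded in member names so arbitrary annotation
keys remain zip-safe. `format_version` is `"1.0"`; readers reject other
major versions. Reading distinguishes three failure kinds — missing
member, JSON parse failure, manifest/member inconsistency — and
`validate_package` converts all of them plus every scene-level invariant
into report entries, checking feature members one at a time so memory does
not scale with feature count.

## Handoff service

Dataset ids are the first 12 hex characters of the SHA-256 of the package
bytes: re-uploading identical bytes is a no-op, and the registry state is
a pure function of the multiset of valid uploads (listing ordered by name
then id). Packages failing validation are rejected with the report
attached. The server is a small stdlib HTTP service (`/datasets`,
`/data/<id>/<member>`, `/qr/<id>.png`, `POST /upload`) intended as a local
tool: no authentication, packages on local disk, 200 MB default upload
cap.

QR codes are generated by an in-package encoder (byte mode, versions 1–10,
error-correction level M, Reed–Solomon over GF(256), standard mask
selection by penalty scoring) — up to 213 payload bytes, ample for a
handoff URL with a viewpoint query. The test oracle is a separately
written structural decoder that re-derives the format information via its
BCH check, verifies every Reed–Solomon syndrome is zero, and parses the
bit stream; encoder and decoder share only published constants of the
symbology. Viewpoints serialize as `"x,y,z|yaw,pitch,roll"` with two
fixed-point decimals (round trip within half a quantum, 0.005), wrapped
into (−180°, 180°] before encoding, and travel URL-encoded in a `vp=`
query parameter so one QR code carries both dataset and pose.

## Synthetic data

The generators emulate the three analysis shapes the converter ingests,
with ground truth returned alongside the data so tests never re-infer it:

* **Clusters** — unit-variance isotropic Gaussian blobs around centroids
  placed pairwise ≥ `separation` apart (default 8, i.e. 8σ — visually
  distinct, nearest-centroid recoverable), balanced labels, a continuous
  per-cell score, 5 features with cluster-specific means in [1, 10] and
  0.5σ noise, and a fully connected connectivity matrix decaying
  exponentially with centroid distance.
* **Branching trajectory** — a Y-shaped principal graph (straight root →
  fork segment, two quadratic-Bezier branches), cells uniform in arc
  length with 0.05 isotropic jitter (≈ 2.5% of the structure's extent),
  arc-length pseudotime, branch labels, and pseudotime-driven features.
* **Velocity** — cells uniform in a ball of radius 5, with a linear
  (v = A·x) or rotational (v = (−y, x, 0)) embedded field.

Defaults are small (300–1000 cells) so the full suite runs in seconds;
the scale smoke test generates 100,000 cells. Every generator is a pure
function of its arguments including the seed, and all three write legal
h5ad, loom and TSV bundles (loom datasets are created with HDF5 timestamp
tracking disabled so identical inputs give byte-identical files). What
these fixtures do **not** emulate: realistic count distributions
(overdispersion, zero inflation, library-size effects), doublets, batch
structure, or the curved manifolds of real embeddings — so passing tests
demonstrate the correctness of conversion, serialization and estimation
arithmetic, not robustness to messy biology upstream of the converter.

## Problem sizes and tolerances

The acceptance measurements use 300–1000-cell fixtures (100,000 for the
scale run), 20 random grid-oracle instances (n ≤ 500, r ≤ 8, agreement to
1e−12 — the float64 accumulation bound at these sizes), 100 random quota
splits checked against an exact-fraction oracle, 50 QR codes against the
structural decoder, and the rotational-field angle at n = 1000 as
discussed above. Centroid agreement is asserted to 1e−9, arc-length
resampling to 1e−6 against a dense interpolation table, viewpoint round
trips to 0.005 per component, and semantic package equality at the
6-significant-digit storage precision.

## Known limitations

* No native `.rds`/`.pkl` parsing (by design; use the TSV bundle).
* Velocity must already be projected into the embedding.
* The loom path carries no trajectory graph (the format has no standard
  slot for one); convert via h5ad or TSV+sidecar to keep graphs.
* Scene downsampling after a graph has been built keeps the graph of the
  full dataset; downsample the raw dataset (as `build_scene` does) when
  centroid/cell consistency matters.
* The in-browser VR rendering itself is out of scope; this package
  produces and serves the scene format.
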