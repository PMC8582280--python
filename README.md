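# cellvr

Convert processed single-cell analysis results into a compact, validated,
zipped-JSON **VR scene package**, and hand the visualization off to a phone
via a QR code.

Single-cell experiments (scRNA-seq, scATAC-seq, single-cell proteomics) are
routinely summarized as a low-dimensional embedding — UMAP, t-SNE, PCA —
with per-cell annotations (cluster labels, pseudotime, FACS gates), per-cell
feature quantifications (gene expression, TF-motif deviation), trajectory
graphs and RNA-velocity vector fields. Those results live inside analysis
containers (`.h5ad`, `.loom`) that a browser-based VR viewer cannot consume
directly. `cellvr` is the conversion and serving side of that workflow, for
bench scientists and computational biologists who want to explore published
or in-house analyses in inexpensive phone-based VR:

* **ingest** — read `.h5ad` (via anndata), `.loom` (HDF5 column/row
  attributes, read directly with h5py), or a neutral delimited-text bundle
  (coordinates/annotations/features TSVs plus a JSON graph sidecar) for
  results exported from R or pickle-based ecosystems.
* **scene build** — lift 2-D embeddings into the z = 0 plane, optionally
  downsample with proportional stratified quotas, and normalize all
  coordinates into the closed unit ball: centered on the centroid **c** and
  divided by the isotropic scale *s* = max‖xᵢ − **c**‖, recorded in the
  manifest so original coordinates are recoverable.
* **trajectory graphs** — cluster-level abstract graphs (one node per cell
  group at its centroid, edge width 0.1 + 0.9·w linear in the connectivity
  weight w) and principal-curve graphs (each branch resampled to k points
  uniform in cumulative arc length).
* **velocity** — per-cell arrows (tip = x + t·v, latent-time scale t) and a
  Nadaraya–Watson grid field on an r×r×r lattice: wᵢ(g) = exp(−‖xᵢ−g‖²/2σ²),
  mass m(g) = Σwᵢ, field V(g) = Σwᵢvᵢ / m(g), retaining lattice points with
  m(g) ≥ 1% of the maximum so no arrows float in empty space.
* **scene package** — canonical zipped JSON (sorted keys, 6-significant-digit
  floats, fixed member order and timestamps): identical scenes give
  byte-identical archives, and a full validator checks every invariant.
* **handoff** — a local HTTP service with a content-addressed package
  registry, QR codes (generated by an in-package byte-mode QR encoder)
  carrying `base_url/view/<id>` URLs, and shareable camera viewpoints
  `"x,y,z|yaw,pitch,roll"` at fixed-point precision.

## Worked example

```sh
$ cellvr demo --out-dir demo_packages --seed 1
wrote demo_packages/clusters.zip
wrote demo_packages/trajectory.zip
wrote demo_packages/velocity.zip

$ cellvr validate demo_packages/clusters.zip
package is valid
```

`clusters.zip` holds a 300-cell, 3-cluster synthetic experiment:
`index.json` (the manifest), `scatter.json` (300 cell positions inside the
unit ball), `annotations/cluster.json` and `annotations/score.json`,
`features/gene{0,1,2}.json`, and `graph.json` (the 3-node abstract graph
with connectivity-scaled edge widths). Converting your own analysis works
the same way:

```sh
cellvr convert analysis.h5ad --embedding umap \
    --annotations leiden,pseudotime --features Gad1,Klf1 \
    -o scene.zip
cellvr serve --root my_packages --port 8000
```

`GET /datasets` lists registered packages, `GET /qr/<id>.png` returns a QR
code that opens `…/view/<id>` on a phone, and a `vp=` query parameter
carries a camera pose, e.g. `0.00,1.60,3.00|0.00,-15.00,0.00` (position in
scene units, then yaw/pitch/roll in degrees).

Library use mirrors the CLI:

```python
from cellvr import read_annotated_matrix, BuildConfig, build_scene
from cellvr import write_scene_package

raw = read_annotated_matrix("analysis.h5ad")
scene = build_scene(raw, BuildConfig(embedding_name="umap",
                                     annotation_keys=["leiden"],
                                     feature_ids=["Gad1"]))
write_scene_package(scene, "scene.zip")
```

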