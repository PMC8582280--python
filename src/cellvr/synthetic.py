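"""Synthetic single-cell fixtures with known ground truth.

Three generators emulate the analysis outputs the converter ingests:

* ``make_cluster_dataset`` — isotropic Gaussian blobs around well-separated
  centroids with a cluster label, a continuous score, cluster-specific
  marker features, and a cluster-level connectivity matrix (abstract-graph
  input).
* ``make_branching_trajectory`` — a Y-shaped principal graph (root -> fork,
  fork -> two tips) with cells jittered around the curves, an arc-length
  pseudotime and a branch label.
* ``make_velocity_dataset`` — cells uniform in a ball carrying an embedded
  velocity field, either linear (v = A c) or rotational (tangent to circles
  about the z axis).

Every generator is a pure function of its arguments (seed included) and
returns ``(RawDataset, truth)`` where ``truth`` holds the generating
parameters so tests never re-infer them.  Writers emit each dataset as
h5ad, loom, or a delimited-text bundle, all of which round-trip through
:mod:`cellvr.ingest`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import Curve, RawDataset, resample_polyline

# ---------------------------------------------------------------------------
# generators


def _separated_centroids(k: int, separation: float,
                         rng: np.random.Generator) -> np.ndarray:
    """k points in 3-space, pairwise at least ``separation`` apart."""
    box = separation * (k ** (1 / 3) + 1.0)
    centroids: list[np.ndarray] = []
    for _ in range(10000):
        cand = rng.uniform(-box, box, size=3)
        if all(np.linalg.norm(cand - c) >= separation for c in centroids):
            centroids.append(cand)
            if len(centroids) == k:
                return np.asarray(centroids)
    raise RuntimeError("could not place separated centroids")


def make_cluster_dataset(n_cells: int = 300, n_clusters: int = 3,
                         separation: float = 8.0, seed: int = 0,
                         n_features: int = 5,
                         ) -> tuple[RawDataset, dict]:
    """Clustered embedding with labels, score, markers and connectivities.

    Cells are unit-variance isotropic Gaussian blobs; labels are balanced
    (remainder cells go to the earliest clusters).  Cluster-level
    connectivity decays exponentially with centroid distance, giving a
    fully connected abstract graph with informative weights.
    """
    rng = np.random.default_rng(seed)
    centroids = _separated_centroids(n_clusters, separation, rng)
    counts = [n_cells // n_clusters + (1 if i < n_cells % n_clusters else 0)
              for i in range(n_clusters)]
    labels = np.repeat(np.arange(n_clusters), counts)
    positions = centroids[labels] + rng.standard_normal((n_cells, 3))

    group_names = [f"c{i}" for i in range(n_clusters)]
    score = np.linalg.norm(positions - centroids[labels], axis=1)

    marker_means = rng.uniform(1.0, 10.0, size=(n_clusters, n_features))
    X = marker_means[labels] + 0.5 * rng.standard_normal(
        (n_cells, n_features))

    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    conn = np.exp(-dist / (2.0 * separation))
    np.fill_diagonal(conn, 0.0)

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    obs = pd.DataFrame({
        "cluster": pd.Categorical([group_names[c] for c in labels],
                                  categories=group_names),
        "score": score,
    }, index=pd.Index(cell_ids))
    raw = RawDataset(
        cell_ids=cell_ids,
        embeddings={"umap": positions},
        obs=obs,
        var_names=[f"gene{g}" for g in range(n_features)],
        matrix_layers={"X": X},
        cluster_key="cluster",
        connectivity_groups=group_names,
        abstract_connectivities=conn,
    )
    truth = {"centroids": centroids, "labels": labels,
             "group_names": group_names, "marker_means": marker_means,
             "connectivities": conn}
    return raw, truth


def _bend(p0, p1, p2, n: int) -> np.ndarray:
    """Quadratic Bezier polyline through control points p0, p1, p2."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2


def make_branching_trajectory(n_cells: int = 300, seed: int = 0,
                              jitter: float = 0.05,
                              ) -> tuple[RawDataset, dict]:
    """Y-shaped trajectory: root -> fork, then two diverging branches.

    Cells are placed uniformly by arc length along the three generating
    curves (allocation proportional to curve length) with isotropic
    Gaussian jitter.  ``pseudotime`` is the arc-length position measured
    from the root; ``branch`` is the generating curve.
    """
    rng = np.random.default_rng(seed)
    root = np.array([0.0, 0.0, 0.0])
    fork = np.array([1.0, 0.0, 0.0])
    curves = {
        "root-fork": np.linspace(root, fork, 40),
        "fork-tipA": _bend(fork, [1.6, 0.5, 0.15], [2.0, 1.0, 0.3], 40),
        "fork-tipB": _bend(fork, [1.6, -0.5, -0.15], [2.0, -1.0, -0.3], 40),
    }
    endpoints = {"root-fork": ("root", "fork"),
                 "fork-tipA": ("fork", "tipA"),
                 "fork-tipB": ("fork", "tipB")}
    lengths = {k: float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())
               for k, v in curves.items()}
    total = sum(lengths.values())
    alloc = {k: int(round(n_cells * lengths[k] / total)) for k in curves}
    drift = n_cells - sum(alloc.values())
    alloc["root-fork"] += drift

    rows, branch, pseudotime = [], [], []
    offset = {"root-fork": 0.0, "fork-tipA": lengths["root-fork"],
              "fork-tipB": lengths["root-fork"]}
    for name, poly in curves.items():
        k = alloc[name]
        s = np.sort(rng.uniform(0.0, lengths[name], size=k))
        dense = resample_polyline(poly, 512)
        ts = np.linspace(0.0, lengths[name], 512)
        pts = np.column_stack([np.interp(s, ts, dense[:, d])
                               for d in range(3)])
        rows.append(pts + jitter * rng.standard_normal((k, 3)))
        branch += [name] * k
        pseudotime.append(offset[name] + s)
    positions = np.vstack(rows)
    pseudotime = np.concatenate(pseudotime)

    # smooth pseudotime-driven markers plus one branch-specific gene
    is_a = (np.asarray(branch) == "fork-tipA").astype(float)
    X = np.column_stack([
        pseudotime,
        pseudotime.max() - pseudotime,
        is_a * pseudotime,
    ]) + 0.1 * rng.standard_normal((n_cells, 3))

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    obs = pd.DataFrame({
        "branch": pd.Categorical(branch, categories=list(curves)),
        "pseudotime": pseudotime,
    }, index=pd.Index(cell_ids))
    raw = RawDataset(
        cell_ids=cell_ids,
        embeddings={"umap": positions},
        obs=obs,
        var_names=["geneUp", "geneDown", "geneBranchA"],
        matrix_layers={"X": X},
        curve_set=[Curve(curve_id=k, from_node=endpoints[k][0],
                         to_node=endpoints[k][1], points=curves[k])
                   for k in curves],
    )
    truth = {"curves": curves, "endpoints": endpoints, "jitter": jitter,
             "lengths": lengths}
    return raw, truth


def make_velocity_dataset(n_cells: int = 500, field: str = "rotational",
                          seed: int = 0, A: np.ndarray | None = None,
                          radius: float = 5.0,
                          ) -> tuple[RawDataset, dict]:
    """Cells uniform in a ball with an embedded velocity field.

    ``field="linear"``: v = A c (A defaults to the identity);
    ``field="rotational"``: v = (-y, x, 0), tangent to circles about the
    z axis.
    """
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal((n_cells, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = radius * rng.uniform(0.0, 1.0, size=n_cells) ** (1.0 / 3.0)
    positions = direction * r[:, None]

    if field == "linear":
        A = np.eye(3) if A is None else np.asarray(A, dtype=float)
        vectors = positions @ A.T
    elif field == "rotational":
        vectors = np.column_stack([-positions[:, 1], positions[:, 0],
                                   np.zeros(n_cells)])
    else:
        raise ValueError(f"unknown field kind {field!r}")

    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    obs = pd.DataFrame({
        "hemisphere": pd.Categorical(
            np.where(positions[:, 2] >= 0, "upper", "lower"),
            categories=["lower", "upper"]),
        "speed": np.linalg.norm(vectors, axis=1),
    }, index=pd.Index(cell_ids))
    X = np.abs(rng.standard_normal((n_cells, 3)))
    raw = RawDataset(
        cell_ids=cell_ids,
        embeddings={"umap": positions},
        obs=obs,
        var_names=["geneA", "geneB", "geneC"],
        matrix_layers={"X": X},
        velocity_embedding=vectors,
        velocity_basis="umap",
    )
    truth = {"field": field, "A": A, "radius": radius}
    return raw, truth


# ---------------------------------------------------------------------------
# writers


def write_h5ad(raw: RawDataset, path) -> Path:
    """Write a RawDataset as an annotated-matrix (.h5ad) container."""
    import anndata

    n = raw.n_cells
    X = raw.matrix_layers.get("X")
    if X is None:
        X = np.zeros((n, 0))
    adata = anndata.AnnData(
        X=np.asarray(X, dtype=np.float64),
        obs=raw.obs.copy(),
    )
    adata.obs_names = list(raw.cell_ids)
    if raw.var_names:
        adata.var_names = list(raw.var_names)
    for name, emb in raw.embeddings.items():
        adata.obsm[f"X_{name}"] = np.asarray(emb, dtype=np.float64)
    if raw.velocity_embedding is not None:
        adata.obsm[f"velocity_{raw.velocity_basis}"] = np.asarray(
            raw.velocity_embedding, dtype=np.float64)
    if raw.abstract_connectivities is not None:
        adata.uns["paga"] = {
            "connectivities": np.asarray(raw.abstract_connectivities,
                                         dtype=np.float64),
            "groups": raw.cluster_key,
        }
    path = Path(path)
    adata.write_h5ad(path)
    return path


def write_loom(raw: RawDataset, path) -> Path:
    """Write a RawDataset as a loom file (matrix genes x cells).

    All HDF5 objects are created with ``track_times=False`` so identical
    inputs produce byte-identical files.  Cluster-level connectivities and
    principal curves have no loom slot and are not written.
    """
    import h5py

    n = raw.n_cells
    X = raw.matrix_layers.get("X")
    if X is None:
        X = np.zeros((n, 0))
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["LOOM_SPEC_VERSION"] = "3.0.0"
        f.create_dataset("matrix", data=np.asarray(X, dtype=np.float64).T,
                         track_times=False)
        ra = f.create_group("row_attrs")
        ra.create_dataset(
            "Gene", data=np.asarray(raw.var_names, dtype="S"),
            track_times=False)
        ca = f.create_group("col_attrs")
        ca.create_dataset(
            "CellID", data=np.asarray(raw.cell_ids, dtype="S"),
            track_times=False)
        for col in raw.obs.columns:
            series = raw.obs[col]
            if series.dtype.kind in ("O", "U", "S") or str(
                    series.dtype) == "category":
                data = np.asarray(series.astype(str), dtype="S")
            else:
                data = series.to_numpy()
            ca.create_dataset(col, data=data, track_times=False)
        for name, emb in raw.embeddings.items():
            ca.create_dataset(name, data=np.asarray(emb, dtype=np.float64),
                              track_times=False)
        if raw.velocity_embedding is not None:
            ca.create_dataset(
                f"velocity_{raw.velocity_basis}",
                data=np.asarray(raw.velocity_embedding, dtype=np.float64),
                track_times=False)
        f.create_group("layers")
        f.create_group("attrs")
    return path


def write_tsv_bundle(raw: RawDataset, out_dir,
                     embedding_name: str = "umap") -> dict[str, Path]:
    """Write the delimited-text exchange bundle.

    Emits ``coords.tsv``, ``annotations.tsv``, ``features.tsv`` and, when
    the dataset carries a graph, ``graph.json``.  Embedded velocity has no
    slot in this exchange format.
    """
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    emb = np.asarray(raw.embeddings[embedding_name], dtype=float)
    cols = ["x", "y", "z"][: emb.shape[1]]
    coords = pd.DataFrame(emb, columns=cols,
                          index=pd.Index(raw.cell_ids, name="cell_id"))
    paths["coords"] = out_dir / "coords.tsv"
    coords.to_csv(paths["coords"], sep="\t", float_format="%.10g")

    if len(raw.obs.columns):
        obs = raw.obs.copy()
        obs.index.name = "cell_id"
        paths["annotations"] = out_dir / "annotations.tsv"
        obs.to_csv(paths["annotations"], sep="\t", float_format="%.10g")

    if "X" in raw.matrix_layers and raw.var_names:
        feats = pd.DataFrame(raw.matrix_layers["X"],
                             columns=raw.var_names,
                             index=pd.Index(raw.cell_ids, name="cell_id"))
        paths["features"] = out_dir / "features.tsv"
        feats.to_csv(paths["features"], sep="\t", float_format="%.10g")

    sidecar = None
    if raw.curve_set:
        sidecar = {"kind": "principal_curve",
                   "curves": [{"id": cv.curve_id, "from": cv.from_node,
                               "to": cv.to_node,
                               "points": np.asarray(cv.points,
                                                    dtype=float).tolist()}
                              for cv in raw.curve_set]}
    elif raw.abstract_connectivities is not None:
        sidecar = {"kind": "abstract",
                   "groups": list(raw.connectivity_groups),
                   "cluster_key": raw.cluster_key,
                   "connectivities": np.asarray(
                       raw.abstract_connectivities, dtype=float).tolist()}
    if sidecar is not None:
        paths["graph"] = out_dir / "graph.json"
        with open(paths["graph"], "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, sort_keys=True, indent=None,
                      separators=(",", ":"))
    return paths
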