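"""Readers for single-cell analysis outputs.

Three ingest paths produce the same neutral :class:`RawDataset`:

* ``read_annotated_matrix`` — HDF5 annotated-matrix containers (``.h5ad``)
  as written by scanpy/episcanpy/scvelo, via :mod:`anndata`.  Embeddings are
  found in ``obsm`` under ``X_``-prefixed keys (prefix stripped), embedded
  velocity under ``velocity_<embedding>``, and cluster-level connectivities
  in the standard partition-based graph-abstraction result slot in ``uns``.
* ``read_loom`` — loom files (HDF5 dialect: matrix genes x cells, per-cell
  column attributes, per-gene row attributes, extra matrix layers), read
  directly with :mod:`h5py`.  Two-dimensional column attributes are exposed
  as embeddings; one-dimensional ones as per-cell columns.
* ``read_delimited`` — a neutral text exchange path (coordinates TSV plus
  optional annotation/feature TSVs and a JSON graph sidecar) standing in
  for tool-native serializations that are unsafe to deserialize across
  ecosystems (R ``.rds``, Python ``.pkl``).

Extraction helpers then pull out one embedding, the cluster-level abstract
graph, principal curves resampled by arc length, and embedded velocity
vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import IngestError, NoVelocityError, StructuralError
from .scene_model import GraphEdge, GraphNode, TrajectoryGraph, edge_width

DEFAULT_WEIGHT_FLOOR = 0.05
DEFAULT_K_SAMPLES = 30


@dataclass
class Curve:
    """One principal-graph branch: an ordered polyline with named endpoints."""

    curve_id: str
    from_node: str
    to_node: str
    points: np.ndarray  # (k >= 2, 2 or 3)


@dataclass
class RawDataset:
    """Neutral container for everything a scene can be built from."""

    cell_ids: list[str]
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    obs: pd.DataFrame = None  # per-cell columns, indexed like cell_ids
    var_names: list[str] = field(default_factory=list)
    matrix_layers: dict[str, np.ndarray] = field(default_factory=dict)
    cluster_key: Optional[str] = None
    connectivity_groups: Optional[list[str]] = None
    abstract_connectivities: Optional[np.ndarray] = None
    curve_set: Optional[list[Curve]] = None
    velocity_embedding: Optional[np.ndarray] = None
    velocity_basis: Optional[str] = None

    def __post_init__(self) -> None:
        if self.obs is None:
            self.obs = pd.DataFrame(index=pd.Index(self.cell_ids))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def check(self) -> None:
        """Raise :class:`StructuralError` on any cross-structure mismatch."""
        n = self.n_cells
        if len(set(self.cell_ids)) != n:
            raise StructuralError("duplicate cell ids")
        for name, emb in self.embeddings.items():
            if emb.shape[0] != n:
                raise StructuralError(
                    f"embedding {name!r} has {emb.shape[0]} rows for {n} cells")
        if len(self.obs) != n:
            raise StructuralError(
                f"obs table has {len(self.obs)} rows for {n} cells")
        for name, mat in self.matrix_layers.items():
            if mat.shape != (n, len(self.var_names)):
                raise StructuralError(
                    f"layer {name!r} shape {mat.shape} does not match "
                    f"({n}, {len(self.var_names)})")
        c = self.abstract_connectivities
        if c is not None:
            c = np.asarray(c, dtype=float)
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise StructuralError("connectivity matrix must be square")
            if not np.allclose(c, c.T) or np.abs(np.diag(c)).max(initial=0) > 0:
                raise StructuralError(
                    "connectivity matrix must be symmetric with zero diagonal")
        for cv in self.curve_set or []:
            if np.asarray(cv.points).shape[0] < 2:
                raise StructuralError(
                    f"curve {cv.curve_id!r} needs >= 2 sample points")
        if self.velocity_embedding is not None:
            if self.velocity_embedding.shape[0] != n:
                raise StructuralError("velocity rows do not match cell count")


# ---------------------------------------------------------------------------
# readers

def _densify(x) -> np.ndarray:
    if hasattr(x, "toarray"):
        x = x.toarray()
    return np.asarray(x)


def read_annotated_matrix(path) -> RawDataset:
    """Read an ``.h5ad`` annotated-matrix container into a RawDataset."""
    import anndata

    path = Path(path)
    if not path.is_file():
        raise IngestError(f"no such file: {path}")
    try:
        adata = anndata.read_h5ad(path)
    except OSError as exc:
        raise IngestError(f"cannot read {path}: {exc}") from exc

    embeddings: dict[str, np.ndarray] = {}
    velocity: Optional[np.ndarray] = None
    velocity_basis: Optional[str] = None
    for key in list(adata.obsm.keys()):
        arr = np.asarray(adata.obsm[key], dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            continue
        if key.startswith("velocity_"):
            velocity = arr
            velocity_basis = key[len("velocity_"):]
        else:
            name = key[2:] if key.startswith("X_") else key
            embeddings[name] = arr
    if adata.n_obs > 0 and not embeddings:
        raise StructuralError(
            f"{path} has no multi-dimensional embedding; "
            f"obsm keys: {sorted(adata.obsm.keys())}")

    layers = {"X": _densify(adata.X)} if adata.X is not None else {}
    for name in adata.layers.keys():
        layers[name] = _densify(adata.layers[name])

    cluster_key = None
    groups = None
    conn = None
    paga = adata.uns.get("paga")
    if paga is not None and "connectivities" in paga:
        conn = _densify(paga["connectivities"]).astype(float)
        np.fill_diagonal(conn, 0.0)
        conn = np.maximum(conn, conn.T)  # stored triangular by some tools
        cluster_key = str(paga.get("groups", "")) or None
        if cluster_key and cluster_key in adata.obs:
            col = adata.obs[cluster_key]
            if hasattr(col, "cat"):
                groups = [str(g) for g in col.cat.categories]
            else:
                groups = sorted(str(g) for g in pd.unique(col))

    raw = RawDataset(
        cell_ids=[str(i) for i in adata.obs_names],
        embeddings=embeddings,
        obs=adata.obs.copy(),
        var_names=[str(v) for v in adata.var_names],
        matrix_layers=layers,
        cluster_key=cluster_key,
        connectivity_groups=groups,
        abstract_connectivities=conn,
        velocity_embedding=velocity,
        velocity_basis=velocity_basis,
    )
    raw.check()
    return raw


def read_loom(path) -> RawDataset:
    """Read a loom file (matrix genes x cells) into a RawDataset."""
    import h5py

    path = Path(path)
    if not path.is_file():
        raise IngestError(f"no such file: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise IngestError(f"cannot read {path}: {exc}") from exc

    with f:
        if "matrix" not in f or "col_attrs" not in f:
            raise StructuralError(f"{path} is not a loom file")
        matrix = np.asarray(f["matrix"])  # genes x cells
        n = matrix.shape[1]

        def _decode(a: np.ndarray):
            if a.dtype.kind in ("S", "O"):
                return np.asarray([v.decode() if isinstance(v, bytes) else str(v)
                                   for v in a])
            return a

        col_attrs = {k: np.asarray(v) for k, v in f["col_attrs"].items()}
        for k, v in col_attrs.items():
            if v.shape[0] != n:
                raise StructuralError(
                    f"column attribute {k!r} has {v.shape[0]} rows "
                    f"for {n} cells")
        if "CellID" in col_attrs:
            cell_ids = [str(c) for c in _decode(col_attrs.pop("CellID"))]
        else:
            cell_ids = [f"cell{i}" for i in range(n)]

        embeddings: dict[str, np.ndarray] = {}
        velocity = None
        velocity_basis = None
        obs_cols: dict[str, np.ndarray] = {}
        for k, v in col_attrs.items():
            if v.ndim == 2 and v.shape[1] >= 2:
                arr = v.astype(float)
                if k.startswith("velocity_"):
                    velocity = arr
                    velocity_basis = k[len("velocity_"):]
                else:
                    embeddings[k[2:] if k.startswith("X_") else k] = arr
            elif v.ndim == 1:
                obs_cols[k] = _decode(v)
        if n > 0 and not embeddings:
            raise StructuralError(
                f"{path} has no multi-column embedding attribute; "
                f"column attributes: {sorted(col_attrs)}")

        var_names = [f"gene{i}" for i in range(matrix.shape[0])]
        if "row_attrs" in f and "Gene" in f["row_attrs"]:
            gnames = _decode(np.asarray(f["row_attrs"]["Gene"]))
            if len(gnames) != matrix.shape[0]:
                raise StructuralError("row attribute 'Gene' length mismatch")
            var_names = [str(g) for g in gnames]

        layers = {"X": matrix.T.astype(float)}
        if "layers" in f:
            for k, v in f["layers"].items():
                lay = np.asarray(v)
                if lay.shape != matrix.shape:
                    raise StructuralError(f"layer {k!r} shape mismatch")
                layers[k] = lay.T.astype(float)

    obs = pd.DataFrame(obs_cols, index=pd.Index(cell_ids))
    raw = RawDataset(
        cell_ids=cell_ids,
        embeddings=embeddings,
        obs=obs,
        var_names=var_names,
        matrix_layers=layers,
        velocity_embedding=velocity,
        velocity_basis=velocity_basis,
    )
    raw.check()
    return raw


def _read_tsv(path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.is_file():
        raise IngestError(f"no such {what} file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise StructuralError(f"{what} table {path} needs an id column "
                              "plus at least one value column")
    df = df.set_index(df.columns[0])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise StructuralError(f"duplicate cell id {dup!r} in {path}")
    return df


def _strict_join(base: pd.DataFrame, other: pd.DataFrame,
                 what: str) -> pd.DataFrame:
    extra = other.index.difference(base.index)
    missing = base.index.difference(other.index)
    if len(extra):
        raise StructuralError(f"{what} table has unmatched id {extra[0]!r}")
    if len(missing):
        raise StructuralError(f"{what} table is missing id {missing[0]!r}")
    return other.loc[base.index]


def read_delimited(coords, annotations=None, features=None,
                   graph_sidecar=None) -> RawDataset:
    """Read the delimited-text exchange bundle.

    ``coords``: TSV with a header row, first column cell id, then 2 or 3
    numeric coordinate columns.  Optional ``annotations``/``features`` TSVs
    are joined strictly on the same id set (row order taken from coords).
    The optional JSON ``graph_sidecar`` declares either cluster-level
    connectivities or a set of principal curves.
    """
    cdf = _read_tsv(coords, "coordinates")
    if cdf.shape[1] not in (2, 3):
        raise StructuralError(
            f"coordinates table must have 2 or 3 coordinate columns, "
            f"got {cdf.shape[1]}")
    try:
        emb = cdf.astype(float).to_numpy()
    except ValueError as exc:
        raise StructuralError(f"non-numeric coordinate value: {exc}") from exc

    cell_ids = [str(i) for i in cdf.index]
    obs = pd.DataFrame(index=cdf.index)
    if annotations is not None:
        adf = _strict_join(cdf, _read_tsv(annotations, "annotation"),
                           "annotation")
        obs = adf
    var_names: list[str] = []
    layers: dict[str, np.ndarray] = {}
    if features is not None:
        fdf = _strict_join(cdf, _read_tsv(features, "feature"), "feature")
        try:
            mat = fdf.astype(float).to_numpy()
        except ValueError as exc:
            raise StructuralError(
                f"non-numeric feature value: {exc}") from exc
        var_names = [str(c) for c in fdf.columns]
        layers = {"X": mat}

    cluster_key = None
    groups = None
    conn = None
    curves = None
    if graph_sidecar is not None:
        path = Path(graph_sidecar)
        if not path.is_file():
            raise IngestError(f"no such graph sidecar: {path}")
        with open(path, encoding="utf-8") as fh:
            side = json.load(fh)
        kind = side.get("kind")
        if kind == "abstract":
            groups = [str(g) for g in side["groups"]]
            conn = np.asarray(side["connectivities"], dtype=float)
            cluster_key = side.get("cluster_key")
            if cluster_key is None:
                for col in obs.columns:
                    if set(map(str, pd.unique(obs[col]))) == set(groups):
                        cluster_key = str(col)
                        break
            if cluster_key is None or cluster_key not in obs.columns:
                raise StructuralError(
                    "graph sidecar groups match no annotation column")
            known = set(map(str, pd.unique(obs[cluster_key])))
            unknown = [g for g in groups if g not in known]
            if unknown:
                raise StructuralError(
                    f"graph sidecar references unknown group {unknown[0]!r}")
        elif kind == "principal_curve":
            curves = [
                Curve(curve_id=str(c["id"]), from_node=str(c["from"]),
                      to_node=str(c["to"]),
                      points=np.asarray(c["points"], dtype=float))
                for c in side["curves"]
            ]
        else:
            raise StructuralError(
                f"graph sidecar kind must be 'abstract' or "
                f"'principal_curve', got {kind!r}")

    raw = RawDataset(
        cell_ids=cell_ids,
        embeddings={"embedding": emb},
        obs=obs,
        var_names=var_names,
        matrix_layers=layers,
        cluster_key=cluster_key,
        connectivity_groups=groups,
        abstract_connectivities=conn,
        curve_set=curves,
    )
    raw.check()
    return raw


# ---------------------------------------------------------------------------
# extraction

def extract_embedding(raw: RawDataset, name: str) -> tuple[np.ndarray, int]:
    """Return the named embedding's coordinate rows and its dimensionality.

    Embeddings with more than 3 columns are truncated to their first 3
    components (the leading components of any ordered reduction) rather
    than recomputed — recomputation would silently change published
    coordinates.
    """
    if name not in raw.embeddings:
        raise IngestError(
            f"unknown embedding {name!r}; available: "
            f"{sorted(raw.embeddings)}")
    emb = np.asarray(raw.embeddings[name], dtype=float)
    if emb.shape[1] > 3:
        emb = emb[:, :3]
    return emb, int(emb.shape[1])


def extract_abstract_graph(raw: RawDataset, coords: np.ndarray,
                           cluster_key: str,
                           weight_floor: float = DEFAULT_WEIGHT_FLOOR,
                           ) -> TrajectoryGraph:
    """Cluster-level abstract graph positioned at cell-group centroids.

    One node per group at the arithmetic centroid of its member cells'
    coordinates; one straight edge per unordered group pair whose
    connectivity exceeds ``weight_floor``, with width scaled linearly in
    the connectivity weight.
    """
    if raw.abstract_connectivities is None:
        raise StructuralError("dataset carries no abstract connectivities")
    if cluster_key not in raw.obs.columns:
        raise StructuralError(f"no annotation column {cluster_key!r}")
    labels = raw.obs[cluster_key].astype(str).to_numpy()
    groups = raw.connectivity_groups
    if groups is None:
        groups = sorted(set(labels))
    conn = np.asarray(raw.abstract_connectivities, dtype=float)
    if conn.shape[0] != len(groups):
        raise StructuralError(
            f"connectivity matrix is {conn.shape[0]}x{conn.shape[1]} "
            f"but there are {len(groups)} groups")
    coords = np.asarray(coords, dtype=float)
    nodes = []
    for g in groups:
        member = labels == g
        if not member.any():
            raise StructuralError(f"group {g!r} has no cells")
        nodes.append(GraphNode(node_id=str(g),
                               position=coords[member].mean(axis=0),
                               label=str(g)))
    edges = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            w = float(conn[i, j])
            if w > weight_floor:
                edges.append(GraphEdge(
                    source=str(groups[i]), target=str(groups[j]),
                    weight=w, width=edge_width(w),
                    polyline=np.vstack([nodes[i].position,
                                        nodes[j].position]),
                ))
    return TrajectoryGraph(graph_kind="abstract", nodes=nodes, edges=edges)


def resample_polyline(points: np.ndarray, k: int) -> np.ndarray:
    """Resample a polyline to k points evenly spaced by cumulative arc length.

    Coincident consecutive duplicate points are dropped first; a polyline
    that collapses to a single point raises :class:`StructuralError`.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise StructuralError("polyline needs at least 2 points")
    keep = np.ones(pts.shape[0], dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    pts = pts[keep]
    if pts.shape[0] < 2:
        raise StructuralError("polyline collapses to a single point")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], k)
    return np.column_stack(
        [np.interp(targets, s, pts[:, d]) for d in range(pts.shape[1])])


def _to_3d(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(pts.shape[0])])
    return pts


def extract_principal_curves(raw: RawDataset,
                             k_samples: int = DEFAULT_K_SAMPLES,
                             ) -> TrajectoryGraph:
    """Principal-curve trajectory: each branch resampled by arc length.

    Nodes are the union of declared curve endpoints, positioned at the
    curve termini; every edge carries its resampled polyline with weight
    1.0.
    """
    if not raw.curve_set:
        raise StructuralError("dataset carries no principal curves")
    nodes: dict[str, GraphNode] = {}
    edges = []
    for cv in raw.curve_set:
        poly = resample_polyline(_to_3d(cv.points), k_samples)
        for node_id, position in ((cv.from_node, poly[0]),
                                  (cv.to_node, poly[-1])):
            if node_id not in nodes:
                nodes[node_id] = GraphNode(node_id=node_id,
                                           position=position, label=node_id)
        # anchor the polyline exactly on the (first-declared) node positions
        poly[0] = nodes[cv.from_node].position
        poly[-1] = nodes[cv.to_node].position
        edges.append(GraphEdge(source=cv.from_node, target=cv.to_node,
                               weight=1.0, width=edge_width(1.0),
                               polyline=poly))
    return TrajectoryGraph(graph_kind="principal_curve",
                           nodes=list(nodes.values()), edges=edges)


def extract_velocity(raw: RawDataset, embedding_name: str,
                     scale: float = 1.0) -> np.ndarray:
    """Embedded velocity vectors as scene-unit 3-vectors.

    Velocity vectors are displacements, so only the isotropic normalization
    scale divides them (the centroid translation does not apply).  2-D
    vectors are lifted with a zero third component.  Raises
    :class:`NoVelocityError` when the dataset has no embedded velocity —
    callers then build the scene without a velocity layer.
    """
    if raw.velocity_embedding is None:
        raise NoVelocityError("dataset carries no embedded velocity vectors")
    if raw.velocity_basis is not None and raw.velocity_basis != embedding_name:
        raise StructuralError(
            f"velocity vectors are aligned to embedding "
            f"{raw.velocity_basis!r}, not {embedding_name!r}")
    vec = np.asarray(raw.velocity_embedding, dtype=float)
    if vec.shape[0] != raw.n_cells:
        raise StructuralError("velocity row count does not match cell count")
    if vec.shape[1] > 3:
        vec = vec[:, :3]
    vec = _to_3d(vec)
    return vec / float(scale)
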