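"""Canonical in-memory VR scene model and its validation.

A :class:`VRScene` aggregates everything a VR viewer needs to display a
single-cell experiment: normalized 3-D cell positions, per-cell annotation
tracks (categorical labels or continuous scalars such as pseudotime),
per-cell feature tracks (gene expression, TF-motif deviation, protein
abundance), an optional trajectory graph (cluster-level abstract graph or
principal curves), and an optional RNA-velocity layer.

Scene coordinates are dimensionless: after normalization every cell lies in
the closed unit ball, and the manifest records the centroid/scale transform
so original embedding coordinates are recoverable.  Physical sizing in VR is
the viewer's concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import SceneError

#: Maximum rendered edge width in scene units.
WIDTH_MAX = 1.0

#: Supported scene-package format version (major.minor).
FORMAT_VERSION = "1.0"


def edge_width(weight: float) -> float:
    """Rendered width of a trajectory edge as a function of its weight.

    Linear ramp ``0.1 + 0.9*w`` so that width is strictly increasing in
    connectivity weight and never exceeds :data:`WIDTH_MAX` for w in [0, 1].
    A floor of 0.1 keeps zero-confidence edges visible if a caller chooses
    to retain them.
    """
    return 0.1 + 0.9 * float(weight)


def wrap_angle(deg: float) -> float:
    """Canonically wrap an angle in degrees into (-180, 180]."""
    r = math.fmod(float(deg), 360.0)
    if r <= -180.0:
        r += 360.0
    elif r > 180.0:
        r -= 360.0
    return r


@dataclass
class CellTable:
    """Ordered cell identifiers with one 3-vector scene position each."""

    cell_ids: list[str]
    positions: np.ndarray  # (n, 3) float

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class AnnotationTrack:
    """One per-cell annotation: categorical labels or a continuous scalar.

    Categorical values are stored as integer indexes into ``labels`` (compact
    in JSON); ``colors`` holds one hex color per category.  Continuous tracks
    carry their [min, max] range and the colormap name used for display.
    """

    key: str
    kind: str  # "categorical" | "continuous"
    values: np.ndarray  # (n,) int indexes or float
    labels: Optional[list[str]] = None
    colors: Optional[list[str]] = None
    range: Optional[tuple[float, float]] = None
    colormap_name: Optional[str] = None


@dataclass
class FeatureTrack:
    """Per-cell quantification of one measured feature (units as supplied)."""

    feature_id: str
    values: np.ndarray  # (n,) float
    range: tuple[float, float]


@dataclass
class GraphNode:
    node_id: str
    position: np.ndarray  # (3,)
    label: str = ""


@dataclass
class GraphEdge:
    """Trajectory edge carried as a polyline in scene coordinates.

    For abstract graphs the polyline is the two node positions (a straight
    segment); for principal curves it is the resampled curve.  The polyline
    must start at the source node position and end at the target node
    position.
    """

    source: str
    target: str
    weight: float  # in [0, 1]
    width: float  # in (0, WIDTH_MAX]
    polyline: np.ndarray  # (k >= 2, 3)


@dataclass
class TrajectoryGraph:
    graph_kind: str  # "abstract" | "principal_curve"
    nodes: list[GraphNode]
    edges: list[GraphEdge]


@dataclass
class GridField:
    """Velocity vectors kernel-averaged onto a regular lattice.

    Only lattice points whose kernel-weighted local cell density (``mass``)
    reached the construction-time threshold ``min_mass`` are retained, so
    arrows never float in empty regions of the embedding.
    """

    resolution: tuple[int, int, int]
    points: np.ndarray  # (m, 3)
    vectors: np.ndarray  # (m, 3)
    mass: np.ndarray  # (m,)
    min_mass: float = 0.0


@dataclass
class VelocityLayer:
    """Per-cell velocity vectors in scene units (displacement per unit t).

    ``t_default`` is the latent-time animation scale: the viewer displaces
    each arrow tip by ``t * vector`` and the packaged scene stores raw
    vectors only, never pre-baked frames.
    """

    cell_vectors: np.ndarray  # (n, 3)
    t_default: float = 1.0
    grid: Optional[GridField] = None


@dataclass
class SceneManifest:
    """Index of the scene: counts, track listing, normalization transform."""

    format_version: str
    name: str
    n_cells: int
    embedding_name: str
    source_dims: int
    annotation_index: list[dict]  # [{"key": ..., "kind": ...}]
    feature_index: list[str]
    has_graph: bool
    has_velocity: bool
    transform: dict  # {"centroid": [x,y,z], "scale": s}


@dataclass
class VRScene:
    manifest: SceneManifest
    cells: CellTable
    annotations: list[AnnotationTrack] = field(default_factory=list)
    features: list[FeatureTrack] = field(default_factory=list)
    graph: Optional[TrajectoryGraph] = None
    velocity: Optional[VelocityLayer] = None


@dataclass
class CameraPose:
    """Camera position (scene units) plus yaw/pitch/roll in degrees.

    Yaw rotates about the vertical axis, pitch about the lateral axis, roll
    about the view axis, applied yaw -> pitch -> roll.  Angles are
    canonically wrapped into (-180, 180].
    """

    x: float
    y: float
    z: float
    yaw: float
    pitch: float
    roll: float

    def canonical(self) -> "CameraPose":
        return CameraPose(
            self.x, self.y, self.z,
            wrap_angle(self.yaw), wrap_angle(self.pitch), wrap_angle(self.roll),
        )


@dataclass
class ValidationIssue:
    severity: str  # "error" | "warning"
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.path}: {self.message}"


ValidationReport = list


def _finite(a: np.ndarray) -> bool:
    return bool(np.isfinite(np.asarray(a, dtype=float)).all())


def _check_cells(cells: CellTable, out: list) -> None:
    ids = cells.cell_ids
    if len(ids) != len(set(ids)) or any(not i for i in ids):
        out.append(ValidationIssue("error", "cells.cell_ids",
                                   "cell ids must be unique and non-empty"))
    pos = np.asarray(cells.positions, dtype=float)
    if pos.shape != (len(ids), 3):
        out.append(ValidationIssue(
            "error", "cells.positions",
            f"expected shape ({len(ids)}, 3), got {pos.shape}"))
        return
    if not _finite(pos):
        out.append(ValidationIssue("error", "cells.positions",
                                   "non-finite coordinate"))
        return
    # slack covers the 6-significant-digit storage quantization of packaged
    # coordinates (a point exactly on the unit sphere may round outward)
    if pos.size and np.linalg.norm(pos, axis=1).max() > 1.0 + 1e-5:
        out.append(ValidationIssue("error", "cells.positions",
                                   "position outside the closed unit ball"))


def _check_annotation(tr: AnnotationTrack, n: int, out: list) -> None:
    p = f"annotations[{tr.key}]"
    vals = np.asarray(tr.values)
    if vals.shape != (n,):
        out.append(ValidationIssue(
            "error", f"{p}.values", f"expected {n} values, got {vals.shape}"))
        return
    if tr.kind == "categorical":
        labels = tr.labels or []
        if len(labels) != len(set(labels)):
            out.append(ValidationIssue("error", f"{p}.labels",
                                       "labels not unique"))
            return
        if tr.colors is None or len(tr.colors) != len(labels):
            out.append(ValidationIssue("error", f"{p}.colors",
                                       "need one color per category"))
            return
        iv = vals.astype(int)
        if vals.size and (iv.min() < 0 or iv.max() >= len(labels)):
            out.append(ValidationIssue("error", f"{p}.values",
                                       "category index out of range"))
    elif tr.kind == "continuous":
        lo, hi = tr.range if tr.range is not None else (math.nan, math.nan)
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            out.append(ValidationIssue("error", f"{p}.range",
                                       f"invalid range [{lo}, {hi}]"))
            return
        if not _finite(vals):
            out.append(ValidationIssue("error", f"{p}.values",
                                       "non-finite value"))
            return
        if vals.size and (vals.min() < lo - 1e-12 or vals.max() > hi + 1e-12):
            out.append(ValidationIssue("error", f"{p}.values",
                                       "value outside declared range"))
    else:
        out.append(ValidationIssue("error", f"{p}.kind",
                                   f"unknown kind {tr.kind!r}"))


def _check_feature(tr: FeatureTrack, n: int, out: list) -> None:
    p = f"features[{tr.feature_id}]"
    vals = np.asarray(tr.values, dtype=float)
    if vals.shape != (n,):
        out.append(ValidationIssue(
            "error", f"{p}.values", f"expected {n} values, got {vals.shape}"))
        return
    if not _finite(vals):
        out.append(ValidationIssue("error", f"{p}.values", "non-finite value"))
        return
    lo, hi = tr.range
    if vals.size and (vals.min() < lo - 1e-12 or vals.max() > hi + 1e-12):
        out.append(ValidationIssue("error", f"{p}.range",
                                   "range does not bracket values"))


def _check_graph(g: TrajectoryGraph, out: list) -> None:
    node_ids = [nd.node_id for nd in g.nodes]
    if len(node_ids) != len(set(node_ids)):
        out.append(ValidationIssue("error", "graph.nodes",
                                   "duplicate node ids"))
        return
    pos = {nd.node_id: np.asarray(nd.position, dtype=float) for nd in g.nodes}
    for k, e in enumerate(g.edges):
        p = f"graph.edges[{k}]"
        if e.source not in pos or e.target not in pos:
            out.append(ValidationIssue("error", p,
                                       "edge endpoint not a known node"))
            continue
        poly = np.asarray(e.polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 3:
            out.append(ValidationIssue("error", f"{p}.polyline",
                                       "polyline needs >= 2 3-D points"))
            continue
        if (np.linalg.norm(poly[0] - pos[e.source]) > 1e-6
                or np.linalg.norm(poly[-1] - pos[e.target]) > 1e-6):
            out.append(ValidationIssue(
                "error", f"{p}.polyline",
                "polyline does not join source to target node"))
            continue
        if not (0.0 <= e.weight <= 1.0):
            out.append(ValidationIssue("error", f"{p}.weight",
                                       "weight outside [0, 1]"))
            continue
        if not (0.0 < e.width <= WIDTH_MAX):
            out.append(ValidationIssue(
                "error", f"{p}.width", f"width outside (0, {WIDTH_MAX}]"))
    # widths must order exactly like weights across the whole graph
    # weights closer than the storage quantum are treated as ties
    es = sorted(g.edges, key=lambda e: e.weight)
    for a, b in zip(es, es[1:]):
        if a.weight + 1e-6 < b.weight and not a.width < b.width:
            out.append(ValidationIssue(
                "error", "graph.edges",
                "edge width not strictly increasing in weight"))
            break


def _check_velocity(v: VelocityLayer, n: int, out: list) -> None:
    vec = np.asarray(v.cell_vectors, dtype=float)
    if vec.shape != (n, 3):
        out.append(ValidationIssue(
            "error", "velocity.cell_vectors",
            f"expected shape ({n}, 3), got {vec.shape}"))
    elif not _finite(vec):
        out.append(ValidationIssue("error", "velocity.cell_vectors",
                                   "non-finite component"))
    if not (v.t_default > 0):
        out.append(ValidationIssue("error", "velocity.t_default",
                                   "t_default must be > 0"))
    if v.grid is not None:
        g = v.grid
        m = np.asarray(g.points).shape[0]
        if (np.asarray(g.vectors).shape != (m, 3)
                or np.asarray(g.mass).shape != (m,)):
            out.append(ValidationIssue("error", "velocity.grid",
                                       "points/vectors/mass counts differ"))
            return
        nx, ny, nz = g.resolution
        if m > nx * ny * nz:
            out.append(ValidationIssue("error", "velocity.grid.points",
                                       "more points than lattice sites"))
            return
        if m and np.asarray(g.mass, dtype=float).min() < max(0.0, g.min_mass) - 1e-12:
            out.append(ValidationIssue("error", "velocity.grid.mass",
                                       "mass below retention threshold"))


def _check_manifest(scene: VRScene, out: list) -> None:
    m = scene.manifest
    if m.n_cells != scene.cells.n_cells:
        out.append(ValidationIssue(
            "error", "manifest.n_cells",
            f"manifest says {m.n_cells}, scene has {scene.cells.n_cells}"))
    want_ann = [{"key": t.key, "kind": t.kind} for t in scene.annotations]
    if m.annotation_index != want_ann:
        out.append(ValidationIssue("error", "manifest.annotation_index",
                                   "does not enumerate annotation tracks"))
    if m.feature_index != [t.feature_id for t in scene.features]:
        out.append(ValidationIssue("error", "manifest.feature_index",
                                   "does not enumerate feature tracks"))
    if m.has_graph != (scene.graph is not None):
        out.append(ValidationIssue("error", "manifest.has_graph",
                                   "flag contradicts graph presence"))
    if m.has_velocity != (scene.velocity is not None):
        out.append(ValidationIssue("error", "manifest.has_velocity",
                                   "flag contradicts velocity presence"))
    scale = m.transform.get("scale", None)
    if not (isinstance(scale, (int, float)) and scale > 0):
        out.append(ValidationIssue("error", "manifest.transform.scale",
                                   "scale must be > 0"))
    if m.source_dims not in (2, 3):
        out.append(ValidationIssue("error", "manifest.source_dims",
                                   "source_dims must be 2 or 3"))


def validate_scene(scene: VRScene) -> ValidationReport:
    """Check every scene invariant; return a report of violations.

    The report is empty iff the scene is well-formed.  Violations are
    reported as entries (never raised), each with a path naming the
    offending member.
    """
    out: list[ValidationIssue] = []
    _check_cells(scene.cells, out)
    n = scene.cells.n_cells
    keys = [t.key for t in scene.annotations]
    if len(keys) != len(set(keys)):
        out.append(ValidationIssue("error", "annotations",
                                   "duplicate annotation keys"))
    fids = [t.feature_id for t in scene.features]
    if len(fids) != len(set(fids)):
        out.append(ValidationIssue("error", "features",
                                   "duplicate feature ids"))
    for tr in scene.annotations:
        _check_annotation(tr, n, out)
    for tr in scene.features:
        _check_feature(tr, n, out)
    if scene.graph is not None:
        _check_graph(scene.graph, out)
    if scene.velocity is not None:
        _check_velocity(scene.velocity, n, out)
    _check_manifest(scene, out)
    return out


def summarize_scene(scene: VRScene) -> SceneManifest:
    """Return the manifest that exactly enumerates the scene's contents.

    Name, embedding name, source dimensionality and the normalization
    transform are carried over from the existing manifest; counts, indexes
    and flags are recomputed.  Idempotent for a valid scene.  Raises
    :class:`SceneError` carrying the first validation error if the scene is
    invalid.
    """
    report = validate_scene(scene)
    errors = [r for r in report if r.severity == "error"]
    if errors:
        raise SceneError(f"invalid scene: {errors[0]}")
    m = scene.manifest
    return SceneManifest(
        format_version=m.format_version,
        name=m.name,
        n_cells=scene.cells.n_cells,
        embedding_name=m.embedding_name,
        source_dims=m.source_dims,
        annotation_index=[{"key": t.key, "kind": t.kind}
                          for t in scene.annotations],
        feature_index=[t.feature_id for t in scene.features],
        has_graph=scene.graph is not None,
        has_velocity=scene.velocity is not None,
        transform={"centroid": list(map(float, m.transform["centroid"])),
                   "scale": float(m.transform["scale"])},
    )
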