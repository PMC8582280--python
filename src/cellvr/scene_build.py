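"""Build a normalized, colored, optionally downsampled VRScene.

Pipeline (``build_scene``): extract the requested embedding, lift 2-D
embeddings into the z = 0 plane, optionally downsample cells (stratified by
a categorical key with largest-remainder quotas), normalize coordinates into
the closed unit ball, then attach annotation, feature, graph and velocity
tracks.  Trajectory-graph node and polyline coordinates pass through the
same normalization transform as the cells; velocity vectors are divided by
the isotropic scale only.

Normalization is isotropic (unit ball, not unit cube) on purpose: it
preserves the aspect ratio of the embedding, whereas per-axis scaling would
misrepresent the distances the embedding encodes.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._colors import DEFAULT_COLORMAP_NAME, DEFAULT_PALETTE, colormap_hex
from .errors import IngestError, SceneError
from .ingest import (
    DEFAULT_K_SAMPLES,
    DEFAULT_WEIGHT_FLOOR,
    Curve,
    RawDataset,
    extract_abstract_graph,
    extract_embedding,
    extract_principal_curves,
    extract_velocity,
)
from .errors import NoVelocityError
from .scene_model import (
    FORMAT_VERSION,
    AnnotationTrack,
    CellTable,
    FeatureTrack,
    SceneManifest,
    VelocityLayer,
    VRScene,
    validate_scene,
)
from .velocity_field import GridConfig, estimate_grid_field


@dataclass
class BuildConfig:
    """Everything ``build_scene`` needs beyond the raw dataset.

    ``annotation_keys``/``feature_ids`` name per-cell columns and features to
    package.  ``max_cells`` enables downsampling (default: keep every cell —
    silently dropping cells would misrepresent the experiment);
    ``stratify_key`` defaults to the dataset's cluster key when present.
    ``clip_percentiles`` [lo, hi], when set, clamps feature values to those
    empirical percentiles before packaging.
    """

    name: str = "scene"
    embedding_name: str = "umap"
    annotation_keys: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)
    max_cells: Optional[int] = None
    seed: int = 0
    stratify_key: Optional[str] = None
    palette: list[str] = field(default_factory=lambda: list(DEFAULT_PALETTE))
    colormap_name: str = DEFAULT_COLORMAP_NAME
    clip_percentiles: Optional[tuple[float, float]] = None
    include_graph: bool = True
    include_velocity: bool = True
    weight_floor: float = DEFAULT_WEIGHT_FLOOR
    k_samples: int = DEFAULT_K_SAMPLES
    t_default: float = 1.0
    velocity_grid: bool = False
    grid_config: Optional[GridConfig] = None

    def __post_init__(self) -> None:
        if not self.palette:
            raise ValueError("palette must be non-empty")
        if self.clip_percentiles is not None:
            lo, hi = self.clip_percentiles
            if not (0 <= lo < hi <= 100):
                raise ValueError("clip_percentiles must satisfy "
                                 "0 <= lo < hi <= 100")
        if self.max_cells is not None and self.max_cells < 1:
            raise ValueError("max_cells must be >= 1")

    @classmethod
    def from_file(cls, path) -> "BuildConfig":
        """Read a flat ``key = value`` config file (keys match field names;
        lists comma-separated; '#' starts a comment)."""
        opts: dict = {}
        list_keys = {"annotation_keys", "feature_ids", "palette"}
        int_keys = {"max_cells", "seed", "k_samples"}
        float_keys = {"weight_floor", "t_default"}
        bool_keys = {"include_graph", "include_velocity", "velocity_grid"}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"bad config line: {line!r}")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key in list_keys:
                    opts[key] = [v.strip() for v in val.split(",") if v.strip()]
                elif key in int_keys:
                    opts[key] = int(val)
                elif key in float_keys:
                    opts[key] = float(val)
                elif key in bool_keys:
                    opts[key] = val.lower() in ("1", "true", "yes", "on")
                elif key == "clip_percentiles":
                    lo, hi = (float(v) for v in val.split(","))
                    opts[key] = (lo, hi)
                else:
                    opts[key] = val
        return cls(**opts)


# ---------------------------------------------------------------------------
# coordinate handling

def normalize_coordinates(coords: np.ndarray,
                          ) -> tuple[np.ndarray, dict]:
    """Center coordinates on their centroid and scale into the unit ball.

    Returns the normalized coordinates and the transform
    ``{"centroid": c, "scale": s}`` with ``original = output * s + c``.
    The scale is the maximum Euclidean norm after centering (1 when that
    maximum is 0, e.g. a single cell), so at least one point lands on the
    unit sphere in the non-degenerate case.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("need at least one coordinate row")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinate")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    scale = float(np.linalg.norm(centered, axis=1).max())
    if scale == 0.0:
        scale = 1.0
    return centered / scale, {"centroid": centroid, "scale": scale}


def apply_transform(coords: np.ndarray, transform: dict) -> np.ndarray:
    """Apply a recorded normalization transform to new points."""
    pts = np.asarray(coords, dtype=float)
    return (pts - np.asarray(transform["centroid"], dtype=float)) \
        / float(transform["scale"])


def lift_to_3d(coords2d: np.ndarray) -> np.ndarray:
    """Embed 2-D coordinates in the z = 0 plane (first two axes unchanged)."""
    pts = np.asarray(coords2d, dtype=float)
    if pts.ndim != 2:
        pts = pts.reshape(0, 2) if pts.size == 0 else pts
    if pts.shape[1] == 3:
        return pts
    if pts.shape[1] != 2:
        raise ValueError(f"expected 2 or 3 columns, got {pts.shape[1]}")
    return np.column_stack([pts, np.zeros(pts.shape[0])])


# ---------------------------------------------------------------------------
# downsampling

def stratified_quotas(counts: list[int], max_cells: int) -> list[int]:
    """Per-category keep quotas, proportional with largest-remainder
    rounding and a minimum of 1 per nonempty category."""
    n = sum(counts)
    k = sum(1 for c in counts if c > 0)
    if k > max_cells:
        raise ValueError(
            f"{k} categories cannot each keep one cell within "
            f"max_cells={max_cells}")
    # exact integer largest-remainder apportionment
    quotas = [c * max_cells // n for c in counts]
    remainders = [c * max_cells % n for c in counts]
    for idx in sorted(range(len(counts)),
                      key=lambda i: (-remainders[i], i)):
        if sum(quotas) >= max_cells:
            break
        quotas[idx] += 1
    # guarantee one representative per nonempty category
    for i, c in enumerate(counts):
        if c > 0 and quotas[i] == 0:
            donor = max(range(len(quotas)), key=lambda j: quotas[j])
            quotas[donor] -= 1
            quotas[i] = 1
    return quotas


def downsample_indices(n: int, max_cells: int, seed: int,
                       labels: Optional[np.ndarray] = None) -> np.ndarray:
    """Sorted indices of the kept cells (identity when n <= max_cells).

    Uniform without replacement; with ``labels``, per-category quotas are
    proportional (largest remainder, minimum 1 per nonempty category).
    The same seed always yields the same selection.
    """
    if max_cells < 1:
        raise ValueError("max_cells must be >= 1")
    if n <= max_cells:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    if labels is None:
        return np.sort(rng.choice(n, size=max_cells, replace=False))
    labels = np.asarray(labels).astype(str)
    cats = sorted(set(labels))
    counts = [int((labels == c).sum()) for c in cats]
    quotas = stratified_quotas(counts, max_cells)
    kept = []
    for cat, quota in zip(cats, quotas):
        idx = np.flatnonzero(labels == cat)
        kept.append(rng.choice(idx, size=quota, replace=False))
    return np.sort(np.concatenate(kept))


def _subset_raw(raw: RawDataset, idx: np.ndarray) -> RawDataset:
    return RawDataset(
        cell_ids=[raw.cell_ids[i] for i in idx],
        embeddings={k: v[idx] for k, v in raw.embeddings.items()},
        obs=raw.obs.iloc[idx],
        var_names=list(raw.var_names),
        matrix_layers={k: v[idx] for k, v in raw.matrix_layers.items()},
        cluster_key=raw.cluster_key,
        connectivity_groups=raw.connectivity_groups,
        abstract_connectivities=raw.abstract_connectivities,
        curve_set=raw.curve_set,
        velocity_embedding=(None if raw.velocity_embedding is None
                            else raw.velocity_embedding[idx]),
        velocity_basis=raw.velocity_basis,
    )


def downsample(obj, max_cells: int, seed: int,
               stratify_key: Optional[str] = None):
    """Downsample a :class:`RawDataset` or :class:`VRScene` to at most
    ``max_cells`` cells; every per-cell track is subset consistently.

    For a scene, the trajectory graph and manifest transform are kept as
    built (they summarize the full dataset); the manifest cell count is
    updated.
    """
    if isinstance(obj, RawDataset):
        labels = None
        if stratify_key is not None:
            if stratify_key not in obj.obs.columns:
                raise IngestError(f"no annotation column {stratify_key!r}")
            labels = obj.obs[stratify_key].to_numpy()
        idx = downsample_indices(obj.n_cells, max_cells, seed, labels)
        return obj if idx.size == obj.n_cells else _subset_raw(obj, idx)
    if isinstance(obj, VRScene):
        labels = None
        if stratify_key is not None:
            for tr in obj.annotations:
                if tr.key == stratify_key and tr.kind == "categorical":
                    labels = np.asarray(tr.labels)[
                        np.asarray(tr.values, dtype=int)]
                    break
            if labels is None:
                raise SceneError(
                    f"no categorical annotation {stratify_key!r}")
        n = obj.cells.n_cells
        idx = downsample_indices(n, max_cells, seed, labels)
        if idx.size == n:
            return obj
        scene = copy.deepcopy(obj)
        scene.cells = CellTable(
            cell_ids=[scene.cells.cell_ids[i] for i in idx],
            positions=np.asarray(scene.cells.positions)[idx])
        for tr in scene.annotations:
            tr.values = np.asarray(tr.values)[idx]
        for tr in scene.features:
            tr.values = np.asarray(tr.values)[idx]
        if scene.velocity is not None:
            scene.velocity.cell_vectors = np.asarray(
                scene.velocity.cell_vectors)[idx]
        scene.manifest.n_cells = int(idx.size)
        return scene
    raise TypeError(f"cannot downsample {type(obj).__name__}")


# ---------------------------------------------------------------------------
# colors

def assign_categorical_colors(labels, palette=None) -> dict[str, str]:
    """Stable hex color per category: categories sorted lexicographically,
    category i gets ``palette[i % len(palette)]``.  Depends only on the
    label *set*, not input order."""
    palette = palette or DEFAULT_PALETTE
    return {lab: palette[i % len(palette)]
            for i, lab in enumerate(sorted(set(map(str, labels))))}


def map_continuous_colors(values, colormap_name: str = DEFAULT_COLORMAP_NAME,
                          clip_percentiles=None,
                          return_hex: bool = False):
    """Normalize values to colormap positions u in [0, 1].

    With ``clip_percentiles=[lo, hi]``: ``u = clamp((v - q_lo) /
    (q_hi - q_lo), 0, 1)`` using empirical percentiles; without, min/max
    scaling.  Constant input maps everything to 0 with a "degenerate range"
    warning.
    """
    vals = np.asarray(values, dtype=float)
    if not np.isfinite(vals).all():
        bad = np.flatnonzero(~np.isfinite(vals))
        raise ValueError(f"non-finite values at cells {bad[:10].tolist()}")
    if clip_percentiles is not None:
        lo, hi = np.percentile(vals, list(clip_percentiles))
    else:
        lo, hi = vals.min(), vals.max()
    if hi == lo:
        warnings.warn("degenerate range: constant values map to u = 0")
        u = np.zeros_like(vals)
    else:
        u = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    if return_hex:
        return u, [colormap_hex(x) for x in u]
    return u


# ---------------------------------------------------------------------------
# track assembly

def _is_categorical(col: pd.Series) -> bool:
    if isinstance(col.dtype, pd.CategoricalDtype):
        return True
    return col.dtype.kind in ("O", "U", "S", "b")


def _annotation_track(key: str, col: pd.Series, config: BuildConfig,
                      ) -> AnnotationTrack:
    if _is_categorical(col):
        strs = col.astype(str).to_numpy()
        color_of = assign_categorical_colors(strs, config.palette)
        labels = sorted(color_of)
        index_of = {lab: i for i, lab in enumerate(labels)}
        return AnnotationTrack(
            key=key, kind="categorical",
            values=np.asarray([index_of[s] for s in strs], dtype=int),
            labels=labels, colors=[color_of[lab] for lab in labels])
    vals = col.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise IngestError(f"annotation {key!r} has non-finite values")
    rng = ((float(vals.min()), float(vals.max())) if vals.size
           else (0.0, 0.0))
    return AnnotationTrack(key=key, kind="continuous", values=vals,
                           range=rng, colormap_name=config.colormap_name)


def _feature_track(fid: str, values: np.ndarray, config: BuildConfig,
                   ) -> FeatureTrack:
    vals = np.asarray(values, dtype=float)
    if config.clip_percentiles is not None and vals.size:
        lo, hi = np.percentile(vals, list(config.clip_percentiles))
        vals = np.clip(vals, lo, hi)
    rng = ((float(vals.min()), float(vals.max())) if vals.size
           else (0.0, 0.0))
    return FeatureTrack(feature_id=fid, values=vals, range=rng)


def _transformed_curves(curves: list[Curve], transform: dict) -> list[Curve]:
    out = []
    for cv in curves:
        pts = lift_to_3d(np.asarray(cv.points, dtype=float))
        out.append(replace(cv, points=apply_transform(pts, transform)))
    return out


def build_scene(raw: RawDataset, config: Optional[BuildConfig] = None,
                ) -> VRScene:
    """Run the full conversion pipeline on a raw dataset.

    Returns a validated scene; any invariant violation after assembly is a
    bug and raises :class:`SceneError`.
    """
    config = config or BuildConfig()
    coords, source_dims = extract_embedding(raw, config.embedding_name)

    if config.max_cells is not None and raw.n_cells > config.max_cells:
        stratify = config.stratify_key
        if (stratify is None and raw.cluster_key is not None
                and raw.cluster_key in raw.obs.columns):
            stratify = raw.cluster_key
        raw = downsample(raw, config.max_cells, config.seed, stratify)
        coords, source_dims = extract_embedding(raw, config.embedding_name)

    coords = lift_to_3d(coords)
    normed, transform = normalize_coordinates(coords)
    cells = CellTable(cell_ids=list(raw.cell_ids), positions=normed)

    annotations = []
    for key in config.annotation_keys:
        if key not in raw.obs.columns:
            raise IngestError(f"unknown annotation key {key!r}; "
                              f"available: {sorted(raw.obs.columns)}")
        annotations.append(_annotation_track(key, raw.obs[key], config))

    features = []
    if config.feature_ids:
        if "X" not in raw.matrix_layers:
            raise IngestError("dataset has no feature matrix")
        col_of = {v: i for i, v in enumerate(raw.var_names)}
        for fid in config.feature_ids:
            if fid not in col_of:
                raise IngestError(f"unknown feature {fid!r}")
            features.append(_feature_track(
                fid, raw.matrix_layers["X"][:, col_of[fid]], config))

    graph = None
    if config.include_graph:
        if raw.curve_set:
            curves = _transformed_curves(raw.curve_set, transform)
            graph = extract_principal_curves(
                replace(raw, curve_set=curves), config.k_samples)
        elif (raw.abstract_connectivities is not None
              and raw.cluster_key is not None):
            graph = extract_abstract_graph(
                raw, normed, raw.cluster_key, config.weight_floor)

    velocity = None
    if config.include_velocity:
        try:
            vec = extract_velocity(raw, config.embedding_name,
                                   scale=transform["scale"])
        except NoVelocityError:
            vec = None
        if vec is not None:
            grid = None
            if config.velocity_grid:
                grid = estimate_grid_field(
                    normed, vec, config.grid_config or GridConfig())
            velocity = VelocityLayer(cell_vectors=vec,
                                     t_default=config.t_default, grid=grid)

    manifest = SceneManifest(
        format_version=FORMAT_VERSION,
        name=config.name,
        n_cells=cells.n_cells,
        embedding_name=config.embedding_name,
        source_dims=source_dims,
        annotation_index=[{"key": t.key, "kind": t.kind}
                          for t in annotations],
        feature_index=[t.feature_id for t in features],
        has_graph=graph is not None,
        has_velocity=velocity is not None,
        transform={"centroid": [float(c) for c in transform["centroid"]],
                   "scale": float(transform["scale"])},
    )
    scene = VRScene(manifest=manifest, cells=cells, annotations=annotations,
                    features=features, graph=graph, velocity=velocity)
    report = [r for r in validate_scene(scene) if r.severity == "error"]
    if report:
        raise SceneError(f"assembled scene failed validation: {report[0]}")
    return scene
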