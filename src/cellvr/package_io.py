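"""Scene-package serialization: a zip of small JSON members.

Layout (format version 1.0)::

    name.zip
      index.json              manifest: counts, track indexes, transform
      scatter.json            [{"i": cell_id, "p": [x, y, z]}, ...]
      annotations/<key>.json  categorical: {"kind","labels","colors","values"}
                              continuous:  {"kind","range","colormap","values"}
      features/<id>.json      {"id", "range", "values"}
      graph.json              {"kind", "nodes", "edges"}          (optional)
      velocity.json           {"t_default", "vectors", "grid"?}   (optional)

One JSON member per feature lets a viewer fetch features lazily instead of
downloading a monolith.  Serialization is canonical — sorted keys, no
insignificant whitespace, floats at 6 significant digits, fixed member
order and timestamps — so identical scenes produce byte-identical archives
and a write -> read -> write round trip is a byte-level identity.
"""

from __future__ import annotations

import json
import urllib.parse
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    MissingMemberError,
    PackageConsistencyError,
    PackageError,
    PackageParseError,
)
from .scene_model import (
    FORMAT_VERSION,
    AnnotationTrack,
    CellTable,
    FeatureTrack,
    GraphEdge,
    GraphNode,
    GridField,
    SceneManifest,
    TrajectoryGraph,
    ValidationIssue,
    VelocityLayer,
    VRScene,
    validate_scene,
)

_ZIP_DATE = (1980, 1, 1, 0, 0, 0)  # fixed timestamp for byte reproducibility


@dataclass
class ScenePackage:
    """Handle on an on-disk scene package."""

    path: Path
    members: list[str]
    manifest: SceneManifest


# ---------------------------------------------------------------------------
# canonical JSON

def _fmt(value) -> str:
    if value is None:
        return "null"
    if value is True:
        return "true"
    if value is False:
        return "false"
    if isinstance(value, str):
        return json.dumps(value, ensure_ascii=False)
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if not np.isfinite(value):
            raise PackageError(f"non-finite float {value!r} in package")
        return format(float(value), ".6g")
    if isinstance(value, dict):
        items = sorted(value.items())
        return "{" + ",".join(f"{json.dumps(k)}:{_fmt(v)}"
                              for k, v in items) + "}"
    if isinstance(value, (list, tuple, np.ndarray)):
        return "[" + ",".join(_fmt(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value).__name__}")


def canonical_json(value) -> bytes:
    """Canonical UTF-8 JSON bytes (sorted keys, 6-significant-digit floats,
    no insignificant whitespace)."""
    return _fmt(value).encode("utf-8")


def _member_name(key: str) -> str:
    """Filesystem/zip-safe member stem for a track key (reversible)."""
    return urllib.parse.quote(key, safe="._-")


# ---------------------------------------------------------------------------
# scene -> JSON members

def _scatter_obj(cells: CellTable) -> list:
    return [{"i": cid, "p": list(map(float, p))}
            for cid, p in zip(cells.cell_ids, np.asarray(cells.positions))]


def _annotation_obj(tr: AnnotationTrack) -> dict:
    if tr.kind == "categorical":
        return {"kind": "categorical", "labels": list(tr.labels),
                "colors": list(tr.colors),
                "values": [int(v) for v in np.asarray(tr.values)]}
    return {"kind": "continuous", "range": list(map(float, tr.range)),
            "colormap": tr.colormap_name or "",
            "values": [float(v) for v in np.asarray(tr.values)]}


def _feature_obj(tr: FeatureTrack) -> dict:
    return {"id": tr.feature_id, "range": list(map(float, tr.range)),
            "values": [float(v) for v in np.asarray(tr.values)]}


def _graph_obj(g: TrajectoryGraph) -> dict:
    return {
        "kind": g.graph_kind,
        "nodes": [{"id": nd.node_id, "p": list(map(float, nd.position)),
                   "label": nd.label} for nd in g.nodes],
        "edges": [{"s": e.source, "t": e.target, "w": float(e.weight),
                   "width": float(e.width),
                   "points": [list(map(float, p)) for p in
                              np.asarray(e.polyline)]}
                  for e in g.edges],
    }


def _velocity_obj(v: VelocityLayer) -> dict:
    obj = {"t_default": float(v.t_default),
           "vectors": [list(map(float, r))
                       for r in np.asarray(v.cell_vectors)]}
    if v.grid is not None:
        g = v.grid
        obj["grid"] = {
            "resolution": [int(r) for r in g.resolution],
            "points": [list(map(float, p)) for p in np.asarray(g.points)],
            "vectors": [list(map(float, p)) for p in np.asarray(g.vectors)],
            "mass": [float(m) for m in np.asarray(g.mass)],
            "min_mass": float(g.min_mass),
        }
    return obj


def _manifest_obj(m: SceneManifest) -> dict:
    return {
        "format_version": m.format_version,
        "name": m.name,
        "n_cells": int(m.n_cells),
        "embedding_name": m.embedding_name,
        "source_dims": int(m.source_dims),
        "annotation_index": [{"key": e["key"], "kind": e["kind"]}
                             for e in m.annotation_index],
        "feature_index": list(m.feature_index),
        "has_graph": bool(m.has_graph),
        "has_velocity": bool(m.has_velocity),
        "transform": {"centroid": list(map(float,
                                           m.transform["centroid"])),
                      "scale": float(m.transform["scale"])},
    }


def expected_members(manifest: SceneManifest) -> list[str]:
    """Members the manifest promises, in canonical archive order."""
    members = ["index.json", "scatter.json"]
    members += [f"annotations/{_member_name(e['key'])}.json"
                for e in manifest.annotation_index]
    members += [f"features/{_member_name(f)}.json"
                for f in manifest.feature_index]
    if manifest.has_graph:
        members.append("graph.json")
    if manifest.has_velocity:
        members.append("velocity.json")
    return members


def write_scene_package(scene: VRScene, out_path) -> ScenePackage:
    """Serialize a valid scene to a canonical zipped-JSON package."""
    errors = [r for r in validate_scene(scene) if r.severity == "error"]
    if errors:
        raise PackageError(f"refusing to write invalid scene: {errors[0]}")
    out_path = Path(out_path)
    payload: list[tuple[str, bytes]] = [
        ("index.json", canonical_json(_manifest_obj(scene.manifest))),
        ("scatter.json", canonical_json(_scatter_obj(scene.cells))),
    ]
    for tr in scene.annotations:
        payload.append((f"annotations/{_member_name(tr.key)}.json",
                        canonical_json(_annotation_obj(tr))))
    for tr in scene.features:
        payload.append((f"features/{_member_name(tr.feature_id)}.json",
                        canonical_json(_feature_obj(tr))))
    if scene.graph is not None:
        payload.append(("graph.json", canonical_json(_graph_obj(scene.graph))))
    if scene.velocity is not None:
        payload.append(("velocity.json",
                        canonical_json(_velocity_obj(scene.velocity))))

    with zipfile.ZipFile(out_path, "w") as zf:
        for name, data in payload:
            zi = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            zi.compress_type = zipfile.ZIP_DEFLATED
            zi.external_attr = 0o644 << 16
            zi.create_system = 3
            zf.writestr(zi, data, compresslevel=6)
    return ScenePackage(path=out_path, members=[n for n, _ in payload],
                        manifest=scene.manifest)


# ---------------------------------------------------------------------------
# JSON members -> scene

def _load_member(zf: zipfile.ZipFile, name: str):
    try:
        data = zf.read(name)
    except KeyError:
        raise MissingMemberError(f"missing member {name}") from None
    try:
        return json.loads(data.decode("utf-8"))
    except (ValueError, UnicodeDecodeError) as exc:
        raise PackageParseError(f"member {name} is not valid JSON: "
                                f"{exc}") from exc


def _parse_manifest(obj: dict) -> SceneManifest:
    try:
        version = str(obj["format_version"])
        major = version.split(".", 1)[0]
        if major != FORMAT_VERSION.split(".", 1)[0]:
            raise PackageParseError(
                f"unsupported format major version {version!r}")
        return SceneManifest(
            format_version=version,
            name=str(obj["name"]),
            n_cells=int(obj["n_cells"]),
            embedding_name=str(obj["embedding_name"]),
            source_dims=int(obj["source_dims"]),
            annotation_index=[{"key": str(e["key"]), "kind": str(e["kind"])}
                              for e in obj["annotation_index"]],
            feature_index=[str(f) for f in obj["feature_index"]],
            has_graph=bool(obj["has_graph"]),
            has_velocity=bool(obj["has_velocity"]),
            transform={"centroid": [float(c) for c in
                                    obj["transform"]["centroid"]],
                       "scale": float(obj["transform"]["scale"])},
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PackageParseError(f"malformed index.json: {exc}") from exc


def _parse_annotation(key: str, kind: str, obj: dict,
                      n_cells: int) -> AnnotationTrack:
    member = f"annotations/{_member_name(key)}.json"
    try:
        if obj["kind"] != kind:
            raise PackageConsistencyError(
                f"{member}: kind {obj['kind']!r} contradicts manifest "
                f"({kind!r})")
        values = obj["values"]
        if len(values) != n_cells:
            raise PackageConsistencyError(
                f"{member}: {len(values)} values for {n_cells} cells")
        if kind == "categorical":
            return AnnotationTrack(
                key=key, kind=kind,
                values=np.asarray([int(v) for v in values], dtype=int),
                labels=[str(x) for x in obj["labels"]],
                colors=[str(x) for x in obj["colors"]])
        return AnnotationTrack(
            key=key, kind=kind,
            values=np.asarray([float(v) for v in values], dtype=float),
            range=(float(obj["range"][0]), float(obj["range"][1])),
            colormap_name=str(obj["colormap"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise PackageParseError(f"malformed {member}: {exc}") from exc


def _parse_feature(fid: str, obj: dict, n_cells: int) -> FeatureTrack:
    member = f"features/{_member_name(fid)}.json"
    try:
        if str(obj["id"]) != fid:
            raise PackageConsistencyError(
                f"{member}: id {obj['id']!r} contradicts manifest")
        values = obj["values"]
        if len(values) != n_cells:
            raise PackageConsistencyError(
                f"{member}: {len(values)} values for {n_cells} cells")
        return FeatureTrack(
            feature_id=fid,
            values=np.asarray([float(v) for v in values], dtype=float),
            range=(float(obj["range"][0]), float(obj["range"][1])))
    except (KeyError, TypeError, ValueError) as exc:
        raise PackageParseError(f"malformed {member}: {exc}") from exc


def _parse_graph(obj: dict) -> TrajectoryGraph:
    try:
        nodes = [GraphNode(node_id=str(nd["id"]),
                           position=np.asarray(nd["p"], dtype=float),
                           label=str(nd.get("label", "")))
                 for nd in obj["nodes"]]
        edges = [GraphEdge(source=str(e["s"]), target=str(e["t"]),
                           weight=float(e["w"]), width=float(e["width"]),
                           polyline=np.asarray(e["points"], dtype=float))
                 for e in obj["edges"]]
        return TrajectoryGraph(graph_kind=str(obj["kind"]), nodes=nodes,
                               edges=edges)
    except (KeyError, TypeError, ValueError) as exc:
        raise PackageParseError(f"malformed graph.json: {exc}") from exc


def _parse_velocity(obj: dict, n_cells: int) -> VelocityLayer:
    try:
        vectors = np.asarray(obj["vectors"], dtype=float)
        if vectors.shape[0] != n_cells:
            raise PackageConsistencyError(
                f"velocity.json: {vectors.shape[0]} vectors for "
                f"{n_cells} cells")
        grid = None
        if "grid" in obj:
            g = obj["grid"]
            grid = GridField(
                resolution=tuple(int(r) for r in g["resolution"]),
                points=np.asarray(g["points"], dtype=float),
                vectors=np.asarray(g["vectors"], dtype=float),
                mass=np.asarray(g["mass"], dtype=float),
                min_mass=float(g.get("min_mass", 0.0)))
        return VelocityLayer(cell_vectors=vectors,
                             t_default=float(obj["t_default"]), grid=grid)
    except (KeyError, TypeError, ValueError) as exc:
        raise PackageParseError(f"malformed velocity.json: {exc}") from exc


def read_scene_package(path) -> VRScene:
    """Read a scene package back into a :class:`VRScene`.

    Raises :class:`MissingMemberError`, :class:`PackageParseError` or
    :class:`PackageConsistencyError` for the corresponding failure kinds.
    """
    path = Path(path)
    if not path.is_file():
        raise MissingMemberError(f"no such package: {path}")
    try:
        zf = zipfile.ZipFile(path)
    except zipfile.BadZipFile as exc:
        raise PackageParseError(f"{path} is not a zip archive: "
                                f"{exc}") from exc
    with zf:
        manifest = _parse_manifest(_load_member(zf, "index.json"))
        n = manifest.n_cells
        scatter = _load_member(zf, "scatter.json")
        if not isinstance(scatter, list):
            raise PackageParseError("scatter.json must be an array")
        if len(scatter) != n:
            raise PackageConsistencyError(
                f"manifest promises {n} cells, scatter.json has "
                f"{len(scatter)}")
        try:
            cell_ids = [str(row["i"]) for row in scatter]
            positions = np.asarray([row["p"] for row in scatter],
                                   dtype=float).reshape(len(scatter), 3)
        except (KeyError, TypeError, ValueError) as exc:
            raise PackageParseError(f"malformed scatter.json: {exc}") from exc
        cells = CellTable(cell_ids=cell_ids, positions=positions)

        annotations = [
            _parse_annotation(e["key"], e["kind"],
                              _load_member(
                                  zf, f"annotations/"
                                      f"{_member_name(e['key'])}.json"), n)
            for e in manifest.annotation_index]
        features = [
            _parse_feature(fid,
                           _load_member(
                               zf, f"features/{_member_name(fid)}.json"), n)
            for fid in manifest.feature_index]
        graph = (_parse_graph(_load_member(zf, "graph.json"))
                 if manifest.has_graph else None)
        velocity = (_parse_velocity(_load_member(zf, "velocity.json"), n)
                    if manifest.has_velocity else None)
    return VRScene(manifest=manifest, cells=cells, annotations=annotations,
                   features=features, graph=graph, velocity=velocity)


def validate_package(path) -> list[ValidationIssue]:
    """Validate a package on disk; violations become report entries.

    Checks archive structure (manifest present, promised members present,
    no extraneous top-level members), member parseability, and every
    scene-level invariant.  Feature members are checked one at a time and
    discarded, so validation memory does not grow with the number of
    features retained simultaneously.
    """
    out: list[ValidationIssue] = []
    path = Path(path)
    if not path.is_file():
        return [ValidationIssue("error", "archive", f"no such file: {path}")]
    try:
        zf = zipfile.ZipFile(path)
    except zipfile.BadZipFile as exc:
        return [ValidationIssue("error", "archive",
                                f"not a zip archive: {exc}")]
    with zf:
        names = set(zf.namelist())
        try:
            manifest = _parse_manifest(_load_member(zf, "index.json"))
        except PackageError as exc:
            return [ValidationIssue("error", "index.json", str(exc))]
        promised = expected_members(manifest)
        for name in promised:
            if name not in names:
                out.append(ValidationIssue("error", name,
                                           "missing member"))
        extra = sorted(names - set(promised))
        for name in extra:
            out.append(ValidationIssue("error", name,
                                       "extraneous member"))
        if out:
            return out

        from .scene_model import (_check_annotation, _check_cells,
                                  _check_feature, _check_graph,
                                  _check_velocity)
        n = manifest.n_cells
        try:
            scatter = _load_member(zf, "scatter.json")
            if len(scatter) != n:
                raise PackageConsistencyError(
                    f"manifest promises {n} cells, scatter.json has "
                    f"{len(scatter)}")
            cells = CellTable(
                cell_ids=[str(r["i"]) for r in scatter],
                positions=np.asarray([r["p"] for r in scatter],
                                     dtype=float).reshape(len(scatter), 3))
            _check_cells(cells, out)
        except (PackageError, KeyError, TypeError, ValueError) as exc:
            out.append(ValidationIssue("error", "scatter.json", str(exc)))
        for e in manifest.annotation_index:
            member = f"annotations/{_member_name(e['key'])}.json"
            try:
                tr = _parse_annotation(e["key"], e["kind"],
                                       _load_member(zf, member), n)
                _check_annotation(tr, n, out)
            except PackageError as exc:
                out.append(ValidationIssue("error", member, str(exc)))
        for fid in manifest.feature_index:
            member = f"features/{_member_name(fid)}.json"
            try:
                tr = _parse_feature(fid, _load_member(zf, member), n)
                _check_feature(tr, n, out)  # checked then discarded
            except PackageError as exc:
                out.append(ValidationIssue("error", member, str(exc)))
        if manifest.has_graph:
            try:
                _check_graph(_parse_graph(_load_member(zf, "graph.json")),
                             out)
            except PackageError as exc:
                out.append(ValidationIssue("error", "graph.json", str(exc)))
        if manifest.has_velocity:
            try:
                _check_velocity(
                    _parse_velocity(_load_member(zf, "velocity.json"), n),
                    n, out)
            except PackageError as exc:
                out.append(ValidationIssue("error", "velocity.json",
                                           str(exc)))
    return out


def open_scene_package(path) -> ScenePackage:
    """Lightweight handle: archive path, member list, parsed manifest."""
    path = Path(path)
    try:
        zf = zipfile.ZipFile(path)
    except (OSError, zipfile.BadZipFile) as exc:
        raise PackageParseError(f"cannot open {path}: {exc}") from exc
    with zf:
        manifest = _parse_manifest(_load_member(zf, "index.json"))
        members = zf.namelist()
    return ScenePackage(path=path, members=members, manifest=manifest)
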