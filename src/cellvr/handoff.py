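"""Local handoff service: package registry, QR codes, shareable viewpoints.

A :class:`Registry` stores validated scene packages on disk under a root
directory, content-addressed by digest so duplicate uploads deduplicate.
:func:`make_handoff_qr` renders the phone-handoff URL
``<base_url>/view/<dataset_id>`` (optionally carrying a camera viewpoint as
a ``vp=`` query parameter) as a QR PNG.  Camera poses serialize to the
fixed-point string ``"x,y,z|yaw,pitch,roll"`` (2 decimals, angles wrapped
into (-180, 180]) so two viewers can navigate to the same point precisely.

The HTTP server is a minimal local tool (stdlib ``http.server``), not a
public website: no authentication, packages on local disk.
"""

from __future__ import annotations

import hashlib
import json
import re
import shutil
import urllib.parse
import zipfile
from dataclasses import dataclass
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Optional

from .errors import RegistryError
from .package_io import open_scene_package, validate_package
from .qr import qr_png
from .scene_model import CameraPose, wrap_angle

#: hex digest prefix length for content-addressed dataset ids
ID_LENGTH = 12

#: default per-package upload size limit (bytes)
MAX_PACKAGE_BYTES = 200 * 1024 * 1024


# ---------------------------------------------------------------------------
# viewpoints

def encode_viewpoint(pose: CameraPose) -> str:
    """Serialize a camera pose as ``"x,y,z|yaw,pitch,roll"`` (fixed-point,
    2 decimals; angles canonically wrapped before encoding)."""
    p = pose.canonical()
    return "{:.2f},{:.2f},{:.2f}|{:.2f},{:.2f},{:.2f}".format(
        p.x, p.y, p.z, p.yaw, p.pitch, p.roll)


_VP_RE = re.compile(r"^-?\d+(\.\d+)?$")


def decode_viewpoint(text: str) -> CameraPose:
    """Parse a viewpoint string; malformed tokens raise ``ValueError``
    naming the offending token."""
    parts = text.split("|")
    if len(parts) != 2:
        raise ValueError(f"viewpoint needs exactly one '|': {text!r}")
    tokens: list[float] = []
    for half in parts:
        fields = half.split(",")
        if len(fields) != 3:
            raise ValueError(f"expected 3 comma-separated values in "
                             f"{half!r}")
        for tok in fields:
            if not _VP_RE.match(tok.strip()):
                raise ValueError(f"bad viewpoint token {tok!r}")
            tokens.append(float(tok))
    x, y, z, yaw, pitch, roll = tokens
    return CameraPose(x, y, z, wrap_angle(yaw), wrap_angle(pitch),
                      wrap_angle(roll))


def view_url(base_url: str, dataset_id: str,
             pose: Optional[CameraPose] = None) -> str:
    """Phone-handoff URL for a dataset, with the pose as ``vp=`` query."""
    url = f"{base_url.rstrip('/')}/view/{dataset_id}"
    if pose is not None:
        url += "?vp=" + urllib.parse.quote(encode_viewpoint(pose), safe="")
    return url


# ---------------------------------------------------------------------------
# registry

@dataclass
class DatasetEntry:
    dataset_id: str
    name: str
    n_cells: int
    has_graph: bool
    has_velocity: bool
    path: Path


class Registry:
    """Content-addressed store of validated scene packages.

    The registry state is a pure function of the multiset of valid uploads:
    ids are digest prefixes, so re-uploading identical bytes is a no-op,
    and listing order (name, then id) is independent of upload order.
    """

    def __init__(self, root) -> None:
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)
        self._entries: dict[str, DatasetEntry] = {}
        for pkg in sorted(self.root.glob("*.zip")):
            try:
                self._add_entry(pkg.stem, pkg)
            except Exception:
                continue  # foreign file in the root; not a registry entry

    def _add_entry(self, dataset_id: str, path: Path) -> None:
        pkg = open_scene_package(path)
        self._entries[dataset_id] = DatasetEntry(
            dataset_id=dataset_id,
            name=pkg.manifest.name,
            n_cells=pkg.manifest.n_cells,
            has_graph=pkg.manifest.has_graph,
            has_velocity=pkg.manifest.has_velocity,
            path=path,
        )

    @staticmethod
    def dataset_id_for(data: bytes) -> str:
        return hashlib.sha256(data).hexdigest()[:ID_LENGTH]

    def register_dataset(self, package_path) -> str:
        """Validate and store a package; return its content-derived id.

        Rejects any package with an error-severity validation finding; the
        raised :class:`RegistryError` carries the report.
        """
        package_path = Path(package_path)
        report = validate_package(package_path)
        errors = [r for r in report if r.severity == "error"]
        if errors:
            exc = RegistryError(
                f"package rejected: {'; '.join(map(str, errors[:3]))}")
            exc.report = report
            raise exc
        data = package_path.read_bytes()
        if len(data) > MAX_PACKAGE_BYTES:
            raise RegistryError(
                f"package exceeds the {MAX_PACKAGE_BYTES} byte limit")
        dataset_id = self.dataset_id_for(data)
        dest = self.root / f"{dataset_id}.zip"
        if not dest.exists():
            shutil.copyfile(package_path, dest)
        if dataset_id not in self._entries:
            self._add_entry(dataset_id, dest)
        return dataset_id

    def list_datasets(self) -> list[dict]:
        """Registered datasets, ordered by (name, id)."""
        entries = sorted(self._entries.values(),
                         key=lambda e: (e.name, e.dataset_id))
        return [{"dataset_id": e.dataset_id, "name": e.name,
                 "n_cells": e.n_cells, "has_graph": e.has_graph,
                 "has_velocity": e.has_velocity} for e in entries]

    def get(self, dataset_id: str) -> DatasetEntry:
        if dataset_id not in self._entries:
            raise RegistryError(f"unknown dataset id {dataset_id!r}")
        return self._entries[dataset_id]

    def member_bytes(self, dataset_id: str, member: str) -> bytes:
        entry = self.get(dataset_id)
        with zipfile.ZipFile(entry.path) as zf:
            if member not in zf.namelist():
                raise RegistryError(f"no member {member!r} in "
                                    f"{dataset_id}")
            return zf.read(member)


def make_handoff_qr(registry: Registry, dataset_id: str, base_url: str,
                    pose: Optional[CameraPose] = None) -> bytes:
    """PNG QR code encoding the handoff URL for a registered dataset."""
    registry.get(dataset_id)  # raises for unknown ids
    return qr_png(view_url(base_url, dataset_id, pose))


# ---------------------------------------------------------------------------
# HTTP service

def _make_handler(registry: Registry, base_url: Optional[str]):
    class Handler(BaseHTTPRequestHandler):
        server_version = "cellvr"

        def log_message(self, fmt, *args):  # quiet by default
            pass

        def _send(self, status: int, content_type: str,
                  body: bytes) -> None:
            self.send_response(status)
            self.send_header("Content-Type", content_type)
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def _send_json(self, obj, status: int = 200) -> None:
            self._send(status, "application/json",
                       json.dumps(obj).encode("utf-8"))

        def do_GET(self) -> None:  # noqa: N802 (stdlib naming)
            parsed = urllib.parse.urlparse(self.path)
            parts = [p for p in parsed.path.split("/") if p]
            try:
                if parts == ["datasets"]:
                    self._send_json(registry.list_datasets())
                elif len(parts) == 3 and parts[0] == "data":
                    body = registry.member_bytes(parts[1], "/".join(
                        parts[2:]))
                    self._send(200, "application/json", body)
                elif (len(parts) == 2 and parts[0] == "qr"
                        and parts[1].endswith(".png")):
                    dataset_id = parts[1][:-4]
                    base = base_url or f"http://{self.headers.get('Host', 'localhost')}"
                    query = urllib.parse.parse_qs(parsed.query)
                    pose = None
                    if "vp" in query:
                        pose = decode_viewpoint(query["vp"][0])
                    png = make_handoff_qr(registry, dataset_id, base, pose)
                    self._send(200, "image/png", png)
                elif len(parts) == 2 and parts[0] == "view":
                    entry = registry.get(parts[1])
                    self._send_json({"dataset_id": entry.dataset_id,
                                     "name": entry.name,
                                     "n_cells": entry.n_cells})
                else:
                    self._send_json({"error": "not found"}, 404)
            except RegistryError as exc:
                self._send_json({"error": str(exc)}, 404)
            except ValueError as exc:
                self._send_json({"error": str(exc)}, 400)

        def do_POST(self) -> None:  # noqa: N802
            if self.path.rstrip("/") != "/upload":
                self._send_json({"error": "not found"}, 404)
                return
            length = int(self.headers.get("Content-Length", 0))
            if length > MAX_PACKAGE_BYTES:
                self._send_json({"error": "package too large"}, 413)
                return
            body = self.rfile.read(length)
            ctype = self.headers.get("Content-Type", "")
            if ctype.startswith("multipart/form-data"):
                try:
                    body = _extract_multipart_file(body, ctype)
                except ValueError as exc:
                    self._send_json({"error": str(exc)}, 400)
                    return
            tmp = registry.root / ".upload.tmp"
            tmp.write_bytes(body)
            try:
                dataset_id = registry.register_dataset(tmp)
            except RegistryError as exc:
                self._send_json({"error": str(exc)}, 400)
                return
            finally:
                tmp.unlink(missing_ok=True)
            self._send_json({"dataset_id": dataset_id})

    return Handler


def _extract_multipart_file(body: bytes, content_type: str) -> bytes:
    """First file part of a multipart/form-data body."""
    match = re.search(r'boundary="?([^";]+)"?', content_type)
    if not match:
        raise ValueError("multipart body without boundary")
    boundary = b"--" + match.group(1).encode()
    for part in body.split(boundary):
        if b"\r\n\r\n" not in part:
            continue
        head, _, payload = part.partition(b"\r\n\r\n")
        if b"filename=" in head:
            return payload.rstrip(b"\r\n-")
    raise ValueError("multipart body contains no file part")


def serve(root, host: str = "127.0.0.1", port: int = 8000,
          base_url: Optional[str] = None) -> ThreadingHTTPServer:
    """Create (but do not start) the handoff HTTP server.

    Call ``serve_forever()`` on the returned server, or ``handle_request``
    in tests.  ``base_url`` overrides the URL advertised inside QR codes
    (defaults to the request's Host header).
    """
    registry = Registry(root)
    server = ThreadingHTTPServer((host, port),
                                 _make_handler(registry, base_url))
    server.registry = registry
    return server
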