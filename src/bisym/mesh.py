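"""Core geometric types and triangle-mesh file I/O.

All coordinates are millimetres throughout the package; no unit
autodetection is attempted.  Meshes are plain vertex/face arrays with an
optional set of named per-vertex scalar fields (the heatmap carrier).

Supported formats: PLY (ascii and binary little-endian), STL (ascii and
binary), OBJ (geometry only).  Heatmaps are exported in one fixed PLY
dialect — binary little-endian, float64 positions, float32 per-vertex
properties — so outputs are byte-diffable across runs.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import numpy as np
import trimesh

from .errors import GeometryError, MeshFormatError, MeshIOError, ParameterError

log = logging.getLogger(__name__)

_FORMATS = ("ply", "stl", "obj")

# STL stores triangle soup; vertices closer than this are merged on read so
# face adjacency exists for downstream axis estimation.
STL_MERGE_TOL_MM = 1e-6


@dataclass
class TriangleMesh:
    """Triangle surface mesh: ``vertices`` (n, 3) mm, ``faces`` (m, 3) indices.

    ``scalar_fields`` maps field names (e.g. ``"distance_mm"``) to one real
    per vertex.
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalar_fields: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (m, 3) array")
        self.validate()

    def validate(self) -> None:
        if not np.isfinite(self.vertices).all():
            raise GeometryError("non-finite vertex coordinates")
        n = len(self.vertices)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= n):
            raise GeometryError("face index out of range")
        if len(self.faces):
            f = self.faces
            if ((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])).any():
                raise GeometryError("degenerate face repeats a vertex index")
        for name, fld in self.scalar_fields.items():
            fld = np.asarray(fld, dtype=np.float64)
            if fld.shape != (n,):
                raise GeometryError(
                    f"scalar field '{name}' has {fld.shape} entries, expected ({n},)"
                )
            self.scalar_fields[name] = fld

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            {k: v.copy() for k, v in self.scalar_fields.items()},
        )

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        cross = np.cross(self.vertices[self.faces[:, 1]] - a,
                         self.vertices[self.faces[:, 2]] - a)
        return 0.5 * np.linalg.norm(cross, axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals (unit length)."""
        return np.asarray(self.as_trimesh().vertex_normals, dtype=np.float64)


@dataclass
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=np.float64).reshape(3)
        self.normal = np.asarray(self.normal, dtype=np.float64).reshape(3)
        nrm = np.linalg.norm(self.normal)
        if abs(nrm - 1.0) > 1e-9:
            if nrm < 1e-12:
                raise GeometryError("plane normal has zero length")
            self.normal = self.normal / nrm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal


@dataclass
class RigidTransform:
    """Proper rigid motion p ↦ R p + t.

    The rotation is constrained to be orthonormal with det +1: a chirality
    change is the mirroring stage's job, never the registration's.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise GeometryError("rotation must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }


def _resolve_format(path: FilePath, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ParameterError(f"unsupported mesh format '{fmt}' (expected one of {_FORMATS})")
    return fmt


def _merge_close_vertices(vertices: np.ndarray, faces: np.ndarray,
                          tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (grid snap), preserving first-seen order."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    remap = rank[inverse]
    new_faces = remap[faces]
    keep = ~((new_faces[:, 0] == new_faces[:, 1])
             | (new_faces[:, 1] == new_faces[:, 2])
             | (new_faces[:, 0] == new_faces[:, 2]))
    return new_vertices, new_faces[keep]


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read a PLY/STL/OBJ surface into a :class:`TriangleMesh`.

    Vertex order is preserved from the file.  For STL, coincident vertices
    (within ``STL_MERGE_TOL_MM``) are merged so the triangle soup becomes a
    connected surface.  Per-vertex float PLY properties beyond x/y/z are
    loaded into ``scalar_fields``.
    """
    path = FilePath(path)
    fmt = _resolve_format(path, fmt)
    if not path.exists():
        raise MeshIOError(f"mesh file not found: {path}")
    try:
        loaded = trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - normalise all parser failures
        raise MeshIOError(f"could not read mesh file {path}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path} contains no mesh geometry")
        loaded = geoms[0]
    if not isinstance(loaded, trimesh.Trimesh) or loaded.faces is None or len(loaded.faces) == 0:
        raise MeshFormatError(f"{path} does not contain a triangle mesh")
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if fmt == "stl":
        vertices, faces = _merge_close_vertices(vertices, faces, STL_MERGE_TOL_MM)
    fields: dict[str, np.ndarray] = {}
    raw = loaded.metadata.get("_ply_raw") if hasattr(loaded, "metadata") else None
    if raw and "vertex" in raw:
        data = raw["vertex"]["data"]
        for name in raw["vertex"]["properties"]:
            if name in ("x", "y", "z"):
                continue
            try:
                col = np.asarray(data[name], dtype=np.float64).reshape(-1)
            except (ValueError, TypeError):
                continue
            if col.shape == (len(vertices),):
                fields[name] = col
    try:
        return TriangleMesh(vertices, faces, fields)
    except GeometryError as exc:
        raise MeshFormatError(f"{path}: {exc}") from exc


def _write_ply_binary(mesh: TriangleMesh, path: FilePath) -> None:
    """Fixed heatmap dialect: binary little-endian, float64 x/y/z, float32 fields."""
    names = sorted(mesh.scalar_fields)
    header = ["ply", "format binary_little_endian 1.0",
              f"element vertex {mesh.n_vertices}",
              "property double x", "property double y", "property double z"]
    header += [f"property float {n}" for n in names]
    header += [f"element face {mesh.n_faces}",
               "property list uchar int vertex_indices", "end_header"]
    vdtype = [("xyz", "<f8", (3,))] + [(n, "<f4") for n in names]
    varr = np.empty(mesh.n_vertices, dtype=vdtype)
    varr["xyz"] = mesh.vertices
    for n in names:
        varr[n] = mesh.scalar_fields[n].astype(np.float32)
    fdtype = [("count", "u1"), ("idx", "<i4", (3,))]
    farr = np.empty(mesh.n_faces, dtype=fdtype)
    farr["count"] = 3
    farr["idx"] = mesh.faces
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(varr.tobytes())
        fh.write(farr.tobytes())


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write ``mesh`` to ``path``; format by extension unless given.

    PLY carries any scalar fields as named per-vertex properties and
    round-trips geometry within 1e-6 mm (float64 positions).  STL and OBJ
    are geometry-only; a scalar field on those formats logs a warning and
    is dropped.
    """
    path = FilePath(path)
    fmt = _resolve_format(path, fmt)
    mesh.validate()
    try:
        if fmt == "ply":
            _write_ply_binary(mesh, path)
            return
        if mesh.scalar_fields:
            log.warning(
                "%s has no per-vertex attributes; dropping scalar fields %s for %s",
                fmt.upper(), sorted(mesh.scalar_fields), path)
        tm = mesh.as_trimesh()
        data = trimesh.exchange.stl.export_stl(tm) if fmt == "stl" else \
            trimesh.exchange.obj.export_obj(tm, include_normals=False)
        with open(path, "wb" if isinstance(data, bytes) else "w") as fh:
            fh.write(data)
    except OSError as exc:
        raise MeshIOError(f"could not write mesh file {path}: {exc}") from exc


def signed_volume(mesh: TriangleMesh) -> float:
    """Signed volume (mm³) by the divergence theorem over triangles.

    Positive for a closed mesh with outward winding; negates when the face
    winding or the spatial chirality flips, which makes it the chirality
    witness used by the mirroring tests.
    """
    a = mesh.vertices[mesh.faces[:, 0]]
    b = mesh.vertices[mesh.faces[:, 1]]
    c = mesh.vertices[mesh.faces[:, 2]]
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)
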