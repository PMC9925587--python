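"""Axial cropping of the proximal bone segment.

The region of interest is the band within a fixed depth (default 15 mm)
below the plateau, cut in an axial plane — a plane perpendicular to the
bone's long axis.  The long axis is estimated from the vertex covariance,
with the proximal sign picked by end thickness: the condylar (plateau) end
is wider than the shaft.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AmbiguityError, GeometryError, ParameterError
from .mesh import TriangleMesh

DEFAULT_CROP_DEPTH_MM = 15.0


@dataclass
class AxisEstimate:
    """Long-axis direction (unit vector, pointing proximally) and plateau level.

    ``plateau_level`` is the maximum vertex projection onto ``direction``;
    ``method`` records how the axis was obtained ("pca" or "user").
    """

    direction: np.ndarray
    plateau_level: float
    method: str = "pca"

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=np.float64).reshape(3)
        nrm = np.linalg.norm(self.direction)
        if abs(nrm - 1.0) > 1e-9:
            if nrm < 1e-12:
                raise GeometryError("axis direction has zero length")
            self.direction = self.direction / nrm
        self.plateau_level = float(self.plateau_level)

    def to_dict(self) -> dict:
        return {"direction": self.direction.tolist(),
                "plateau_level": self.plateau_level, "method": self.method}


def axis_from_direction(mesh: TriangleMesh, direction: np.ndarray) -> AxisEstimate:
    """User-supplied axis; the plateau level is still taken from the mesh."""
    d = np.asarray(direction, dtype=np.float64).reshape(3)
    d = d / np.linalg.norm(d)
    return AxisEstimate(d, float((mesh.vertices @ d).max()), method="user")


def estimate_axis(mesh: TriangleMesh,
                  proximal_hint: np.ndarray | None = None) -> AxisEstimate:
    """Estimate the proximal-pointing long axis of a bone mesh.

    The direction is the dominant principal axis of the vertex covariance.
    Its sign is chosen so that the widest end is proximal: the 10% of
    vertices with the largest projection must have a larger perpendicular
    RMS radius than the 10% with the smallest (condyles are wider than the
    shaft).  ``proximal_hint``, when given, overrides the sign.
    """
    if mesh.n_vertices < 3:
        raise GeometryError("need at least 3 vertices to estimate an axis")
    centred = mesh.vertices - mesh.vertices.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] < 1e-12 * max(evals[2], 1.0):
        raise GeometryError("vertex set is collinear")
    direction = evecs[:, 2]
    if proximal_hint is not None:
        hint = np.asarray(proximal_hint, dtype=np.float64).reshape(3)
        if abs(direction @ hint) < 1e-12:
            raise AmbiguityError("proximal hint is perpendicular to the axis")
        if direction @ hint < 0:
            direction = -direction
    else:
        if (evals[2] - evals[1]) / max(evals[2], 1e-300) < 0.01:
            raise AmbiguityError(
                "top two covariance eigenvalues within 1%: long axis is "
                "ambiguous; pass a proximal hint")
        proj = centred @ direction
        k = max(1, int(round(0.10 * len(proj))))
        order = np.argsort(proj)
        lo, hi = order[:k], order[-k:]
        perp = centred - np.outer(proj, direction)
        r2 = np.einsum("ij,ij->i", perp, perp)
        # wide condylar end is proximal
        if np.sqrt(r2[hi].mean()) < np.sqrt(r2[lo].mean()):
            direction = -direction
    return AxisEstimate(direction, float((mesh.vertices @ direction).max()),
                        method="pca")


def crop_below_plateau(mesh: TriangleMesh, axis: AxisEstimate,
                       depth: float = DEFAULT_CROP_DEPTH_MM,
                       return_vertex_map: bool = False):
    """Keep the faces lying entirely within ``depth`` mm below the plateau.

    A face is retained iff all three vertex projections onto the axis are
    ≥ plateau_level − depth; crossing faces are dropped, not split, leaving
    an open boundary at the cut.  Unreferenced vertices are removed and
    indices remapped.  With ``return_vertex_map`` the indices of the kept
    vertices in the input mesh are returned alongside.
    """
    if depth <= 0:
        raise ParameterError("crop depth must be positive")
    proj = mesh.vertices @ axis.direction
    level = axis.plateau_level
    vertex_ok = proj >= level - depth
    face_ok = vertex_ok[mesh.faces].all(axis=1)
    faces = mesh.faces[face_ok]
    if len(faces) == 0:
        raise GeometryError(
            f"crop at depth {depth} mm below level {level:.3f} removed every face")
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    cropped = TriangleMesh(
        mesh.vertices[used], remap[faces],
        {k: v[used] for k, v in mesh.scalar_fields.items()})
    if return_vertex_map:
        return cropped, used
    return cropped
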