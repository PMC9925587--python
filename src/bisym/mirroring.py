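"""Reflection of one side across a sagittal plane.

A left bone matches its contralateral right bone only after one reflection;
rigid registration cannot supply the chirality flip.  Because the later
registration absorbs any rigid difference between two candidate mirror
planes, the exact plane is immaterial to the final distances — only the
flip matters — so the default plane is a generic covariance-based
"side-to-side" plane through the centroid, with a user override.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import GeometryError
from .mesh import Plane, TriangleMesh

log = logging.getLogger(__name__)


def mirror_across_plane(mesh: TriangleMesh, plane: Plane,
                        repair_winding: bool = True) -> TriangleMesh:
    """Reflect every vertex across ``plane``.

    v ↦ v − 2·((v − p)·n)·n.  Reflection reverses chirality; with
    ``repair_winding`` (default) each face's vertex order is reversed so
    outward orientation — and hence the sign of the signed volume — is
    retained.
    """
    d = (mesh.vertices - plane.point) @ plane.normal
    vertices = mesh.vertices - 2.0 * d[:, None] * plane.normal
    faces = mesh.faces[:, ::-1].copy() if repair_winding else mesh.faces.copy()
    return TriangleMesh(vertices, faces,
                        {k: v.copy() for k, v in mesh.scalar_fields.items()})


def default_sagittal_plane(mesh: TriangleMesh) -> Plane:
    """Plane through the centroid, normal along the shortest principal axis.

    For a long bone the shortest covariance axis is a generic medial–lateral
    direction, which makes the plane sagittal-like.  Deterministic for fixed
    input; exact eigenvalue ties are broken by the symmetric eigensolver's
    fixed ordering (logged).
    """
    if mesh.n_vertices < 3:
        raise GeometryError("need at least 3 vertices to define a plane")
    centred = mesh.vertices - mesh.vertices.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    if evals[1] < 1e-12 * max(evals[2], 1.0):
        raise GeometryError("vertex set is collinear; sagittal plane undefined")
    if evals[2] > 0 and (evals[1] - evals[0]) / evals[2] < 1e-9:
        log.info("near-isotropic vertex cloud: sagittal normal tie broken by "
                 "eigensolver order")
    normal = evecs[:, 0]
    # fix an overall sign for determinism
    if normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    return Plane(mesh.vertices.mean(axis=0), normal)
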