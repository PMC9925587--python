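"""Correspondence points and Euclidean distance statistics.

After the two surfaces are superimposed, each point of the moving surface
is matched to its nearest counterpart on the fixed surface and the
Euclidean separation (mm) is the local asymmetry measure.  Two matching
modes exist: "vertex" (nearest fixed vertex — exact, with a brute-force
oracle) and "surface" (nearest point on any fixed triangle — the pipeline
default, more accurate between vertices).

Face-dropping at the axial cut leaves an open rim whose points have no
true counterpart and inflate distances; ``mask_cut_edge`` excludes a band
above the cut so statistics can be reported both raw and masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._geometry import nearest_on_surface
from .cropping import AxisEstimate
from .errors import ParameterError
from .mesh import TriangleMesh


@dataclass
class CorrespondenceSet:
    """Matched point pairs and their distances.

    ``source_indices[i]`` indexes the source point matched to
    ``target_points[i]``; ``distances[i]`` is their Euclidean separation in
    mm.  ``mask[i]`` is False where the pair is excluded as an artifact.
    """

    source_points: np.ndarray
    source_indices: np.ndarray
    target_points: np.ndarray
    distances: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.source_points = np.asarray(self.source_points, dtype=np.float64)
        self.source_indices = np.asarray(self.source_indices, dtype=np.int64)
        self.target_points = np.asarray(self.target_points, dtype=np.float64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.mask is None:
            self.mask = np.ones(len(self.distances), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.source_indices)
        if not (len(self.target_points) == len(self.distances) == len(self.mask) == n):
            raise ParameterError("correspondence arrays must have equal length")
        if (self.distances < 0).any():
            raise ParameterError("distances must be non-negative")

    def copy(self) -> "CorrespondenceSet":
        return CorrespondenceSet(self.source_points.copy(),
                                 self.source_indices.copy(),
                                 self.target_points.copy(),
                                 self.distances.copy(), self.mask.copy())


def nearest_correspondence(source_points: np.ndarray, target_mesh: TriangleMesh,
                           mode: str = "surface") -> CorrespondenceSet:
    """Match each source point to its nearest counterpart on the target.

    mode "vertex": nearest target vertex (KD-tree; identical distances to an
    exhaustive all-pairs scan).  mode "surface": nearest point on any target
    triangle via point-to-triangle projection.  All pairs start unmasked.
    """
    pts = np.atleast_2d(np.asarray(source_points, dtype=np.float64))
    if pts.size == 0:
        raise ParameterError("empty source point set")
    if target_mesh.n_vertices == 0:
        raise ParameterError("empty target mesh")
    if mode == "vertex":
        tree = cKDTree(target_mesh.vertices)
        dist, idx = tree.query(pts)
        matched = target_mesh.vertices[idx]
    elif mode == "surface":
        matched, dist = nearest_on_surface(pts, target_mesh.vertices,
                                           target_mesh.faces)
    else:
        raise ParameterError(f"unknown correspondence mode '{mode}'")
    return CorrespondenceSet(pts, np.arange(len(pts)), np.asarray(matched),
                             np.asarray(dist, dtype=np.float64))


def mask_cut_edge(cs: CorrespondenceSet, axis: AxisEstimate, cut_level: float,
                  band: float) -> CorrespondenceSet:
    """Mask points whose axial projection lies within ``band`` mm of the cut.

    ``cut_level`` is the projection of the cutting plane (plateau level −
    crop depth).  Band 0 leaves the mask unchanged.
    """
    if band < 0:
        raise ParameterError("mask band must be non-negative")
    out = cs.copy()
    if band == 0:
        return out
    proj = out.source_points @ axis.direction
    out.mask &= proj > cut_level + band
    return out


def mask_sphere(cs: CorrespondenceSet, center: np.ndarray,
                radius: float) -> CorrespondenceSet:
    """Mask points inside a user-supplied exclusion sphere (center mm, radius mm).

    Intended for known segmentation artifacts such as the tibiofibular
    joint region; no automatic joint detection is attempted.
    """
    if radius < 0:
        raise ParameterError("exclusion radius must be non-negative")
    out = cs.copy()
    c = np.asarray(center, dtype=np.float64).reshape(3)
    out.mask &= np.linalg.norm(out.source_points - c, axis=1) > radius
    return out


def subject_summary(cs: CorrespondenceSet, use_mask: bool = False) -> dict:
    """Distance statistics: n, mean, RMS, max (+ index), percentiles 50/75/95.

    The RMS is sqrt(mean of squared distances); mean ≤ RMS ≤ max always.
    With ``use_mask`` only unmasked pairs contribute.
    """
    sel = cs.mask if use_mask else np.ones(len(cs.distances), dtype=bool)
    if not sel.any():
        raise ParameterError("no points selected (all masked)")
    d = cs.distances[sel]
    idx = cs.source_indices[sel]
    arg = int(np.argmax(d))
    return {
        "n_points": int(len(d)),
        "mean_mm": float(d.mean()),
        "rms_mm": float(np.sqrt(np.mean(d**2))),
        "max_mm": float(d.max()),
        "max_source_index": int(idx[arg]),
        "percentiles_mm": {"p50": float(np.percentile(d, 50)),
                           "p75": float(np.percentile(d, 75)),
                           "p95": float(np.percentile(d, 95))},
    }


def heatmap_field(source_mesh: TriangleMesh, cs: CorrespondenceSet) -> TriangleMesh:
    """Attach per-vertex distances to the source mesh as field "distance_mm".

    Requires one correspondence per source vertex (the vertex-sourced
    pipeline default).  Masked points keep their distance; the companion
    field "mask" is 1 where the point counts and 0 where it is excluded.
    """
    if len(cs.distances) != source_mesh.n_vertices:
        raise ParameterError(
            f"{len(cs.distances)} distances for {source_mesh.n_vertices} vertices")
    out = source_mesh.copy()
    field_vals = np.empty(source_mesh.n_vertices)
    field_vals[cs.source_indices] = cs.distances
    mask_vals = np.zeros(source_mesh.n_vertices)
    mask_vals[cs.source_indices] = cs.mask.astype(float)
    out.scalar_fields["distance_mm"] = field_vals
    out.scalar_fields["mask"] = mask_vals
    return out
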