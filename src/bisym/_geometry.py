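"""Vectorised exact point-to-triangle distance with KD-tree pruning.

The closest point on a triangle to a query point is found by the standard
barycentric region classification (vertex / edge / face regions).  For a
whole mesh, candidate faces per query are pruned with a provably safe
radius: the nearest-vertex distance is an upper bound on the true
point-to-surface distance, so any face containing a closer point has its
centroid within that bound plus the largest centroid-to-vertex spread.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, a: np.ndarray, b: np.ndarray,
                               c: np.ndarray) -> np.ndarray:
    """Closest point on triangle (a, b, c) for each query; all inputs (n, 3)."""
    p = points
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 1.0 / 3.0)
        w = np.where(denom != 0, vc / denom, 1.0 / 3.0)
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def nearest_on_surface(points: np.ndarray, vertices: np.ndarray,
                       faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact nearest point on a triangle mesh for each query point.

    Returns (closest_points (n, 3), distances (n,)).
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    tri = vertices[faces]                     # (m, 3, 3)
    centroids = tri.mean(axis=1)
    spread = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()

    vtree = cKDTree(vertices)
    d_upper, _ = vtree.query(points)          # upper bound on surface distance
    ctree = cKDTree(centroids)
    # any face containing a point closer than d_upper has centroid within
    # d_upper + spread of the query (triangle inequality); small epsilon for
    # floating-point safety
    candidates = ctree.query_ball_point(points, d_upper + spread + 1e-9)

    counts = np.fromiter((len(c) for c in candidates), dtype=np.int64,
                         count=len(points))
    # every query has at least one candidate: its nearest vertex belongs to
    # some face whose centroid lies within `spread` of that vertex
    qidx = np.repeat(np.arange(len(points)), counts)
    fidx = np.concatenate([np.asarray(c, dtype=np.int64) for c in candidates])

    closest = closest_point_on_triangles(points[qidx], tri[fidx, 0],
                                         tri[fidx, 1], tri[fidx, 2])
    d2 = np.einsum("ij,ij->i", points[qidx] - closest, points[qidx] - closest)

    # per-query argmin: sort candidate rows by (query, distance), take the
    # first row of each query's block
    order = np.lexsort((d2, qidx))
    firsts = order[np.searchsorted(qidx[order], np.arange(len(points)),
                                   side="left")]
    return closest[firsts], np.sqrt(d2[firsts])
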