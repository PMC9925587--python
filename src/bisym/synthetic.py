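"""Synthetic bilateral proximal-tibia-like mesh pairs with known asymmetry.

The generator emulates the pipeline's input — left/right pairs of
proximal tibia surfaces that are near mirror images — without any
download: a parametric closed surface with a wide rounded-rectangular
plateau carrying two condylar elevations, a tapering shaft, and an
anteriorly offset tuberosity bump.  The condyle height difference plus
the off-centre tuberosity make the shape genuinely chiral, as real tibias
are: a true "right" can only be obtained from a "left" by reflection.

A pair is built as: right = generated shape; left = mirror of the right,
plus (a) optional localized patch deformations along the outward normal
with cosine falloff (standing in for true anatomical asymmetry), (b)
optional i.i.d. Gaussian vertex noise at CT-voxel-scale σ, and (c) an
arbitrary rigid perturbation (scanner pose).  Everything injected is
recorded in a ground-truth object against which recovery is tested.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .mesh import Plane, RigidTransform, TriangleMesh, signed_volume, write_mesh
from .mirroring import mirror_across_plane

# fixed shape constants not worth exposing as parameters
_TUBEROSITY_MAG_MM = 4.0
_DOME_HEIGHT_MM = 2.0


@dataclass
class TibiaShapeParams:
    """Shape parameters of the parametric proximal tibia (all lengths mm).

    ``mesh_resolution`` scales the grid density (≥ 2); ``condyle_heights``
    is (medial, lateral) — the medial condyle sits at +x on the generated
    right bone.
    """

    shaft_length: float = 80.0
    shaft_radius: float = 12.0
    plateau_width: float = 75.0
    plateau_depth: float = 50.0
    condyle_heights: tuple[float, float] = (5.0, 3.0)
    condyle_separation: float = 35.0
    tuberosity_offset: float = 8.0
    mesh_resolution: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("shaft_length", "shaft_radius", "plateau_width",
                     "plateau_depth", "condyle_separation"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if min(self.condyle_heights) <= 0:
            raise ParameterError("condyle heights must be positive")
        if self.mesh_resolution < 2:
            raise ParameterError("mesh_resolution must be >= 2")


@dataclass
class Patch:
    """One localized deformation: ``center`` is a 3D point in the left-mesh
    frame or a named preset ("medial_plateau", "lateral_plateau",
    "cut_edge"); displacement is ``magnitude_mm`` at the center falling
    off cosine-smoothly to zero at ``radius_mm``, along the outward vertex
    normal unless a fixed ``direction`` vector is given."""

    center: object
    radius_mm: float
    magnitude_mm: float
    direction: object = "normal"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ParameterError("patch radius must be positive")


@dataclass
class AsymmetrySpec:
    patches: list[Patch] = field(default_factory=list)
    global_scale_delta: float = 0.0
    noise_sigma: float = 0.0
    noise_on: str = "left"              # "left" | "both"
    rigid_perturbation: RigidTransform | None = None

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")
        if self.noise_on not in ("left", "both"):
            raise ParameterError("noise_on must be 'left' or 'both'")


@dataclass
class BilateralGroundTruth:
    """Record of the asymmetry actually injected into a pair."""

    spec: AsymmetrySpec
    patch_centers: list[np.ndarray]
    displacement_mm: np.ndarray         # per left vertex, ≥ 0, 0 outside patches
    rigid_perturbation: RigidTransform
    patches_overlap: bool = False

    def to_dict(self, subject_id: str = "") -> dict:
        return {
            "subject_id": subject_id,
            "patches": [
                {"center": c.tolist(), "radius_mm": p.radius_mm,
                 "magnitude_mm": p.magnitude_mm}
                for p, c in zip(self.spec.patches, self.patch_centers)
            ],
            "noise_sigma": self.spec.noise_sigma,
            "noise_on": self.spec.noise_on,
            "global_scale_delta": self.spec.global_scale_delta,
            "patches_overlap": self.patches_overlap,
            "rigid_perturbation": self.rigid_perturbation.to_dict(),
        }


def _superellipse_radius(theta, a, b, p):
    return (np.abs(np.cos(theta) / a) ** p + np.abs(np.sin(theta) / b) ** p) ** (-1.0 / p)


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def generate_tibia(params: TibiaShapeParams | None = None) -> TriangleMesh:
    """Build the closed, chiral, proximal-tibia-like surface.

    Deterministic for fixed parameters; outward winding (positive signed
    volume); the long axis is +z with the plateau at the top, so the
    proximal cross-sections are much wider than the distal shaft.
    """
    params = params or TibiaShapeParams()
    res = params.mesh_resolution
    ntheta, nz, ncap = 16 * res, 10 * res, 4 * res
    L = params.shaft_length
    a_p, b_p = params.plateau_width / 2.0, params.plateau_depth / 2.0
    r_s = params.shaft_radius
    h_med, h_lat = params.condyle_heights
    sep = params.condyle_separation
    sigma_c = sep / 3.0
    y_c = -0.15 * b_p                            # condyles sit slightly posterior
    theta_t = np.pi / 2.0 - params.tuberosity_offset / a_p

    theta = 2.0 * np.pi * np.arange(ntheta) / ntheta

    def cross_section(z):
        beta = _smoothstep((z - 0.55 * L) / (0.45 * L))
        a = r_s + beta * (a_p - r_s)
        b = r_s + beta * (b_p - r_s)
        p = 2.0 + 2.0 * beta
        rho = _superellipse_radius(theta, a, b, p)
        dth = np.angle(np.exp(1j * (theta - theta_t)))   # wrapped difference
        rho = rho + _TUBEROSITY_MAG_MM * beta * np.exp(
            -dth**2 / (2 * 0.5**2)) * np.exp(-(z - 0.78 * L) ** 2 / (2 * (0.10 * L) ** 2))
        return rho

    def condyle_height(x, y):
        d_med = (x - sep / 2.0) ** 2 + (y - y_c) ** 2
        d_lat = (x + sep / 2.0) ** 2 + (y - y_c) ** 2
        return (h_med * np.exp(-d_med / (2 * sigma_c**2))
                + h_lat * np.exp(-d_lat / (2 * sigma_c**2)))

    vertices: list[np.ndarray] = []
    # shaft/flare wall: nz rings of ntheta
    z_levels = L * np.arange(nz) / (nz - 1)
    for z in z_levels:
        rho = cross_section(z)
        ring = np.column_stack([rho * np.cos(theta), rho * np.sin(theta),
                                np.full(ntheta, z)])
        vertices.append(ring)
    wall = np.concatenate(vertices)

    def ring_index(iz, it):
        return iz * ntheta + it

    faces: list[tuple[int, int, int]] = []
    for iz in range(nz - 1):
        for it in range(ntheta):
            jt = (it + 1) % ntheta
            v00, v01 = ring_index(iz, it), ring_index(iz, jt)
            v10, v11 = ring_index(iz + 1, it), ring_index(iz + 1, jt)
            faces.append((v00, v01, v11))
            faces.append((v00, v11, v10))

    all_vertices = [wall]
    n_so_far = len(wall)

    # top cap: inner rings scaled from the top boundary, domed, with condyles
    rho_top = cross_section(L)
    boundary_top = np.arange(ring_index(nz - 1, 0), ring_index(nz - 1, 0) + ntheta)
    prev_ring = boundary_top
    for k in range(1, ncap):
        s = 1.0 - k / ncap
        x = s * rho_top * np.cos(theta)
        y = s * rho_top * np.sin(theta)
        z = L + (1.0 - s**2) * (_DOME_HEIGHT_MM + condyle_height(x, y))
        ring = np.column_stack([x, y, z])
        idx = n_so_far + np.arange(ntheta)
        all_vertices.append(ring)
        n_so_far += ntheta
        for it in range(ntheta):
            jt = (it + 1) % ntheta
            faces.append((prev_ring[it], prev_ring[jt], idx[jt]))
            faces.append((prev_ring[it], idx[jt], idx[it]))
        prev_ring = idx
    apex_top = n_so_far
    all_vertices.append(np.array([[0.0, 0.0,
                                   L + _DOME_HEIGHT_MM + condyle_height(0.0, 0.0)]]))
    n_so_far += 1
    for it in range(ntheta):
        jt = (it + 1) % ntheta
        faces.append((prev_ring[it], prev_ring[jt], apex_top))

    # bottom cap: flat rings at z = 0
    rho_bot = cross_section(0.0)
    boundary_bot = np.arange(ntheta)
    prev_ring = boundary_bot
    for k in range(1, ncap):
        s = 1.0 - k / ncap
        ring = np.column_stack([s * rho_bot * np.cos(theta),
                                s * rho_bot * np.sin(theta),
                                np.zeros(ntheta)])
        idx = n_so_far + np.arange(ntheta)
        all_vertices.append(ring)
        n_so_far += ntheta
        for it in range(ntheta):
            jt = (it + 1) % ntheta
            faces.append((prev_ring[jt], prev_ring[it], idx[it]))
            faces.append((prev_ring[jt], idx[it], idx[jt]))
        prev_ring = idx
    apex_bot = n_so_far
    all_vertices.append(np.array([[0.0, 0.0, 0.0]]))
    n_so_far += 1
    for it in range(ntheta):
        jt = (it + 1) % ntheta
        faces.append((prev_ring[jt], prev_ring[it], apex_bot))

    V = np.concatenate(all_vertices)
    if len(V) < 500:
        raise ParameterError(
            f"mesh_resolution {res} yields only {len(V)} vertices; too few to "
            "represent the condyles")
    mesh = TriangleMesh(V, np.asarray(faces, dtype=np.int64))
    if signed_volume(mesh) < 0:
        mesh = TriangleMesh(V, mesh.faces[:, ::-1])
    return mesh


_PRESET_HINTS = {
    # targets in the LEFT-mesh frame (mirror of the generated right: x negated)
    "medial_plateau": lambda p: np.array([-p.condyle_separation / 2.0,
                                          -0.25 * p.plateau_depth / 2.0,
                                          p.shaft_length]),
    "lateral_plateau": lambda p: np.array([p.condyle_separation / 2.0,
                                           -0.25 * p.plateau_depth / 2.0,
                                           p.shaft_length]),
    "cut_edge": lambda p: np.array([-p.shaft_radius, 0.0,
                                    p.shaft_length - 15.0]),
}


def _resolve_patch_center(patch: Patch, left: TriangleMesh,
                          params: TibiaShapeParams) -> np.ndarray:
    if isinstance(patch.center, str):
        if patch.center not in _PRESET_HINTS:
            raise ParameterError(f"unknown patch preset '{patch.center}'")
        target = _PRESET_HINTS[patch.center](params)
    else:
        target = np.asarray(patch.center, dtype=np.float64).reshape(3)
    idx = int(np.argmin(np.linalg.norm(left.vertices - target, axis=1)))
    return left.vertices[idx].copy()


def make_bilateral_pair(params: TibiaShapeParams | None = None,
                        spec: AsymmetrySpec | None = None,
                        seed: int = 0):
    """Generate (left, right, truth): a near-mirror bilateral pair.

    right = generated bone; left = its mirror image across the x = 0 plane
    (winding repaired), with the spec's patches, global scale change, vertex
    noise, and rigid perturbation applied, in that order.  The truth object
    records the resolved patch centers and the exact per-vertex displacement
    magnitudes before noise.
    """
    params = params or TibiaShapeParams()
    spec = spec or AsymmetrySpec()
    right = generate_tibia(params)
    left = mirror_across_plane(right, Plane(np.zeros(3), np.array([1.0, 0, 0])))

    displacement = np.zeros((left.n_vertices, 3))
    centers = []
    covered = np.zeros(left.n_vertices, dtype=int)
    normals = left.vertex_normals() if spec.patches else None
    for patch in spec.patches:
        c = _resolve_patch_center(patch, left, params)
        centers.append(c)
        d = np.linalg.norm(left.vertices - c, axis=1)
        inside = d < patch.radius_mm
        w = np.zeros(left.n_vertices)
        w[inside] = 0.5 * (1.0 + np.cos(np.pi * d[inside] / patch.radius_mm))
        if isinstance(patch.direction, str) and patch.direction == "normal":
            direction = normals
        else:
            v = np.asarray(patch.direction, dtype=np.float64).reshape(3)
            direction = np.broadcast_to(v / np.linalg.norm(v),
                                        (left.n_vertices, 3))
        displacement += patch.magnitude_mm * w[:, None] * direction
        covered += inside.astype(int)

    vertices = left.vertices + displacement
    if spec.global_scale_delta:
        cen = vertices.mean(axis=0)
        vertices = cen + (1.0 + spec.global_scale_delta) * (vertices - cen)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 22]))
    if spec.noise_sigma > 0:
        vertices = vertices + rng.normal(0.0, spec.noise_sigma, vertices.shape)
        if spec.noise_on == "both":
            right = TriangleMesh(
                right.vertices + rng.normal(0.0, spec.noise_sigma,
                                            right.vertices.shape),
                right.faces.copy())

    perturb = spec.rigid_perturbation or RigidTransform.identity()
    vertices = vertices @ perturb.rotation.T + perturb.translation
    left_out = TriangleMesh(vertices, left.faces.copy())

    truth = BilateralGroundTruth(
        spec=spec,
        patch_centers=centers,
        displacement_mm=np.linalg.norm(displacement, axis=1),
        rigid_perturbation=perturb,
        patches_overlap=bool((covered > 1).any()),
    )
    return left_out, right, truth


def random_rigid(rng: np.random.Generator, max_angle_deg: float = 30.0,
                 max_translation_mm: float = 20.0) -> RigidTransform:
    """Random proper rotation (axis uniform, angle ≤ max) + bounded translation."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform(R, t)


def default_params_sampler(rng: np.random.Generator,
                           base: TibiaShapeParams) -> TibiaShapeParams:
    """Per-subject anatomy jitter: ±3% multiplicative on every length."""
    j = lambda v: float(v * rng.uniform(0.97, 1.03))  # noqa: E731
    return replace(base,
                   shaft_length=j(base.shaft_length),
                   shaft_radius=j(base.shaft_radius),
                   plateau_width=j(base.plateau_width),
                   plateau_depth=j(base.plateau_depth),
                   condyle_heights=(j(base.condyle_heights[0]),
                                    j(base.condyle_heights[1])),
                   condyle_separation=j(base.condyle_separation),
                   tuberosity_offset=j(base.tuberosity_offset))


def make_cohort(n_subjects: int, outdir, master_seed: int = 0,
                base_params: TibiaShapeParams | None = None,
                base_spec: AsymmetrySpec | None = None,
                params_sampler=None, spec_sampler=None) -> Path:
    """Write ``n_subjects`` mesh pairs + manifest CSV + ground-truth JSON.

    Each subject's shape parameters are jittered by ``params_sampler``
    (default ±3%) and its left side perturbed by a random rigid motion
    unless the spec sampler provides one.  Fully reproducible from
    ``master_seed``; returns the manifest path.
    """
    if n_subjects < 1:
        raise ParameterError("need at least one subject")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base_params = base_params or TibiaShapeParams()
    base_spec = base_spec or AsymmetrySpec()
    params_sampler = params_sampler or default_params_sampler

    manifest_path = outdir / "manifest.csv"
    rows = []
    truths = []
    for i in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), 31, i]))
        subject = f"S{i + 1:03d}"
        params = params_sampler(rng, base_params)
        if spec_sampler is not None:
            spec = spec_sampler(rng, base_spec)
        else:
            spec = replace(base_spec, rigid_perturbation=(
                base_spec.rigid_perturbation or random_rigid(rng, 20.0, 15.0)))
        seed_i = int(rng.integers(0, 2**31))
        left, right, truth = make_bilateral_pair(params, spec, seed=seed_i)
        lp, rp = outdir / f"{subject}_left.ply", outdir / f"{subject}_right.ply"
        write_mesh(left, lp)
        write_mesh(right, rp)
        rows.append((subject, str(lp), str(rp)))
        truths.append(truth.to_dict(subject))

    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "left_path", "right_path"])
        writer.writerows(rows)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truths, fh, indent=2, sort_keys=True)
    return manifest_path
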