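"""Per-subject and cohort orchestration of the symmetry workflow.

Per subject: (1) mirror the moving side; (2) rigid CPD superimposition of
the mirrored surface onto the fixed side over the full bones; (3) long-axis
and plateau-level estimation on the fixed side; (4) axial crop of both
surfaces at the configured depth with the SAME axis and level, so the two
crops cover the same anatomical band; (5) a second CPD pass on the crops —
this re-registration prevents malposition driven by surface points outside
the region of interest; (6) nearest-point correspondence from the moving
crop's vertices to the fixed crop; (7) optional cut-edge/region masking;
(8) summary statistics and the per-vertex distance heatmap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, derive_seed
from .correspondence import (CorrespondenceSet, heatmap_field, mask_cut_edge,
                             mask_sphere, nearest_correspondence,
                             subject_summary)
from .cropping import AxisEstimate, axis_from_direction, crop_below_plateau, estimate_axis
from .errors import ParameterError, PipelineStageError
from .mesh import RigidTransform, TriangleMesh, write_mesh
from .mirroring import default_sagittal_plane, mirror_across_plane
from .registration import (apply_transform, cpd_rigid, pca_prealign,
                           subsample_points)

log = logging.getLogger(__name__)


@dataclass
class SubjectSymmetryReport:
    """Everything measured for one left/right pair.

    ``summary``/``summary_masked`` hold n, mean, RMS, max (mm) and
    percentiles; mean ≤ RMS ≤ max by construction.  The report embeds both
    registration transforms and the effective config, so a run is
    reproducible from its own report.
    """

    subject_id: str
    summary: dict
    summary_masked: dict | None
    max_location: list
    max_region: str | None
    transforms: dict
    axis: dict
    config_echo: dict
    warnings: list = field(default_factory=list)
    heatmap: TriangleMesh | None = None
    correspondences: CorrespondenceSet | None = None
    source_vertex_map: np.ndarray | None = None  # crop vertex -> original index

    @property
    def mean_mm(self) -> float:
        return self.summary["mean_mm"]

    @property
    def rms_mm(self) -> float:
        return self.summary["rms_mm"]

    @property
    def max_mm(self) -> float:
        return self.summary["max_mm"]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "version": __version__,
            "n_points": self.summary["n_points"],
            "mean_mm": self.summary["mean_mm"],
            "rms_mm": self.summary["rms_mm"],
            "max_mm": self.summary["max_mm"],
            "max_location": self.max_location,
            "max_region": self.max_region,
            "percentiles_mm": self.summary["percentiles_mm"],
            "masked": self.summary_masked,
            "transforms": self.transforms,
            "axis": self.axis,
            "config_echo": self.config_echo,
            "warnings": self.warnings,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_subject(left: TriangleMesh, right: TriangleMesh,
                config: RunConfig | None = None,
                subject_id: str = "subject") -> SubjectSymmetryReport:
    """Run the full mirror → register → crop → re-register → measure chain."""
    config = config or RunConfig()
    reg = config.registration
    warnings: list[str] = []

    moving, fixed = (left, right) if config.mirror_side == "left" else (right, left)

    @_stage("mirror")
    def _mirror():
        if config.mirror_plane is not None:
            p = np.asarray(config.mirror_plane, dtype=float).reshape(6)
            from .mesh import Plane
            return mirror_across_plane(moving, Plane(p[:3], p[3:]))
        return mirror_across_plane(moving, default_sagittal_plane(moving))

    mirrored = _mirror()

    n_sub = reg.subsample_n
    seed1 = derive_seed(config.seed, "subsample_pass1")

    @_stage("register_full")
    def _pass1():
        if n_sub == "all":
            src, tgt = mirrored.vertices, fixed.vertices
        else:
            src = subsample_points(mirrored, int(n_sub), seed1)
            tgt = subsample_points(fixed, int(n_sub), seed1)
        # deterministic coarse fit first: CPD's EM basin does not cover the
        # arbitrary relative pose of the two sides
        pre = pca_prealign(src, tgt)
        res = cpd_rigid(apply_transform(src, pre), tgt, reg)
        # fold the pre-alignment into the reported map: s·R·(R0 p + t0) + t
        res.transform = RigidTransform(
            res.transform.rotation @ pre.rotation,
            res.scale * res.transform.rotation @ pre.translation
            + res.transform.translation)
        return res

    res1 = _pass1()
    if not res1.converged:
        warnings.append("first registration pass hit max_iterations")
    aligned = apply_transform(mirrored, res1.transform, res1.scale)

    @_stage("estimate_axis")
    def _axis() -> AxisEstimate:
        if config.crop.axis_direction is not None:
            return axis_from_direction(fixed, np.asarray(config.crop.axis_direction,
                                                         dtype=float))
        return estimate_axis(fixed)

    axis = _axis()
    depth = config.crop.depth_mm
    cut_level = axis.plateau_level - depth

    @_stage("crop")
    def _crop():
        fixed_crop = crop_below_plateau(fixed, axis, depth)
        moving_crop, vmap = crop_below_plateau(aligned, axis, depth,
                                               return_vertex_map=True)
        return fixed_crop, moving_crop, vmap

    fixed_crop, moving_crop, vmap = _crop()

    seed2 = derive_seed(config.seed, "subsample_pass2")

    @_stage("register_crop")
    def _pass2():
        if n_sub == "all":
            src, tgt = moving_crop.vertices, fixed_crop.vertices
        else:
            n2 = min(int(n_sub), 4 * moving_crop.n_vertices)
            src = subsample_points(moving_crop, n2, seed2)
            tgt = subsample_points(fixed_crop, n2, seed2)
        return cpd_rigid(src, tgt, reg)

    res2 = _pass2()
    if not res2.converged:
        warnings.append("second registration pass hit max_iterations")
    moving_final = apply_transform(moving_crop, res2.transform, res2.scale)

    @_stage("correspondence")
    def _correspond():
        cs = nearest_correspondence(moving_final.vertices, fixed_crop,
                                    mode=config.correspondence.mode)
        cs = mask_cut_edge(cs, axis, cut_level, config.crop.mask_band_mm)
        for sphere in config.correspondence.exclusion_spheres:
            cs = mask_sphere(cs, np.asarray(sphere["center"], dtype=float),
                             float(sphere["radius"]))
        return cs

    cs = _correspond()

    @_stage("summary")
    def _summaries():
        raw = subject_summary(cs, use_mask=False)
        try:
            masked = subject_summary(cs, use_mask=True)
        except ParameterError:
            warnings.append("all correspondence points masked; masked summary "
                            "unavailable")
            return raw, None
        return raw, masked

    raw, masked = _summaries()
    heat = heatmap_field(moving_final, cs)

    max_idx = raw["max_source_index"]
    max_point = moving_final.vertices[max_idx]
    max_region = None
    for i, sphere in enumerate(config.correspondence.exclusion_spheres):
        c = np.asarray(sphere["center"], dtype=float)
        if np.linalg.norm(max_point - c) <= float(sphere["radius"]):
            max_region = sphere.get("label", f"exclusion_{i}")
            break

    return SubjectSymmetryReport(
        subject_id=subject_id,
        summary=raw,
        summary_masked=masked,
        max_location=max_point.tolist(),
        max_region=max_region,
        transforms={"pass1": {**res1.transform.to_dict(), "scale": res1.scale,
                              "sigma2": res1.final_variance,
                              "iterations": res1.iterations_used,
                              "converged": res1.converged},
                    "pass2": {**res2.transform.to_dict(), "scale": res2.scale,
                              "sigma2": res2.final_variance,
                              "iterations": res2.iterations_used,
                              "converged": res2.converged}},
        axis=axis.to_dict(),
        config_echo=config.to_dict(),
        warnings=warnings,
        heatmap=heat,
        correspondences=cs,
        source_vertex_map=vmap,
    )


@dataclass
class CohortSummary:
    """Cohort aggregate: per-subject means plus pooled boxplot statistics."""

    n_subjects: int
    per_subject: list          # [{subject_id, mean_mm, rms_mm, max_mm}]
    mean_of_means_mm: float
    sd_of_means_mm: float | None   # sample SD; None (reported "n/a") for n = 1
    sem_of_means_mm: float | None
    boxplot: dict
    failures: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "version": __version__,
            "n_subjects": self.n_subjects,
            "per_subject": self.per_subject,
            "mean_of_means_mm": self.mean_of_means_mm,
            "sd_of_means_mm": "n/a" if self.sd_of_means_mm is None
            else self.sd_of_means_mm,
            "sem_of_means_mm": "n/a" if self.sem_of_means_mm is None
            else self.sem_of_means_mm,
            "boxplot": self.boxplot,
            "failures": self.failures,
        }


def boxplot_stats(distances: np.ndarray) -> dict:
    """Tukey boxplot statistics: quartiles by linear interpolation, whiskers
    at the most extreme data within 1.5 × IQR of the box."""
    d = np.asarray(distances, dtype=np.float64)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = d[(d >= lo_fence) & (d <= hi_fence)]
    return {
        "convention": "tukey_1.5_iqr_linear_interpolation",
        "n": int(len(d)),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(((d < lo_fence) | (d > hi_fence)).sum()),
    }


def run_cohort(subjects, config: RunConfig | None = None,
               outdir=None) -> CohortSummary:
    """Run :func:`run_subject` for each (subject_id, left, right) entry.

    Entries may carry meshes or file paths.  Per-subject failures are
    logged and skipped, never silently dropped: they appear in
    ``failures``.  With ``outdir`` set, per-subject JSON reports, heatmap
    PLYs, the cohort JSON and a boxplot CSV are written there.
    """
    from .mesh import read_mesh  # local import to avoid cycle at module load

    config = config or RunConfig()
    subjects = list(subjects)
    if not subjects:
        raise ParameterError("cohort manifest is empty")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    per_subject = []
    pooled = []
    failures = []
    for subject_id, left, right in subjects:
        try:
            if not isinstance(left, TriangleMesh):
                left = read_mesh(left)
            if not isinstance(right, TriangleMesh):
                right = read_mesh(right)
            report = run_subject(left, right, config, subject_id=subject_id)
        except Exception as exc:  # noqa: BLE001 - skip-and-report policy
            log.error("subject %s failed: %s", subject_id, exc)
            failures.append({"subject_id": subject_id, "error": str(exc)})
            continue
        per_subject.append({"subject_id": subject_id,
                            "mean_mm": report.mean_mm,
                            "rms_mm": report.rms_mm,
                            "max_mm": report.max_mm,
                            "masked_mean_mm": (
                                report.summary_masked["mean_mm"]
                                if report.summary_masked else None)})
        pooled.append(report.correspondences.distances)
        if outdir is not None:
            (outdir / f"{subject_id}_report.json").write_text(report.to_json())
            write_mesh(report.heatmap, outdir / f"{subject_id}_heatmap.ply")

    if not per_subject:
        raise ParameterError("every subject failed; no cohort statistics")

    means = np.array([s["mean_mm"] for s in per_subject])
    n = len(means)
    sd = float(means.std(ddof=1)) if n > 1 else None
    summary = CohortSummary(
        n_subjects=n,
        per_subject=per_subject,
        mean_of_means_mm=float(means.mean()),
        sd_of_means_mm=sd,
        sem_of_means_mm=(sd / np.sqrt(n)) if sd is not None else None,
        boxplot=boxplot_stats(np.concatenate(pooled)),
        failures=failures,
    )
    if outdir is not None:
        (outdir / "cohort.json").write_text(
            json.dumps(summary.to_dict(), sort_keys=True, indent=2))
        with open(outdir / "boxplot.csv", "w") as fh:
            fh.write("stat,value\n")
            for k, v in summary.boxplot.items():
                fh.write(f"{k},{v}\n")
    return summary
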