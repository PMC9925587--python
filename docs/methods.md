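# Methods

## Problem and measurement model

The quantity of interest is the local shape difference between a bone and
the mirror image of its contralateral partner, expressed as per-point
Euclidean distances in millimetres on the proximal region of interest.
The measurement is *directed*: distances run from the mirrored (moving)
surface to the fixed surface.  The reverse direction is not symmetric in
general; both directed means are bounded by the symmetric Hausdorff
distance, and the directed choice is recorded in every report.

The pipeline assumes its inputs are closed-ish triangle meshes of the same
bone type in millimetres, with no unit autodetection.  It does not assume
any particular pose: chirality is handled by one explicit reflection, and
all remaining pose differences are absorbed by rigid registration.

## Mirroring

Reflection across a plane through the centroid with normal along the
*shortest* principal axis of the vertex covariance.  The exact plane is
immaterial — two reflections differ by a proper rigid motion, which the
registration estimates anyway — so no anatomical landmarking is required;
a user-supplied plane override exists (`mirror_plane`, six numbers).
Reflected faces have their vertex order reversed by default so outward
orientation survives (the signed-volume sign is the invariant the tests
use).  By default the left side is mirrored onto the right; `--mirror`
flips this.

## Rigid Coherent Point Drift

The moving sample is a Gaussian mixture (one component per point, shared
isotropic σ²) with a uniform outlier component of weight `w`; the fixed
sample is the data.  EM alternates posterior correspondence probabilities
with closed-form rigid updates.  Numerical choices:

- **Objective**: the negative log-likelihood of the mixture, recorded per
  E-step.  With exact M-steps it is non-increasing; the test suite asserts
  this at 1e-9 relative slack on every iteration.
- **σ² update**: the exact posterior-weighted residual
  (x̄² − 2s·tr(AᵀR) + s²·ȳ²)/(3N_P).  The familiar shortcut
  x̄² − s·tr(AᵀR) is only valid when s is the fitted scale; using it with
  s fixed at 1 biases σ² and can break monotonicity.
- **Variance annealing**: σ² may decrease by at most a factor of 10 per
  iteration.  On exactly matching sets the unrestricted update collapses
  σ² in one step while correspondences are still soft, freezing the
  transform several decades short of machine precision; the clamped value
  lies between the per-iteration optimum and the previous σ², i.e. on the
  increasing side of the EM Q-function, so monotonicity is preserved.
  Below 1e-12 mm² the run is declared converged.
- **Convergence**: relative objective change below `tolerance`
  (default 1e-8), capped at `max_iterations` (default 150, warning when
  hit — common and harmless in the noisy regime).
- **Rotation**: SVD of the posterior-weighted cross-covariance, projected
  to det +1.  Registration never supplies a reflection; a dedicated test
  registers a bone onto its own un-repaired mirror image and asserts the
  residual stays large.
- **Outlier density**: uniform over the data bounding box (a fixed value;
  any fixed choice preserves the EM guarantee).  Default `w` = 0.1 as mild
  protection against segmentation artifacts; scale estimation is off by
  default because a similarity fit between two bones of one subject could
  absorb genuine size asymmetry.
- **Pre-alignment**: plain CPD-EM has a limited rotational basin (in
  particular it cannot cross the ~180° ambiguity created by mirroring
  across a non-anatomical plane).  The pipeline therefore precedes the
  first pass with a deterministic principal-axes alignment whose four
  proper axis-sign combinations are scored by mean nearest-neighbour
  distance; the EM refines the winner.  The second (cropped) pass starts
  from the already-aligned pose.

Registration operates on `subsample_n` = 2000 points per surface by
default (tests and the acceptance script use 600–800, which this geometry
comfortably supports), sampled uniformly by *face area*.  Faces are
canonicalised (sorted vertex indices) before drawing barycentric
coordinates, so mirror/rigid copies of one mesh yield corresponding
samples under the same seed — this makes the noise-free null pipeline
exact to machine precision rather than limited by sampling density.

## Axis estimation and cropping

The long axis is the dominant covariance eigenvector; the proximal sign
is chosen by end thickness (the condylar end has the larger perpendicular
RMS radius over the outer 10 % of vertices), with an explicit hint
override and an ambiguity error when the top two eigenvalues are within
1 %.  The plateau level is the maximal vertex projection of the *fixed*
surface, and both surfaces are cropped with that same axis and level so
the two crops cover the same anatomical band.  The default depth is
15 mm.  Faces crossing the cut plane are dropped, not split — the cut rim
is therefore open and slightly ragged, which is exactly why rim points
are maskable downstream rather than hidden by remeshing.  Containment
(all retained projections within [level − depth, level]) and idempotence
are exact and tested.

## Correspondence and statistics

Default mode matches each moving-crop vertex to the nearest point on any
fixed-crop triangle (exact point-to-triangle projection; candidates are
pruned with a KD-tree using the nearest-vertex distance plus the largest
face circumradius as a provably safe search radius).  "Vertex" mode
(nearest fixed vertex) is retained as the testing workhorse because its
brute-force O(N²) oracle is exact.  Reports carry mean, RMS and max —
mean ≤ RMS ≤ max always — plus 50/75/95 percentiles, in raw and masked
variants.  The mask excludes a band (default 2 mm) above the cut level,
where rim points have no true counterpart, and optional user-supplied
exclusion spheres (e.g. a known tibiofibular segmentation artifact); no
automatic artifact detection is attempted.

## Synthetic bilateral pairs

The generator emulates the pipeline's input without any data download: a
closed parametric proximal-tibia-like surface (superellipse cross-section
blending from a circular shaft into a wide rounded-rectangular plateau,
two posteriorly shifted condylar elevations of unequal height, an
anteriorly offset tuberosity bump).  The height inequality plus the
off-centre bump make the shape genuinely chiral, as real tibias are — a
test registers the bone onto its own mirror and requires a ≥ 10× residual
versus self-registration.  Default dimensions are adult-scale: 80 mm
segment length, 75 × 50 mm plateau, 12 mm shaft radius, condyles 5/3 mm,
≈ 2500 vertices at resolution 3.

A pair is: right = generated bone; left = its mirror, plus

- **patches** — localized outward-normal displacement with cosine falloff
  to zero at the patch radius (smooth, so it cannot be confused with
  cut-edge discontinuities); defaults in tests use 1.6 mm magnitude and
  8 mm radius on the posterior medial plateau;
- **global scale delta** — optional fractional size difference;
- **vertex noise** — i.i.d. Gaussian per coordinate at CT-voxel-scale σ
  (0.1–0.4 mm is the realistic range; applied to the left only, or to
  both sides with `noise_on="both"`);
- **rigid perturbation** — an arbitrary pose difference standing in for
  scanner positioning.

Ground truth records resolved patch centres, the exact per-vertex
displacement magnitudes before noise, and the perturbation.  What the
generator does **not** emulate: real anatomical shape variation beyond
±3 % parameter jitter, CT partial-volume and segmentation artifacts
(noise is i.i.d., not spatially correlated), and open or defective
meshes.  Passing tests therefore demonstrate correctness of the
geometric machinery under known asymmetry, not clinical performance on
real segmentations.

## Validation design

Every stage has an independent oracle: reflection is an involution;
CPD is checked against constructed ground-truth transforms, against a
coarse exhaustive grid search on small instances, and by the EM
monotonicity guarantee; vertex-mode matching against the exhaustive scan;
surface mode against a brute-force scan over all triangles; the cohort
noise floor against a Monte-Carlo simulation of two independently noisy
triangulated planes at the same σ and the same mean edge length as the
cropped bone (run with a separately implemented point-triangle distance).
The noise-floor comparison uses the cut-edge-masked cohort mean, since
the interior-only oracle has no rim.  `scripts/acceptance.py` recomputes
all of these quantities from scratch from a single seed; test runs use
10–20 seeded trials and 600-point registration samples, sizes this
geometry supports well.

## Known limitations

- The CPD cost is the dense O(M·N) formulation; fine for the few-thousand
  point samples used here, not for raw 100k-vertex segmentations (crop or
  subsample first).
- The covariance-based sagittal plane and PCA long axis are generic
  heuristics, not anatomical coordinate systems; pathological or heavily
  truncated bones may need the explicit axis/plane overrides.
- Faces are dropped, not split, at the cut plane, so the measured band is
  up to one edge length short of exactly 15 mm.
- The ±0.0343 mm style cohort dispersion is reported as sample SD *and*
  SEM with n, because either convention may be wanted downstream.
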