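# Methods

`erupt3d` measures how a maxillary canine has moved between two CBCT scans
of the same patient: a pre-operative baseline and a follow-up. The output
is six numbers per tooth — three translations (mesial/distal,
palatal/facial, incisal/apical, in mm) and three rotations (pitch, roll,
yaw, in degrees) — plus the segmented tooth volumes and a
registration-error summary. This note records the model, the conventions,
the numerical choices, and what the synthetic validation does and does not
show.

## Measurement model

The tooth is treated as a rigid body. Its apparent motion between two scans
is the composition of two rigid motions: the patient's head repositioning
between acquisitions (global) and the biological movement of the tooth
relative to the maxilla (local, the quantity of interest). The pipeline
separates them in two registration steps:

1. **Stable-region voxel registration.** The follow-up volume is rigidly
   aligned onto the baseline by maximizing mutual information computed only
   inside a region of interest restricted to bone that surgery and eruption
   do not alter (clinically: the maxilla cropped above the root apices,
   below the infraorbital rim, between the zygomatic processes). Because
   the moving tooth is excluded from the ROI, the recovered transform is
   the head repositioning alone. The follow-up volume is then resampled
   into baseline space, cancelling the global motion.
2. **Tooth surface registration.** The tooth is segmented in both scans;
   trimmed point-to-surface ICP maps the baseline tooth surface onto the
   (already globally aligned) follow-up surface. The resulting rigid
   transform is the local tooth motion.

One ordering detail matters for accuracy: the automated path segments the
tooth **in the native follow-up scan** and carries the mesh through the
registration transform (a rigid map, applied to vertices exactly), rather
than thresholding the resampled volume. Thresholding after trilinear
resampling blurs the edge and grid-locks the marching-cubes staircase
toward the baseline grid axes, which twists the weakly constrained yaw
mode by more than a degree on phantom tests; segmenting natively removes
that bias entirely. The resampled volume is still produced — the
part-comparison QC and any visual overlay use it. The interactive
contour-driven path segments the registered volume, because that is the
image an operator actually draws on.

### Decomposition into clinical components

A rigid transform `T = (R, t)` is reported in an anatomical frame `A`
whose rows are the mesiodistal (M/D), palatofacial (P/F) and incisoapical
(I/A) unit axes (per case from three operator landmarks — incisal tip,
mesial and facial crown points, Gram–Schmidt orthonormalized — or the scan
axes for phantoms):

* translations: the displacement of the pre-operative tooth centroid,
  `A (T(c) − c)`, so the reported translation does not depend on the
  rotation's lever arm; signs + mesial, + facial, + incisal;
* rotations: `R' = A R Aᵀ` read as **extrinsic Euler angles in the fixed
  order pitch (about M/D) → roll (about P/F) → yaw (about I/A)**, positive
  counter-clockwise. Euler orders do not commute; the order is embedded in
  every report. Roll within 0.5° of ±90° sets a gimbal-degeneracy flag.
* side convention: a right-side tooth is the sagittal mirror of a
  left-side one, so the three mirror-antisymmetric components (dMD, roll,
  yaw) change sign when `side == "right"`. Mirroring a scene and flipping
  the flag is then an exact no-op for all six components.

`compose`/`decompose` are exact inverses (round-trip to 1e-9 away from the
gimbal band), which the tests exercise on 1000 random transforms and on a
worked example with magnitudes typical of a 6-month eruption
(1.4/1.4/2.4 mm, 4.5/6.3/6.0°).

## Module-level choices

### Mutual-information registration

The similarity is Shannon MI in bits from a 64×64 joint histogram: fixed
intensities binned directly at the masked voxel centres, moving intensities
sampled there through the current transform with trilinear interpolation
(out-of-field samples dropped; an error is raised below 10% overlap).
Optimization is Powell's method over translation plus a rotation vector
(scaled by the ROI half-diagonal so all six parameters are in
mm-equivalent units, avoiding Euler singularities), through a 3-level
pyramid (block-mean shrink 4/2/1). Each level is Gaussian-presmoothed
(σ = 1 voxel) — this suppresses intensity noise and trilinear-interpolation
artifacts in the MI landscape without moving edge locations, and is the
single change that most improved run-to-run reproducibility of the
optimum. Initialization is the identity: consecutive scans of one patient
are coarsely aligned.

Sampling is exhaustive and deterministic at the coarsest level; the
pipeline's default uses seeded random subsampling (50% / 30%) at the finer
levels, which leaves the alignment deterministic for a given seed while
cutting cost several-fold. Fully exhaustive sampling remains the library
default for `RegistrationParams` and is available everywhere.

Before hill-climbing at the coarsest level, an exhaustive translation scan
(±2.4 mm in 0.6 mm steps, rotation held at the initialization) picks the
best MI basin. Textured bone gives the MI landscape periodic side lobes,
and a poor initialization can otherwise strand a local optimizer in one;
the scan costs a fraction of a second at 4× shrink and makes the
registration robust to initializations several mm off.

### Segmentation

The interactive path mirrors a livewire workflow: per-pixel local costs
(Mortensen–Barrett weights 0.43 gradient, 0.43 Laplacian zero-crossing,
0.14 gradient-direction smoothness), Dijkstra minimum-cost paths between
anchor points (8-connected, diagonal steps ×√2), contours chained and
closed per slice. Axial contours are fused by shape-based interpolation:
each contour becomes a signed distance field on its slice, fields are
linearly interpolated along the slice axis, and the zero sublevel set is
the segmentation. Coronal/sagittal contours act as carving constraints on
their planes (foreground must lie inside every covering contour) rather
than entering a full 3-D variational fusion — a declared simplification
that keeps the multi-view idea testable. Surfacing is marching cubes at
the 0.5 level of the binary mask; the largest connected component is kept.

For unattended phantom runs an intensity-band threshold replaces the
interactive step.

### ICP

Trimmed point-to-surface ICP: up to 2000 seeded source vertices, exact
nearest points on the target triangles (a KD-tree-pruned query that is
bit-identical to an all-triangles scan), worst 10% of residuals discarded,
rigid update by the Kabsch/SVD closed form, convergence when an update
moves no source point by more than 1e-4 mm. Two additions matter on
voxelized surfaces:

* both meshes are Taubin-smoothed (10 iterations) before ICP. The
  staircase pattern of binary marching cubes otherwise makes the surfaces
  interlock and converge by slow tangential creep; the smoothing is
  volume-preserving to first order and applied identically to both sides,
  so it does not bias the recovered motion. Volumes and the centroid are
  always measured on the raw meshes.
* a geometric-series extrapolation of the update sequence: when successive
  incremental updates stay aligned (cosine > 0.9) and shrink by a steady
  ratio r, the remaining tail is applied at once (gain r/(1−r), capped at
  20). This cuts the slow rotational sliding mode from hundreds of
  iterations to tens without changing the fixed point.

### Registration validation (part comparison)

Both ROI volumes are thresholded, surfaced, and the unsigned distance from
every vertex of the baseline surface to the follow-up surface (true
point-to-triangle) is summarized as MAD ± SD. Declared conventions: the
map is directed pre → post (a symmetric average is an option), and the SD
uses the population (n) denominator.

### Reliability statistics

ICC form is fixed to **ICC(2,1)** — two-way random effects, absolute
agreement, single rater — computed from the two-way ANOVA mean squares
with the F-based 95% CI (Satterthwaite denominator df). Agreement, not
consistency, is the right target when two observers measure the same
physical quantity; the form is printed in every report. The Wilcoxon
signed-rank test drops zero differences, uses average ranks for ties, and
is exact (full sign-pattern enumeration via subset-sum convolution) up to
n = 25, with a tie- and continuity-corrected normal approximation above.
No multiple-testing correction is applied across the per-component
comparisons; reports say so.

## The phantom generator

Patient CBCT data cannot ship with a software artifact, so validation runs
on synthetic pairs with known ground truth. One scene is a bone-like block
(intensity 600) containing a canine-like tooth (intensity 1800) on an air
background (0), voxelized at 0.2 mm (clinical cleft protocols use
0.15–0.2 mm) on a 112×112×150 grid (22.4×22.4×30 mm field of view around
the tooth).

* **Tooth analog**: a superellipsoid crown (exponent 2.6, height 4.6 mm)
  fused to a linearly tapered root (8.5 mm), sharing a dimensionless width
  profile S(z); the cross-section is an ellipse with semi-axes 4.6 mm
  (mesiodistal) × 3.6 mm (palatofacial). The elliptical section is not
  cosmetic: canine crowns are mesiodistally wider than they are thick, and
  for an axisymmetric analog a rotation about the long axis (yaw) would be
  invisible to any surface registration. The solid volume has the closed
  form `π a b ∫ S(z)² dz` (evaluated by dense quadrature), ~387 mm³ at
  defaults — inside the 300–600 mm³ range of reported canine volumes — and
  serves as the oracle for segmentation and meshing accuracy.
* **Voxelization** is by voxel-centre inclusion against the analytic
  implicit function, so voxel counts can be compared with the analytic
  volume exactly.
* **Bone texture**: a case-seeded sum of six 3-D sinusoids (wavelengths
  2.5–6 mm, amplitude ±150) rides on the bone intensity and moves rigidly
  with the scene. A homogeneous block would give mutual information no
  in-plane gradient inside the stable slab; the texture is what makes the
  registration problem well-posed, standing in for trabecular structure.
* **Motions**: the local tooth motion is drawn uniformly within ±3 mm per
  axis and ±8° per Euler axis about the tooth centroid — bracketing
  reported 6-month eruption magnitudes (means ≤ 1.5 mm, ≤ 5°) with margin —
  and the global head repositioning within ±1.5 mm / ±3° about the
  field-of-view centre. Additive Gaussian noise (SD 30 = 5% of bone) is
  drawn independently per scan. Everything derives from one integer seed;
  a fixed seed reproduces a pair bit-identically.
* The stable ROI is a 3.6 mm slab of bone below the tooth's reachable
  excursion, the phantom analog of the clinical crop.

**What the phantom does not emulate**: cleft anatomy, neighbouring teeth,
beam hardening, scatter, metal artifacts, scanner-dependent noise spectra,
non-rigid tooth change (root resorption). Passing phantom tests therefore
demonstrates the correctness of the measurement chain given
CBCT-like contrast and noise, not robustness to every clinical artifact.

## Observer emulation

The clinical validation of such a method uses two human observers
repeating the workflow. A software artifact replaces them with seeded
"observer emulation" runs: each run perturbs the registration
initialization (uniform ±0.5 mm, ±0.5°) and shifts the segmentation
threshold (uniform ±150 intensity units ≈ ±¼ of the bone–tooth contrast,
which moves the extracted surface by roughly half a voxel — the analog of
anchor-placement variation in interactive contouring). The software
settings themselves, including the seeded MI sampling, are shared between
the runs of a case, exactly as they are for two humans operating the same
tool. The reliability harness runs the full pipeline twice per case and
reports, per measure family, ICC(2,1) with 95% CI and the between-run
MAD ± SD, in the layout of an inter-observer study. All perturbation
magnitudes are configurable and recorded in the report.

## Problem sizes and numerical settings

The shipped validation suite uses 20 phantom pairs for transform recovery
and 10 pairs × 2 emulation runs for the reliability re-enactment; these
sizes give stable summary statistics for a desk-scale study while keeping
a full run in the minutes range. Key tolerances: registration Powell xtol
5e-4 mm (finest level), ICP update tolerance 1e-4 mm, mesh welding 1e-6 mm,
rigid-transform invariants 1e-8, decompose/compose round-trip 1e-9.
Degenerate inputs are errors, not silent results: empty masks, open meshes
(reported with their boundary-edge count), all-zero difference sets,
zero-variance rating tables, insufficient volume overlap, reflections
posing as rigid transforms.

## Known limitations

* Rigid-body assumption: real teeth can resorb; volume change is reported
  but not modelled as shape change.
* The Euler order and the centroid-based translation are conventions;
  numbers are comparable only between reports using the same conventions
  (they are embedded in the output metadata for this reason).
* Exhaustive-sampling MI registration is several-fold slower than the
  pipeline's seeded subsampling default; both are deterministic given the
  seed, but results differ at the ~0.01 mm level between the two settings.
* The livewire direction term uses a per-pixel neighbourhood-mean gradient
  direction rather than the original per-link formulation, so path costs
  are attached to pixels, not edges.
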