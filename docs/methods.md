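# Methods

This note records the models and procedures `deformgen` implements, the
defaults it ships with and why, what the synthetic phantoms do and do not
emulate, and the numerical choices a maintainer would want to know about.

## Deformation representation

All grids are axis-aligned; the world coordinate of voxel index i is
`origin + i·spacing` (mm), with array axes ordered (LR, AP, SI). A
deformation vector field (DVF) stores per-voxel displacements in
millimetres — not voxels, because clinical CT spacing is anisotropic.
Warping follows the pull-back convention: the warped image at x is the
moving image sampled at x + d(x), so the DVF produced by registering image
t to a reference lives on the reference grid. Out-of-grid samples take
−1000 HU (air) for CT-like volumes and 0 for masks; DVF algebra
(inversion, composition, transfer) clamps to the nearest edge value
instead, to avoid fabricating boundary vectors.

Vectorization order is frozen and written into every persisted model:
component-major (all LR, then AP, then SI), each block in index order with
the first axis fastest. Training DVFs are vectorized jointly (one long
column per DVF), not per-direction.

## Active shape model of deformation

Given N vectorized DVFs, the model is the mean deformation plus the
leading eigenpairs of the sample covariance (denominator N−1). The
covariance of a 64×64×48 field has (3·196 608)² entries and is never
materialized; eigenpairs come from the N×N Gram matrix of the centred
columns, whose positive eigenvalues coincide with the covariance's and
whose eigenvectors map through the data matrix. Correctness is pinned by a
test that materializes the dense covariance on 6×6×6 grids and demands
1e−8 agreement.

Numerical choices:

- eigenvalues below 1e−12·λ(1) are treated as exact zeros (numerical rank
  of an N-sample Gram matrix);
- eigenvector sign is fixed by making the largest-magnitude entry
  positive, so fits are reproducible across linear-algebra backends;
- the retained count T̂ is the smallest prefix reaching α percent of the
  total variance; an exact-boundary cumulative sum counts as reached
  (tolerance 1e−12 of the total).

Sampling draws b_j ~ N(0, λ(j)) over the T̂ retained modes and redraws the
whole vector while the Mahalanobis distance √(Σ b²/λ) exceeds D_max —
rejection rather than clipping or rescaling, because it preserves the
Gaussian shape inside the ball. After 1 000 consecutive rejections (only
plausible for D_max far below typical draws) a single radial rescale onto
the ball is applied instead, so pathological configurations terminate.
D_max = 0 returns the mean. All sampling is reproducible from a seed.

## Demons registration

The training DVFs come from a multi-resolution symmetric-force demons
solver (forces from both the fixed and the warped-moving gradients), the
demons family member closest to published dual-force schemes; the force
term is isolated in one function so alternatives can be swapped in. The
per-iteration update is

  u = (f − m̃)(∇f + ∇m̃) / (‖∇f + ∇m̃‖² + κ²(f − m̃)²),

smoothed by `sigma_update` (fluid), capped at `step_cap` mm, added to the
field, which is then smoothed by `sigma_field` (diffusion). The sign is
chosen so that the update reduces the residual under the pull-back
convention (a force pointing up the combined gradient when the warped
moving image is too dark).

Defaults, selected for stable convergence on the phantom suite: 3 pyramid
levels (×4, ×2, ×1) with (80, 60, 40) iterations, σ_update = σ_field =
2 mm, step cap 2 mm, κ = 1/mean(spacing) — the usual demons normalisation
balancing the intensity term against the gradient term; with κ tied to
image gradients instead, CT-scale intensity differences (~10³ HU) crush
every update and the solver stalls. Intensities are clamped to
[−1000, 2000] HU first, limiting metal-artifact-like outliers. Forces are
zeroed where **both** images are below −900 HU: pure air carries only
noise, which the solver would otherwise chase into spurious training-DVF
variance. Everything is deterministic — two runs are bit-identical — and
the solver records the full-resolution mean squared intensity difference
after each level, which the tests require to be non-increasing.

Measured on the default phantoms: registering an image to itself leaves
< 0.05 voxel mean displacement; a 2-voxel translation under 15 HU noise is
recovered to 0.41 voxel mean error in the anatomy; a 4 mm smooth
deformation to 0.25 voxel. Accuracy is texture-limited: in regions whose
intensity structure is weaker than the noise, demons under-recovers
(a damping of roughly 0.8 on the phantom suite), which is the dominant
error term propagated into the learned models.

## Rigid pre-alignment and common space

Before deformable registration, every volume is aligned to the reference
planning volume by the integer-voxel translation maximising normalized
cross-correlation over the overlap (exhaustive search, ties broken toward
the smaller translation then lexicographically), and all volumes are
cropped to the intersection bounding box — the "common space" is read as
the largest region common to all aligned volumes, not their union.
Translation-only alignment suffices because sub-voxel rigid residue is
absorbed by the deformable step.

## Workflows

Between-patient model: register every non-reference planning volume to the
reference (fields EF), fit at α = 90. Within-patient model: register each
daily volume to its own planning volume, carry the resulting field to the
reference space by resampling its three component images through that
subject's EF (no Jacobian reorientation — the components are moved as
scalar images, which keeps the transfer linear and matches how the
training fields are pooled), include the reference subject's own daily
fields untransferred, fit the pooled set at α = 95.

Artificial images: sample DE from the between-patient model (D_max = 3 by
default), invert it by fixed-point iteration (v ← −d(x+v), tolerance
0.01 voxel, ≤ 50 sweeps, non-convergence recorded in metadata rather than
raised) and warp the reference to get an artificial planning CT; for each
intra D_max (default 2, 3.5, 4.5) sample DT, transfer it through DE into
the artificial planning space (this is the stored ground truth DI), invert
and warp to get the daily CT. Masks propagate through the same warps with
nearest-neighbour sampling. Validation registers each daily back to its
planning volume and reports, per structure, the mean ± SD ± max of
‖DN − DI‖ next to the mean ± SD of ‖DI‖.

## Synthetic phantom population

The phantoms stand in for a clinical head-and-neck cohort. The reference
anatomy is geometric — body ellipsoid (~0 HU), mandible-like bone arc
(+1000 HU), two parotid-like ellipsoids (+40 HU) on air (−1000 HU) — on a
64×64×48 grid at (2, 2, 3) mm: big enough for a 3-level pyramid, small
enough for seconds-scale registrations. Two additions make it a fair test
bed for intensity-driven registration rather than a pathological one:

- **soft-tissue texture** (60 HU sd, 5 mm correlation length, seeded,
  bone excluded): real soft tissue is full of fat/muscle contrast at this
  scale, and a piecewise-constant interior would leave any intensity-based
  method blind inside organs;
- **body-confined deformation**: latent modes are multiplied by a
  feathered body window (6 mm feather) — air does not deform, and motion
  planted in air would be unrecoverable in principle.

Population structure: subject i's planning volume is the clean reference
warped by Σ_k w_ik B_k over K_inter orthogonal latent modes (Gaussian
weights, truncated at ±2.5 sd so no draw approaches the foldover guard of
half the smallest body semi-axis); fraction j warps the planning volume by
the population-common intra pattern Σ_k v_ijk C_k expressed in subject i's
anatomy (resampled through the subject's inter field) — within-patient
variation is shared across the cohort in reference coordinates, exactly
the structure the intra model assumes. Fresh 15 HU Gaussian noise (a
plausible in-room CT level) is added to every volume independently. All
ground-truth fields are stored; regeneration is bit-identical under the
seed.

Deformation scales: 5 mm peak between patients, 6 mm peak within — chosen
against clinical reports of multi-millimetre organ displacement over a
radiotherapy course (published organ-mean deformation magnitudes between
artificial planning and daily CTs reach 7–19 mm); the resulting phantom
organ-mean magnitudes of ~1–3 mm are on the conservative side of that
range. Latent smoothness is 20 mm, comfortably above the voxel scale and
below the anatomy scale.

What the phantoms do **not** emulate: anatomical texture and organ shape
realism, weight loss, tumor shrinkage, neck flexion, dental artifacts,
appearing/disappearing objects (air pockets), scanner-specific noise
spectra, or oblique grid geometry. A passing suite therefore shows that
the learning/sampling/validation machinery is correct and that the
pipeline recovers known low-rank deformation structure through a real
registration step — not that any particular clinical cohort is well
modelled.

## End-to-end figures of merit

On the default 8-subject × 5-fraction cohort with 2 inter and 3 intra
latent modes, the full register → transfer → fit pipeline recovers the
planted structure: the top-2 inter modes carry well over 80% of the
fitted variance, the intra eigen-scree drops by ≥ ×5 after mode 3, and the
top-3 intra subspace aligns with the generator basis at mean
principal-angle cosine ≈ 0.93. The scree-separation figure is the most
cohort-sensitive of the three (roughly ×3–×9 across seeds, since a single
strong registration-error mode competes with the weakest planted mode);
the fixed-seed test suite uses a cohort where all three criteria hold
simultaneously. On sampled artificial pairs, per-structure registration
error (0.2–0.6 mm mean) stays well below the true deformation magnitude
(1–3.5 mm mean) for every structure and D_max — the qualitative
relationship a usable validation harness must exhibit.

## Known limitations

- Demons accuracy is texture-limited and systematically damps large
  deformations; learned eigenvalues are therefore biased low relative to
  the generating variances (subspaces are recovered much better than
  scales).
- DVF inversion is fixed-point, first-order: its residual grows
  quadratically with deformation amplitude over smoothness, noticeable
  above ~8 mm at 20 mm smoothness.
- Component-wise DVF transfer ignores rotation of the deformation vectors
  (deliberately, for linearity and fidelity to the pooled-training
  construction); for strongly rotational inter-patient mappings a
  Jacobian-aware transfer would differ.
- The artificial daily images inherit the reference's noise and texture
  through warping (no independent noise injection by default), leaving a
  faint signature of the underlying deformation.
- Translation-only rigid alignment; no oblique/rotated grids; no DICOM.
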