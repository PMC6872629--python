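# Methods

This note documents the models, parameter choices and numerical decisions
behind `dbmorph`, and what the phantom-based validation does and does not
establish about real data.

## Problem setting

The pipeline targets small-cohort morphometry: two groups of subjects
(diseased, control) imaged as single 2D grayscale slices sharing a common
topology, where the disease signature is a *localized* difference in how
each subject's anatomy deforms onto a common reference. Rather than
testing analyst-chosen measurements, the method registers every subject
onto one reference subject and lets feature selection find the grid cells
whose deformation statistics separate the groups.

## Registration model

**Affine stage.** A 6-parameter affine map (full 2×2 linear part +
translation, rotation about the image center) is fit by minimizing the
mean squared intensity difference with Powell's method over a 3-level
resolution pyramid. MSD is appropriate because query and reference come
from the same modality; mutual information is deliberately not offered.
The transform maps query coordinates to reference coordinates; if the
optimizer cannot improve on the identity the identity is returned, so the
stage never increases dissimilarity.

**Demons stage.** Thirion-style additive demons with the passive
(reference-gradient) force. With `w = query ∘ (id + u)`:

    v = (r − w) ∇r / (‖∇r‖² + α² (w − r)²),    v = 0 where the denominator < 1e−12

`u ← u + v`, then `u` is Gaussian-smoothed (σ, diffusion-like
regularization), iterated per pyramid level, coarse to fine. The field
lives on the reference grid and *pulls*: `warp(query, u) ≈ reference`,
which makes cohort fields directly comparable cell by cell on the
reference frame.

Parameters (all exposed in config):

| parameter | default | meaning / rationale |
|---|---|---|
| `iterations_per_level` | 50 | SSD typically reaches the noise floor in ≲ 40 iterations at 128² |
| `smoothing_sigma` | 0.8 px | per-iteration field smoothing; see below |
| `levels` | 3 | captures displacements up to ~8 px at 128² |
| `alpha` | 1.0 | caps the per-iteration step at ½ px, standard normalization |

Because the *accumulated* field is smoothed every iteration, the
effective regularization is much broader than a single σ: early
increments are diffused ~σ√N_iter. σ = 0.8 px was calibrated on phantom
ground truth as the value that keeps the mean endpoint error well under
25 % of the deformation amplitude *and* preserves the spatial sharpness
of localized deformations; σ ≥ 1.5 px smears a radius-8 px lesion into a
~13 px halo, σ ≤ 0.7 px starts to degrade endpoint error on smooth warps.

**Convention note.** A generative phantom warp (reference → subject) and
the registration output (subject → reference) are mutual inverses;
`registration.invert_field` (fixed-point iteration) converts one into the
other. All recovery errors quoted here compare fields in the same
convention.

**Degenerate inputs.** Constant images produce a zero update everywhere
(zero gradient) and hence a zero field; zero-variance inputs to the
affine stage are rejected. If SSD rises for 10 consecutive iterations the
level stops and the best field so far is returned, flagged
`diverged` in the field metadata; a final guard returns the zero field if
the result would be worse than no deformation at all.

## Feature channels

Fields are downsampled by area-weighted block means onto grids of 3,
3.75 and 5 px cells (exact block means for integer cells; box-filter
overlap weights for fractional ones — mean displacement is conserved
exactly under area weighting). Per cell:

- **magnitude** `m = ‖u‖` (px) and **direction** `d = atan2(u_row,
  u_col)` (radians, zero vector → direction 0). Direction is circular;
  by default it reaches downstream consumers as `(sin d, cos d)` so
  Euclidean distances are continuous across ±π. The raw-angle encoding
  (`direction_encoding: angle`) reproduces the literal polar description.
- **jacobian** `det(I + ∇u)` (optional channel), central differences with
  spacing = cell size, computed *after* downsampling so all channels share
  cell geometry. 1 = no local area change, <1 shrinkage, >1 expansion.

Cells are flattened row-major, channels interleaved per cell, and each
column carries a descriptor (grid row/col, channel, cell size) so any
feature maps back to a unique pixel rectangle on the reference. The three
rates are analyzed independently throughout.

## PCA denoising

Across-subject PCA (columns mean-centered, covariance with the n−1
denominator, via SVD); the smallest leading set of components reaching
95 % cumulative variance is kept and the matrix reconstructed in feature
space, so feature selection still operates on per-location features.
Zero-variance matrices retain no components and reconstruct to the column
means. Re-denoising a denoised matrix is a no-op when the retained
spectrum is separated from the discarded tail; for a flat spectrum the
smallest-k rule necessarily drops one more component on a second pass —
an intrinsic property of fraction-based retention, not a numerical issue.

## Scored SFFS

One run walks a random permutation of all features twice. Forward: the
subset grows by one feature at a time (a feature stays regardless);
quality is the label agreement of a deterministic 2-means clustering of
the subjects in the current subspace (farthest-pair seeding, ties to the
lower row index; assignment fixed point, cap 100; agreement maximized
over the two cluster↔label pairings; all-identical rows score the
majority fraction). Strict improvement = +1, otherwise −1, and the
reference quality tracks the new value (ties count as failure, so inert
features are penalized). Backward: features are removed in the same
order; +1 if quality strictly drops without the feature, −1 otherwise,
the empty subset scoring the majority fraction. Scores are summed over
250 orderings; the top 5 become candidate biomarkers.

Implementation: every quality evaluation runs on the subjects' Gram
matrix, updated rank-1 as features enter or leave, so a single evaluation
is O(n_subjects²) independent of subset size (numba-compiled). This is
what makes 250 orderings over thousands of columns tractable.

**Resolution limit (important).** A feature's score can only respond to
the clustering when the current subset is small — roughly the first
positions of the forward pass and the last of the backward pass. With
d features and R orderings each feature lands in an informative slot
only ~2·R·m/d times (m ≈ informative subset size). At d ≈ 5 000 and
R = 250 that is ~2–4 evaluations per feature: the ranking reliably
separates lesion features from background, but the ordering *within* a
strongly discriminative region (core vs halo cells) is marginal. On
default phantom cohorts the top-5 features always fall inside the planted
lesion's footprint; across 10 generator seeds, the stricter event "≥ 3 of
the top 5 within two cells of the lesion center at every rate"
held in 5/10 (the misses sit 7–16 px out, inside the lesion's Gaussian
tail). Increasing orderings in proportion to the feature count, or
restricting the pool to tissue cells, sharpens the ranking.

## SVM validation

RBF-kernel SVC, C = 1, gamma = 1/(n_features × feature variance), features
standardized with training-fold statistics only (zero-variance features
get unit sd). Leave-5-out: 1000 random splits; splits with a single-class
*training* set are rejected and redrawn; rounds with a single-class
*test* set are skipped in the averaging (their TPR or FPR is undefined)
and counted. Each round's held-out scores give an empirical ROC step
curve evaluated at 101 FPR grid points (TPR at grid f = best TPR at
FPR ≤ f); the mean and across-round variance per grid point are reported
with the trapezoidal AUC of the mean curve.

Two protocols: `paper` mode selects features once on the whole cohort and
then cross-validates the classifier — the reference behavior, but
optimistic because held-out subjects influenced selection. On lesion-free
phantom cohorts this selection bias alone yields mean AUC ≈ 0.65.
`nested` mode re-runs SFFS inside every training split (fewer orderings
per split by default) and is the honest generalization estimate; on pure
noise it stays at chance and is never above paper mode on average.

## Phantom design

The phantom reproduces the statistical structure the pipeline assumes —
shared topology, smooth inter-subject deformation, a localized disease
effect — and nothing anatomical. The reference is a nested-ellipse
object with two scales of smooth seeded texture (dense intensity
gradients keep registration well-posed) on an exactly-zero background.
Each subject = reference warped by (affine jitter ∘ smooth field
[+ lesion]) + Gaussian intensity noise, with the exact composed field
returned as ground truth. Defaults: 15 + 15 subjects, 128², ±2° / ±2 px
jitter, background smooth deformation of peak 1 px and 12 px correlation
length, lesion peak 3 px with 8 px Gaussian radius along a fixed
per-lesion direction, intensity noise sd 0.01.

The background amplitude is deliberately one third of the lesion
amplitude: a validation phantom must carry a detectable planted effect.
Sensitivity: with background deformation comparable to the lesion
amplitude the SFFS localization degrades long before the SVM AUC does —
distributed inter-subject variability is the binding constraint on
*localization*, not on *separation*.

What phantom results do not show: robustness to intensity
non-uniformity, partial-volume effects, genuinely different anatomies
(the phantom violates none of the pipeline's assumptions), multi-scanner
intensity differences, or any anatomical interpretability of biomarker
locations.

## Numerical choices

- Bilinear, edge-clamped interpolation everywhere (warping, field
  inversion); one-sided gradients at borders.
- Per-subject and per-stage seeds derive from the master seed via
  `numpy.random.SeedSequence`; registration is noise-free by
  construction, so full experiments are bit-reproducible (report.json is
  byte-identical across re-runs; wall-clock timings live in a separate
  timings.json).
- Deformation fields are cached per subject in the output directory;
  re-running an experiment reuses them and reproduces identical results.
- Fractional-cell rectangles use floor-based half-open intervals, so the
  cells of one rate partition the reference exactly.
- 1st/99th-percentile intensity normalization with endpoint snapping
  (percentiles within 0.005 of 0/1 are treated as 0/1), which makes
  normalization idempotent.

## Known limitations

- 2D only, single slice per subject; no diffeomorphic or log-domain
  demons variants; no hyperparameter search for the SVM.
- The scored SFFS ranking within a discriminative region is
  resolution-limited at large feature counts (see above).
- Paper-mode AUC estimates carry feature-selection bias by design; use
  nested mode for honest generalization estimates.
- The reference subject is treated as the population frame; with a
  pathological or atypical reference, "deformation toward the reference"
  conflates subject and reference abnormality.
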