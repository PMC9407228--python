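# Methods

`bmdetect` implements a two-stage detector for small enhancing brain lesions
in 3D T1-weighted contrast-enhanced MRI, extended with a sensitivity-based
noisy-student semi-supervised training scheme, and a synthetic phantom module
that emulates the cohort structure the method was designed for.  This note
records the model, its assumptions, the parameters that matter, and the
choices made where the design was genuinely open.

## 1. Detection framework

**Candidate stage.** Volumes are resampled to an exact 1 mm³ grid (trilinear)
and normalized per exam by an affine percentile map (defaults (1, 99) for the
generic operation; the detection pipeline uses (1, 99.5) — see the numerical-choices section).  A
scale-normalized Laplacian-of-Gaussian filter bank (σ ∈ {1.0, 1.75, 2.5,
3.25, 4.0} mm, covering sphere radii ~1–7 mm via r ≈ σ√3) is negated so
bright blobs score positive.  Candidates are 26-connected local maxima
across space and adjacent scales inside an intensity brain mask
(`fine_scale_count` optionally relaxes the finest scales to purely spatial
maxima, which raises capture at the cost of a much denser, noisier candidate
population), refined to sub-voxel centres by intensity mean-shift (bandwidth
clip(0.75 σ, [1.2, 3]) mm annealing to half after two steps so late
iterations centre locally instead of drifting into adjacent vessels; local
25th-percentile background; ≤6 iterations), then greedily
non-maximum-suppressed at 2 mm and jointly constrained by a minimum response
(0.005) and a per-exam cap (300), constants tuned on training phantoms for
the ~95% capture target at the 1.5 mm matching tolerance.

**Classifier stage.** CropNet-bX-Ymm is a contracting 3D CNN on a Y-mm
isotropic cube: per resolution level, X blocks of (3³ conv → ReLU → dropout),
2× max-pooling between levels, and a flattened single sigmoid unit.  With the
default widths (64, 128, 256, 512) the teacher CropNet-b2-16mm has 14.05 M
and the student CropNet-b4-16mm 32.86 M trainable parameters.  Dropout
(rate 0.15) is the model-noising mechanism and is active only in training,
so inference is deterministic.  There is no batch normalization and no
global pooling; the head flattens the final 2³ level.  The per-level widths
and the head layout are pinned by the published parameter counts rather than
by an explicit schedule, which is why they are stated here as package
defaults.

**Training.** Binary cross-entropy over *paired* batches (equal positive and
negative counts) counters the extreme candidate class imbalance.  Full-scale
defaults mirror the study setting: Adam (5×10⁻⁵, β = 0.9/0.999), 12,000
batch iterations without early stopping, teacher batches 150+150, student
batches 75+75+75+75.  The labeled ROI set takes matched candidates plus the
annotation centres themselves as positives (so under-captured lesions still
contribute) and unmatched candidates as negatives; the training-side match
tolerance reuses the evaluation tolerance of 1.5 mm.

## 2. Sensitivity-based noisy-student scheme

1. Train the teacher θt on noised labeled ROIs, minimizing ℓ(θt(X_noised), Y).
2. Measure per-lesion maximum teacher responses on the training exams,
   pooled over all lesions; lesions with no matched candidate count as −∞.
   The sensitivity staircase is s(t) = #{max > t}/L.
3. Calibrate the pseudo-labeling threshold μ as the *largest* threshold
   whose training sensitivity still reaches the target ts (default 0.90):
   operationally the ⌈ts·L⌉-th largest per-lesion maximum, reduced by a
   relative nudge of 10⁻⁹ so that lesion itself counts under the strict rule.
4. Pseudo-label unlabeled candidate ROIs: ŷ = 1 iff θt(x̂) > μ, strictly,
   on *un-noised* ROIs (noise enters only the training losses).
5. Train the higher-capacity student θs on
   ℓ(θs(X_noised), Y) + λ·ℓ(θs(X̂_noised), Ŷ), each half mean-reduced
   separately (λ = 1 recovers equal weighting; λ = 0 reduces exactly to
   supervised training, which the tests assert at trajectory level).
6. Optionally promote the student to teacher and repeat; subsequent rounds
   reuse the student spec, whose capacity already meets the requirement.

Choosing ts near the teacher's peak sensitivity deliberately trades
pseudo-label purity for coverage of hard, low-response lesions; the sweep
driver (`evaluation.run_experiment`) reproduces the ts/λ/iteration/
labeled-fraction analyses at desk scale.

Design points the source setting left open, decided here: sensitivity is
pooled over all training lesions (not per-exam averaged), matching the
single-threshold FROC construction; the pseudo-negative pool is the strict
complement (response ≤ μ) of the pseudo-positives, with a configurable
per-exam cap on the candidates entering pseudo-labeling (default 100 at full
scale) because low-LoG-rank candidates are overwhelmingly flat background.

## 3. Data noising

Composition, in order: Simard-type elastic deformation (per-voxel uniform
(−1,1)³ field, Gaussian-smoothed σ_def = 4 voxels, scaled by α = 2 voxels,
trilinear with mirror boundary) → gamma correction with γ ~ U(0.8, 1.25) →
a random element of the 48-element cube-symmetry group (axis permutation +
per-axis flips with probability 0.5), interpolation-free.  Magnitudes are
package defaults chosen to be label-preserving: 200 noised copies of a
centred lesion keep its intensity centroid within the 1.5 mm tolerance of
the cube centre (asserted in the tests).  Arbitrary-angle rotation exists
behind a flag but is not default.  The batched implementation is asserted
sample-for-sample equivalent to the per-ROI path.

## 4. Evaluation

A lesion counts as detected if a detection lies within 1.5 mm of its centre
(inclusive — "up to" is read as inclusive); a detection matching no lesion is
a false positive; multiple detections of one lesion count it once and are not
false positives.  FROC curves pool lesions across exams; AFP divides total
false positives by the *exam* count (the source setting evaluates exams while
some figures say "per patient"; per-exam is implemented because folds contain
multi-exam patients), and lesion-free exams enter the denominator.  Detection
applies NMS at 1.5 mm keeping the highest response; because NMS and matching
are threshold-independent, the staircase is computed from per-lesion maximum
matched responses and the false-positive response multiset, which the tests
verify against brute-force re-evaluation at every threshold.  AFP at a
requested sensitivity linearly interpolates between straddling operating
points.  Cross-validation folds are assigned per patient (all exams of a
patient share a fold; fold patient counts differ by ≤1); mean fold curves are
averaged on a shared sensitivity grid (0.50–1.00, step 0.01).

## 5. Phantom generator

Each exam is an ellipsoidal "brain" (soft-edged, semi-axes 0.44 of the grid
extent) with a smooth Gaussian-field texture (amplitude 0.05, σ = 6 mm),
3–8 vessel-like tubes (smooth random-walk polylines splatted and blurred to
Gaussian cross-sections, radius 0.5–1.5 mm, contrast 0.3–0.7 — deliberately
lesion-like, the dominant false-positive mode), spherical soft-edged lesions,
and Rician-like noise (magnitude of a complex Gaussian, σ = 0.03).  Lesion
diameters follow a log-normal truncated to [2, 14) mm whose underlying
parameters are solved numerically so the post-truncation moments hit
5.45/2.67 mm; sampling is exact inverse-CDF.  Lesion counts per exam are
Poisson(4.29); zero-lesion exams are allowed and exercise the AFP
denominator.  Centres are uniform in the margin-eroded brain with ≥8 mm
pairwise separation so 1.5 mm matching is unambiguous.  Cohorts are built
from patient→exam multiplicity tables ({1:113, 2:33, 3:10, 4:2} labeled,
{1:579, 2:208, 3:68, 4:12} unlabeled — 217 and 1247 exams); labeled and
unlabeled patient ids are disjoint by construction.  The source statistics
are per patient but training operates per exam; repeated exams of a patient
draw fresh lesions, a declared divergence.  Two sub-seeds (structure, noise)
are logged per exam.

What the phantom does *not* emulate: anatomy (tissue classes, skull, bias
fields), scanner point-spread, registration error, pathology diversity.
Passing tests therefore demonstrate the *mechanics* of the framework — 
candidate capture, calibration correctness, the direction of the
noisy-student effect under vessel-like distractors — not clinical
performance.

## 6. Numerical and engineering choices

* World coordinates in mm, 0-based voxel indices, voxel-centre convention
  (index i ↦ origin + i·spacing); trilinear interpolation for intensities.
* The detection pipeline normalizes with upper percentile 99.5 rather than
  99: on the 64³ phantom the brightest ~1% of voxels belong to lesions and
  vessels, and clipping them merges neighbouring structures into flat
  plateaus that destroy the local-maximum structure the LoG stage needs.
* The CNN engine lowers 3³ convolution to 27 accumulating BLAS GEMMs over
  flat-shifted contiguous row views of the padded channel-last grid (zero
  gather/copy); it is float32 throughout and bitwise deterministic under
  fixed seeds.  Max-pool gradient splits evenly across tied maxima; the BCE
  gradient is taken through the sigmoid jointly for stability, with
  responses clipped by 10⁻⁷ in the reported loss.
* Convolution biases initialize at 0.01 and gradients are globally
  norm-clipped (default 10, configurable) before Adam: narrow desk-scale
  networks can otherwise lose an entire early layer to the dead-ReLU regime
  in the first aggressive optimizer steps and collapse to a constant output.
* All randomness flows from one seed through named child streams (init,
  batch sampling, noising, dropout).

## 7. Desk-scale benchmark

The semi-supervised benchmark the acceptance tests run is sized for a single
CPU core: 20 labeled training exams, 100 unlabeled exams and 20 held-out
labeled exams on 64 mm grids; teacher CropNet-b2-16mm and student
CropNet-b4-16mm with the width schedule (4, 8, 16, 32); Adam at 2×10⁻³ for
250 iterations; teacher batches 16+16 and student batches 8+8+8+8;
ts = 0.90, λ = 1, one student round; 5 seeds, with the median AFP at 90%
pooled test sensitivity compared between student and teacher.  These sizes
are the package's own desk-scale choice; the full-scale defaults in
`TrainingConfig` mirror the study setting.  The λ sweep reuses the seed-0
teacher and pseudo-labels and retrains students at λ ∈ {0.6, 0.8}, checking
the interpolation direction within the Monte-Carlo spread estimated from the
5-seed λ=1 runs.

## 8. Known limitations

* The student-vs-teacher comparison on the phantom benchmark is statistically
  delicate: the semi-supervised effect reported for clinical data is of the
  order of a ~9% AFP reduction, while the cross-seed Monte-Carlo spread of
  AFP at 90% sensitivity on 20 held-out phantom exams is around ±20%.  Two
  further desk-scale factors work against the student: pseudo-positive
  precision is only ~0.2 at ts = 0.90 and the false-positive mode is a
  single homogeneous structure class (synthetic vessels), so pseudo-label
  noise is systematic rather than diverse; and within a 250-iteration budget
  the unlabeled loss half mainly dilutes the labeled supervision (an ablation
  with ground-truth labels on the unlabeled candidates still trails a purely
  supervised student).  The benchmark test states the comparison anyway and
  reports the measured medians; clinical-scale magnitudes are not
  reproducible without the (private) clinical data.
* The candidate stage's "constrained LoG" is re-derived from its stated
  goals (capture vs. count), not from its original tuning, which is not in
  the source text.
* Percentile normalization is a declared stand-in: the source preprocessing
  is unstated.
* The engine targets small desk-scale networks; the full-width models build
  and count correctly and run inference, but training them at the published
  iteration counts is a GPU-scale exercise out of scope here.
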