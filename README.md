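# bmdetect

Detection of small brain metastases (BM, diameter < 15 mm) in 3D
T1-weighted contrast-enhanced MRI (T1c), with a **sensitivity-based
noisy-student** semi-supervised training scheme that exploits a large corpus
of *unlabeled* exams.  The package is aimed at researchers studying
candidate-based lesion detection and semi-supervised training for medical
imaging; because the clinical cohorts such methods are built on are private,
it ships a synthetic phantom module that reproduces their statistical
structure, so the entire pipeline is runnable and testable on a laptop.

## The method

The detector works in two stages:

1. **Candidate generation.**  A constrained multi-scale Laplacian-of-Gaussian
   (LoG) detector on the 1 mm³ isotropic, intensity-normalized volume
   proposes blob-like candidates (scale-normalized response, non-maximum
   suppression, per-exam count and response constraints tuned for ~95%
   lesion capture at a 1.5 mm centre tolerance).
2. **Candidate classification.**  CropNet-bX-Ymm, a contracting 3D CNN over
   a Y-mm cubic ROI with X conv-ReLU-dropout blocks per resolution level,
   maps each candidate ROI to P(BM) ∈ [0, 1].  Batches pair equal numbers of
   positive and negative ROIs to counter the extreme class imbalance, and
   minimize binary cross-entropy ℓ.

Semi-supervised extension (teacher θt = CropNet-b2-16mm ≈ 14M parameters,
student θs = CropNet-b4-16mm ≈ 33M parameters):

    θt  = argmin ℓ(θt(X_noised), Y)                      (teacher, labeled X)
    μ   : largest threshold with train sensitivity ≥ ts   (calibration, ts = 0.90)
    ŷᵢ  = 1  if θt(x̂ᵢ) > μ  else 0                       (pseudo-labels, unlabeled X̂)
    θs  = argmin ℓ(θs(X_noised), Y) + λ·ℓ(θs(X̂_noised), Ŷ)   (student, λ = 1)

The response threshold μ is *calibrated from the teacher's training-data
detection sensitivity* rather than fixed: a high target sensitivity ts keeps
hard, low-response lesions in the pseudo-positive pool at the price of
noisier labels.  Data noise is elastic deformation, gamma correction and
axis-aligned rotations/flips; model noise is dropout.  The student can
replace the teacher and the cycle can be iterated.  Performance is reported
as FROC: lesion sensitivity vs. average false positives per exam (AFP),
with a 1.5 mm (inclusive) centre-matching tolerance.

## Worked example

Simulate a small labeled+unlabeled phantom cohort, run the full
noisy-student pipeline, and evaluate:

```bash
bmdetect simulate --out cohort/ --seed 1 --labeled-patients 6 --unlabeled-patients 10 --config examples/desk.yaml
bmdetect ns-run   --in cohort/ --config examples/desk.yaml --out run/ --seed 1
bmdetect evaluate --in cohort/ --model run/student.npz --config examples/desk.yaml --out eval/
```

which prints (numbers from this exact command sequence):

```
wrote 6 labeled + 10 unlabeled exams to cohort/
saved teacher/student checkpoints and run log to run/
{"afp_at_80": 13.166666666666666, "afp_at_85": 14.833333333333334, "afp_at_90": 27.5}
```

and `run/run.json` records the calibration: the teacher's response threshold
μ = 0.739 reached a training sensitivity of 0.929 against the target
ts = 0.90, and pseudo-labeled 149 of 1,000 unlabeled candidate ROIs
positive.  `eval/froc.csv` holds the full FROC staircase (threshold,
sensitivity, AFP per exam); `afp_at_90 = 27.5` means that at the threshold
detecting 90% of this tiny cohort's lesions the 150-iteration demo model
raises 27.5 false alarms per exam — the desk-scale benchmark in the test
suite, with 20 training exams and 250 iterations, brings the teacher to
around ten per exam.  `evaluate` here scores the cohort's labeled exams; held-out
evaluation splits by patient via `bmdetect.split_cv_by_patient`.

The same pipeline is available as a library (`bmdetect.ns_loop`,
`bmdetect.froc`, ...); `evaluation.run_experiment` sweeps ts, λ, student
iterations and labeled-data fraction over patient-level cross-validation
folds and tabulates teacher/student AFP at 80/85/90% sensitivity.

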