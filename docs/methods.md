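# Methods

## Signal model and features

The pipeline targets cue-paced 4-class sensorimotor EEG: 64-channel 10-10
recordings at 160 Hz, organized in 14 runs per session (runs 1–2 baseline;
runs 3, 7, 11 executed and 4, 8, 12 imagined unilateral fist movements;
runs 5, 9, 13 executed and 6, 10, 14 imagined bilateral fists/feet
movements). Cue annotations T0/T1/T2 mark rest and the two task alternatives
of each run type; the run type resolves T1/T2 to the four classes (left
fist, right fist, both fists, both feet), fixed in that order for
deterministic tie-breaking.

Preprocessing is deliberately minimal: a fifth-order Butterworth band-pass
over 8–30 Hz applied to the continuous run (the mu/beta band where
event-related desynchronization/synchronization lives), then epoching from
cue onset to 4.0 s (640 samples), then optional restriction to the 29
sensorimotor-area electrodes (all montage channels with prefix FC, C, CP,
FT, T or TP). The default filter is causal single-pass; a zero-phase
forward–backward mode exists behind a flag but doubles the effective order,
so it is not the default. No notch filter, artifact rejection, re-referencing
or resampling is applied.

Each epoch `E` (channels × samples) becomes the unit-trace spatial
covariance `CM = E Eᵀ / tr(E Eᵀ)`. No demeaning is applied before the outer
product (band-passed signals are already near zero-mean; a flag is not
provided because the estimator is scale-invariant and the effect is
negligible at 640 samples). No shrinkage is used; a relative eigenvalue
floor (1e-10 of the trace) is available as a numerical repair step and is
verified unnecessary for full-rank 640-sample epochs.

## Geometry

All classifier operations use the affine-invariant metric
δ(A,B) = ‖log(A^{-1/2} B A^{-1/2})‖_F. Matrix log/sqrt go through symmetric
eigendecomposition with a relative eigenvalue floor of 1e-12 — robust and
dimension-agnostic. The Karcher mean is the standard fixed-point iteration
(tangent-average at the current estimate, exp-map back) with tolerance 1e-8
on the gradient norm, at most 50 iterations, arithmetic-mean
initialization, and unit step halved whenever the gradient norm increases.
Converged means are insensitive to the tolerance over 1e-6…1e-10 (tested).
Tangent vectors use half-vectorization with √2 off-diagonal weights so the
Euclidean norm in tangent space equals the manifold distance — the property
the Fisher geodesic filter's orthogonal projection relies on.

## Classifiers and adaptation

`fit` estimates per-class Karcher prototypes (MDM) or, for FgMDM, first a
grand-mean reference and a rank-(K−1) Fisher discriminant basis in the
tangent space; training trials are filtered (tangent-map → project onto the
basis span → exp-map back) before prototype estimation. The within-class
scatter is ridge-regularized by λ·tr(Sw)/dim with λ = 1e-3, without which
the 64-channel tangent dimension (2080) would make the scatter singular at
90 trials.

Streaming semantics (`predict_stream`), per incoming trial:

1. rebias variants update the running reference with the **raw** trial via
   the incremental geodesic mean (weight 1/(n+1), n counting all matrices
   absorbed since calibration), then recenter the trial at the updated
   reference;
2. the (recentered, filtered) trial is classified by nearest prototype,
   ties resolving to the lowest class index;
3. supervised variants update the true class's prototype with the
   recentered trial, unsupervised variants the predicted class's; FgMDM
   adaptive variants instead append the trial to the calibration pool and
   refit reference, filter and prototypes (an exact but O(stream²) refit; a
   windowed refit option trades fidelity for speed).

Two deliberately-resolved ambiguities: FgMDMR updates the reference only
(filter refits are reserved for FgMDMRS/FgMDMRU), and two-level variants
update prototypes with recentered trials. Both are switchable in code;
calibration prototypes are built from recentered calibration data and are
not re-shifted per trial.

## Synthetic subjects

The generator emulates the statistical structure the decoders assume, not
the biophysics. Four unit-trace class-mean SPD matrices are built by
congruence-perturbing a shared random base with exp-map steps of norm
`separation`, in symmetric directions supported on C3-, C4- and Cz-like
channel blocks with contralateral organization (left fist → right block,
right fist → left block, both fists → both, both feet → central). Rest
segments share one further covariance distinct from all class means. Per
trial a covariance is drawn as Wishart(Σ_class, df)/df with df = `noise_df`,
and the segment filled with Gaussian samples from it; trial timing is
4.2 s rest + 4.1 s task so a 4.0-s epoch always fits, with exact sample
onsets. Per nature, 6 runs × 15 trials give 90 motor trials balanced 22–23
per class. An optional oscillatory mode (mu 10 Hz and beta 22 Hz sinusoids
with ERD-style class-dependent attenuation over 1/f noise) produces
band-limited signals closer in appearance to real recordings, but the
covariance-level mode is the test workhorse because ground truth is known
exactly on the manifold.

Defaults: `separation = 0.5` (a mid-range condition where accuracies fall
between chance and ceiling), `noise_df = 640` (matching the 640-sample
epoch length, so generative dispersion and estimation noise are comparable),
`drift_strength = 0`. Within-class dispersion of real recordings is not
calibrated against any dataset; `noise_df` is a free parameter. Session
nonstationarity is modeled as a slowly varying SPD congruence (a symmetric
random-walk exponential) applied across trials (`apply_drift`).

What the generator does **not** emulate: volume conduction and realistic
head geometry, ocular/muscular artifacts, non-Gaussian and nonstationary
background EEG, subject-specific montages. Passing tests therefore
demonstrate correctness of the algorithms under their own assumptions, not
expected accuracy on real recordings.

## Evaluation protocol

Per subject and task nature: 10-fold stratified cross-validation. Fold
assignment is shuffled-within-class round-robin with the fold pointer
carried across classes, so 90 trials balanced 22–23 over 4 classes give
exactly 9 trials per fold with 2–3 per class. For each fold the decoder is
calibrated on the out-of-fold trials and the in-fold trials are streamed in
their original recorded order with adaptation active (supervised variants
receive true labels); adaptation state resets at each fold boundary.
Cohort aggregation uses mean, sample SD (n−1) and a Student-t two-sided
confidence interval, which at n = 103 reproduces published 95% bounds to
the third decimal where a normal-quantile interval does not. The Wolpaw
ITR uses bits/trial = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1)) times
60/trial-length, with below-chance accuracies reported as 0.

## Scale of the shipped checks

The test suite and acceptance script run everything on synthetic subjects
at 6–16 channels with 90 trials — sizes at which every algorithmic property
(metric identities against commuting-matrix closed forms at 1e-8, Karcher
convergence, Fg filter rank and projection behavior, the 12 adaptation
variants, fold balance, CI and ITR values) is exercised exactly, while the
full grid stays fast. The 64-channel path is exercised for the pipeline
counts (640 samples, 29-channel subset, 90 trials, 103 qualified subjects
of the S001–S109 roster). Running the full 103-subject × 12-classifier ×
4-setting grid on the real dataset is supported through the `edf_dir`
source and the CLI but requires the recordings on local disk.

Two empirical notes from the shipped checks. First, chance-level tests use
label-shuffled trials drawn from a single shared covariance: within-subject
label permutation of *class-structured* trials under cross-validation shows
the well-known anti-learning bias (a few percent below chance), which is a
property of permuted-label CV, not of the decoders. Second, rebias beats
the static baseline only when the reference can actually track the shift —
the shipped regression uses a 40-trial calibration, a 90-trial strongly
drifted stream and drift applied as a growing congruence; with a 90-trial
calibration the 1/(n+1) reference update is too inert to win within one
session, consistent with rebias underperforming baseline in within-session
cross-validation on real data.

## Known limitations

- The Fisher-geodesic discriminant span is estimated from within-class
  scatter; at tangent-dimension-to-sample ratios typical here the span is
  tilted (Marchenko–Pastur spread of the scatter eigenvalues), which is
  visible as FgMDM's accuracy loss relative to MDM.
- The EDF writer produces only the subset of EDF+C needed for round-trip
  testing (16-bit records, one annotation channel, fixed 1-s records).
- The Riemannian median and alternative metrics (log-Euclidean,
  Bures–Wasserstein) are out of scope.
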