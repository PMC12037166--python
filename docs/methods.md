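# Methods

This note documents the models, parameters, and numerical choices behind
the package, and what the synthetic-data validation does and does not
establish about real data.

## The analysis model

The pipeline treats reactivation detection as a pattern-classification
problem.  During task sessions, two conditions — active visuomotor
tracking ("task") and passive observation of replayed cursor motion
("replay") — alternate in 12 s blocks.  A linear soft-margin SVM
(LIBSVM via scikit-learn, fixed `C = 1`, convergence tolerance 1e-6) is
trained on *spatiotemporal* samples: the ROI pattern of four consecutive
volumes, concatenated volume-major (vector index `l·V + v` is voxel `v`
at window volume `l`), one sample per block, with the window start
shifted 2 TRs (6 s) after block onset to account for hemodynamic delay.
Decoding quality is reported as leave-one-session-out accuracy across the
first three task sessions; the model used for rest scoring is retrained
on all three sessions.

Rest runs are scored with a sliding window of the same length advancing
one volume per step.  The SVM route labels a window task iff
`w·x + b > 0`; the RSA route labels it task iff it is strictly closer in
Euclidean distance to the class-mean task template than to the non-task
template.  Both routes label exact ties non-task (a measure-zero event in
floating point, pinned for determinism, conservative with respect to the
reactivation hypothesis).  Nearest-template labeling is algebraically a
linear rule — `(t_task − t_non)·x − (‖t_task‖² − ‖t_non‖²)/2 > 0` — and
the implementation is verified against that closed form.  The primary
statistic is the window-level task fraction; a volume-level variant (a
volume is task if any covering window is) is available via
`decoding.volume_level_fraction`.

Preprocessing, in enforced order: discard the first 3 volumes of every
run; regress each voxel on a DCT-II drift basis with
`K = floor(2·T·TR/cutoff)` regressors (cutoff period 128 s, the SPM
high-pass convention — K = 5 for a 119-volume rest run, K = 8 for a
171-volume task run), which also removes the run mean; z-normalize each
voxel by its own within-run mean and sd (ddof = 1).  Constant voxels
become zeros and are flagged, never NaN.  Normalization is per run; the
alternative of reusing task-run statistics is not implemented as a
default because "within each voxel" most naturally reads per run.

## Cohort statistics

`mixed_anova_2x2` is the classical sums-of-squares mixed-design ANOVA for
one two-level within factor and one two-level between factor.  With two
within levels the decomposition is computed exactly via difference scores
(session and interaction effects) and subject means (group effect); for
unbalanced groups the single-degree-of-freedom effects follow the
Type-III / unweighted-means convention (the session F then differs
slightly from a weighted-means analysis; group and interaction terms are
identical either way).  With one group the session F reduces exactly to
the squared paired t.  Effect sizes are partial eta squared,
`SS_effect / (SS_effect + SS_error)`.  All tests are two-sided, and
Bonferroni correction takes the family size as an explicit argument.

## The synthetic-data generator

The generator emulates a two-group (right-hand/left-hand) cohort with
four task sessions (174 volumes, 10 task + 10 replay blocks of 12 s,
TR 3 s) and two 122-volume rest runs.  Block layout is deterministic:
9 s initial fixation, 6 s between blocks, trailing fixation; all onsets
fall on TR boundaries.  The inter-block timing is an assumption (only
total scan counts are fixed by the emulated acquisition), chosen so the
design fits the run with no partial-TR blocks.

Signal model per voxel:

* **Condition patterns.** Each condition evokes a fixed spatial pattern
  supported on a random 10% subset of ROI voxels (`responsive_fraction`),
  with Gaussian weights, unit Euclidean norm, and configurable mutual
  correlation (default 0, via Gram-Schmidt).  Inside the forward model
  the pattern is scaled by `sqrt(n_responsive)`, so `pattern_amplitude`
  (default 1.0) is the RMS response of a responsive voxel in the same
  percent-signal-scale units as `noise_sd` (default 1.0), independent of
  ROI size.  Sparsity reflects that only a minority of an anatomically
  defined ROI carries condition information.
* **Hemodynamics.** Boxcars are convolved with a canonical double-gamma
  HRF (peak delay 6 s, undershoot delay 16 s, unit dispersions,
  peak:undershoot ratio 6, 32 s support, sampled at the TR and scaled to
  peak 1).
* **Noise and drift.** Independent per-voxel AR(1) noise (coefficient
  0.3, innovation sd `noise_sd`) plus a shared slow drift: a cosine of
  period 300 s and a linear ramp, both scaled by `drift_amplitude`
  (default 2.0) — the low-frequency structure the 128 s filter targets.
* **Reactivation events.** Rest runs add `n` non-overlapping 12 s
  task-pattern events at uniformly drawn onsets (exact-uniform via the
  combination bijection), passed through the same HRF forward model.
  Ground truth records onsets (post-discard volume indices) and the
  fraction of sliding windows overlapping any event.
* **Behavior.** Tracking error per session: a subject baseline
  (40 ± 5 error units) with a ±3 learning trend over sessions 1–3;
  session 4 is the baseline minus a fixed 5-unit offline gain minus
  `behavior_coupling` times the planted reactivation increase (in
  percentage points), plus Gaussian noise.  `coupling_for_target_r`
  inverts the linear-Gaussian model to hit a chosen population
  correlation between reactivation increase and improvement.

Every draw is a pure function of the seed (per-subject seeds are spawned
from the master seed), so cohorts are bit-reproducible.

## What the validation shows — and a structural caveat

At the default amplitude/noise ratio the decoder separates task from
replay essentially perfectly (LOSO accuracy ~100% over cohorts of 20),
and with no planted events the cohort-mean task fraction of both scoring
routes sits near 50% (~52%) with the session effect at its nominal
false-positive rate — the pipeline has no material systematic rest bias.
The small (+2 pp) offset that does exist is structural: the first task
block of each session lacks a preceding replay block, and z-scoring of
signal-rich runs slightly amplifies that asymmetry into the decoder
intercept.

**Caveat: additive events versus mean-removing preprocessing.**  The
high-pass filter and z-normalization remove each voxel's within-run
mean.  Consequently the average decision value over a rest run's sliding
windows is pinned to the decoder bias regardless of what was planted:
an additive event raises decision values inside event windows exactly as
much as it lowers them (via the removed mean) everywhere else.  The task
fraction — a threshold-crossing statistic — can then respond only to the
*shape* of the decision-value distribution, and sparse strong events
(coverage below half the run) skew it to the right, which *reduces* the
fraction.  Planted sparse additive events therefore do not reproduce a
monotone post-minus-pre increase under this pipeline; the acceptance
suite documents this as an open discrepancy rather than masking it.  The
implication for real data is substantive: a positive pre-to-post shift
in this statistic reflects a majority-time tilt of ongoing rest activity
toward the task pattern, not a handful of discrete high-amplitude
replay events.  Conditional recovery does hold and is tested: windows
overlapping planted events are labeled task at a clearly higher rate
than non-event windows in the same run, for both scoring routes.

Other validated properties include: exact structural counts (119
retained rest volumes, 116 windows, 20 block samples per session, K = 5
drift terms), filter behavior (a period-300 s drift attenuated to <5%
residual RMS while a 24 s block regressor passes at ≥95%), oracle
equivalence of all statistical kernels to direct-formula computations
(and of the mixed ANOVA to pingouin on balanced designs), and recovery
of a population reactivation-behavior correlation of 0.6 to within 0.1
at n = 21 over 100 cohorts.

## Problem sizes and numerics

Validation experiments use cohorts of 20–40 subjects at the full design
size (200 voxels, 174/122-volume runs); unit tests use 12–30 voxel ROIs.
Constant-voxel detection uses a scale-aware tolerance
(`sd ≤ 1e-8 · max(1, max|data|)`).  The GLM uses plain OLS (no AR
prewhitening) since its role here is a sanity check of the planted
activation, and reports signed infinities on exactly-fit voxels.  SVM
training is deterministic given input order.  Event placement draws are
exactly uniform over feasible non-overlapping onset sets.

## Known limitations

The generator does not model motion, physiological noise, spatial
autocorrelation, multi-ROI structure, or session-to-session pattern
drift, so passing tests bound implementation correctness and statistical
calibration, not robustness to those real-data effects.  The GLM omits
prewhitening, making its t-values mildly optimistic under autocorrelated
noise.  The mixed ANOVA covers the 2×2 design used by the pipeline, not
general factorial layouts (the four-session behavioral ANOVA is out of
scope).
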