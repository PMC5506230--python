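# Methods

`mweeg` estimates the intensity of mind-wandering (MW) — task-unrelated
thought reported on a 7-point Likert scale at periodic thought probes —
from multichannel scalp EEG recorded during a sustained-attention task.
This note documents the models, the estimators, the synthetic-data
generator, and the numerical choices, in enough detail to reproduce or
criticize any of them.

## The task and the modeling unit

A session consists of `n_sections` (default 42) task sections; each section
holds `trials_per_section` (default 10) trials at `trial_interval` (default
2 s) — 20 s of task EEG — and ends with a thought probe answered 1–7.
The modeling unit is the *section*: one feature row per section, built from
the section's 1-s epochs, with the probe answer as the response.

## Feature extraction

1. **Filtering.** Zero-phase 4th-order Butterworth band-pass 0.3–70 Hz plus
   an IIR notch at 50 Hz (Q = 30), both applied forward–backward
   (`filtfilt`), so the cascade's power response is the squared magnitude of
   the design. Attenuation exceeds 20 dB at 0.15 Hz, 50 Hz, and 100 Hz.
2. **Epoching.** 1-s epochs cut within annotated sections only; a recording
   that ends mid-section is an error, never a silent truncation.
3. **Artifact rejection.** An epoch is flagged when any channel exceeds a
   peak-to-peak threshold (default 200 µV) or a sample-to-sample gradient
   threshold (default 150 µV/sample). Flagged epochs are excluded from every
   spectral estimate; sections with fewer than 4 clean epochs are dropped.
   These two documented rules stand in for the proprietary vendor detection
   used with the original hardware.
4. **Band power.** Each epoch is transformed with a plain rectangular-window
   DFT (1 Hz resolution; a Hann taper is available, off by default).
   Per-bin power is |X_k|²/N; band power is the mean over the band's bins,
   averaged over the section's clean epochs. The band scheme is Kubicki's
   eight bands (delta 1.5–6, theta 6.5–8, alpha1 8.5–10, alpha2 10.5–12,
   beta1 12.5–18, beta2 18.5–21, beta3 21.5–30, gamma 35–44 Hz). Because
   band edges fall on half-integer frequencies, every 1-Hz bin center
   belongs to at most one band; bins in the 12–12.5 and 30–35 Hz gaps belong
   to none.
5. **Coherence.** Magnitude-squared coherence |S_xy|²/(S_xx·S_yy) with auto-
   and cross-spectra averaged over the section's clean epochs, then averaged
   over the band's bins. Estimating per epoch would be degenerate (a
   single-segment MSC is identically 1), so the section is the estimation
   unit and at least 2 clean epochs are required. With K averaged epochs the
   null expectation of MSC is ≈ 1/K (≈ 0.05 at K = 20) — a bias, not a bug,
   and identical for every pair.
6. **Layout.** For E electrodes and B bands the row has (E + E(E−1)/2)·B
   predictors — 1,224 for E = 17, B = 8 — named `power_<el>_<band>` and
   `coh_<el1>_<el2>_<band>` (pair in montage order), in a fixed column
   order: all power features first, then all coherence features.
7. **Normalization.** Within each subject, every feature column and the
   response are z-scored (population SD, i.e. divide by n). Zero-variance
   columns become 0 with a warning. Normalization is idempotent.

## Dataset assembly

* Subjects whose raw probe answers span fewer than 2 Likert points are
  excluded (uninformative reporters).
* Whole subjects are assigned to train/test partitions uniformly at random
  under a seed; the test share is round-half-up of one third.
* After normalization and the split, any section row containing a feature
  with |z| > 5 is dropped (train and test alike).
* Both partitions are then scaled by the *training* partition's per-feature
  mean and SD. No statistic anywhere on the training side depends on test
  rows; an instrumentation test perturbs the test partition and asserts the
  training artifacts are bit-identical.

The order normalize → split → outlier-drop → scale is a deliberate choice
where the protocol is ambiguous; it keeps the outlier rule expressed in
within-subject z units and the final scaling leakage-free.

## Predictor selection

Features are screened by |Pearson r| against the response on training rows
only. Candidate sets are formed at thresholds 0, 0.01, … up to the largest
multiple of 0.01 not exceeding the maximum |r| (a maximum of 0.346 yields 35
sets); membership is |r| ≥ threshold, so sets are nested and the top set
retains the single best predictor. A separate one-feature set (the arg-max
of |r|, ties broken by name order) feeds the simple-regression baseline.

## Models

ε-insensitive support vector regression: minimize
C·Σᵢ V_ε(yᵢ − f(xᵢ)) + ½‖β‖², with V_ε(r) = max(|r| − ε, 0), for
f(x) = x'β + β₀ (linear kernel) or its kernelized form with
k(x, x') = exp(−γ‖x − x'‖²) (RBF). The solver is libsvm via scikit-learn,
followed by one exact Newton step on the identified active set (holding
bound-active dual coordinates at ±C and re-solving the free stationarity
conditions), accepted only when the primal objective does not increase;
this removes libsvm's termination-tolerance residual, and the fitted
objective matches a brute-force dual-QP oracle to 1e-6 on small instances.

γ is fixed at 1/p (p = number of features in the candidate set), the common
solver default; (C, ε) are grid-searched over powers of two (defaults
C ∈ 2⁻⁴…2², ε ∈ 2⁻⁶…2¹) by k-fold cross-validated mean squared error
(default k = 10; folds are a random row partition, as equal as possible,
shared across candidates; ties go to the first candidate, C-major order).
The CV kernel matrix is computed once per candidate set and sliced per fold.

The model family, under an electrode budget (default 9; a power feature
uses 1 electrode, a coherence feature 2, duplicates counted once):

| model | kernel | predictor set |
|---|---|---|
| 1 | RBF | best CV MSE over all thresholds |
| 2 | RBF | best CV MSE among sets within the budget |
| 3 | linear | best CV MSE over all thresholds |
| 4 | linear | best CV MSE among sets within the budget |
| 5 | OLS | the single best predictor |

Models 1 and 3 pick their thresholds per kernel (they may differ).

## Evaluation

Held-out precision is Pearson r between predictions and measured responses
on the test subjects, with the usual t-test on n−2 degrees of freedom.
Between-model contrasts use a *dependent* correlation test by default
(Steiger's Z via Dunn & Clark, using the correlation r₁₂ between the two
models' prediction series), because both models are evaluated against the
same measured responses; the independent Fisher-z difference
(z₁−z₂)/√(2/(n−3)) is available. One-sided p-values by default. When two
prediction series are effectively identical (r₁₂ → 1 forces r₁ = r₂), the
statistic is 0 by continuity; constant prediction series are assigned r = 0
with a warning.

The behavioral validation correlates each subject's per-section RT variance
with the raw probe answers, Fisher-transforms the r values, and applies a
one-sample Wilcoxon signed-rank test (exact for n ≤ 25, normal
approximation above; one-sided, positive direction).

## The synthetic cohort generator

No public EEG corpus matches this protocol, so the package ships a
first-class generator with a known latent MW process; every recovery claim
in the test suite is against its ground truth.

* **Latent MW.** Per-section AR(1) (coefficient 0.6, innovation SD 1),
  z-scored per subject. Probe answers are the z-scored trace plus Gaussian
  reporting noise (SD 0.5), affine-mapped (4 + 1.5z), rounded and clipped
  to 1–7.
* **Background EEG.** Per-channel white noise (15 µV SD) plus three
  broadband sources shared by all channels through per-subject random
  mixing weights, carrying half the background variance — scalp channels
  are strongly mutually correlated, as referenced EEG is. Each shared
  source's amplitude drifts per section (log-SD 0.4, independent of MW),
  so spectral features co-fluctuate across sections the way real features
  do under arousal changes. A per-subject global amplitude scale (log-SD
  0.15) makes within-subject normalization consequential. No 1/f shaping:
  spectral realism beyond the correlation structure is not needed for any
  claim the package makes.
* **Linear (coherence) pathway.** A shared beta3-band (22–29 Hz) source is
  mixed into the parietal-occipital group (Pz, O1 at weight 1; O2, Oz at
  0.5) with gain effect_linear·sigmoid(mw_z)·15 µV. Mixing is
  power-compensated: each channel also receives an independent same-band
  source at √(g_max² − g²), so beta3 *power* stays flat and the planted
  effect is specifically *coherence*, strongest for Pz–O1.
* **Non-linear (power) pathway.** Each lateral-prefrontal channel receives
  an independent 13–21 Hz component with amplitude
  ∝ √(0.25 + (mw_z − v)²) — a U-shaped link whose vertex v is staggered
  across channels (F3 −0.35, F4 −0.12, F7 +0.12, F8 +0.35), modeling graded
  engagement depths across the lateral prefrontal cortex. Each single
  power feature is therefore substantially non-monotone in MW (capped
  around |r| ≈ 0.4) while the set is complementary: together the channels
  tile the MW axis, so multivariate models decode MW far better than any
  single feature can — the planted analogue of the multivariate advantage.
* **Heterogeneity.** Each pathway's gain (log-SD 0.35) and each group
  channel's weight (log-SD 0.15) vary between subjects, independently per
  pathway. Within-subject normalization removes scale but not
  signal-to-noise differences, so a single-feature model generalizes worse
  to new subjects than a model that hedges across pathways.
* **Reaction times.** Lognormal per-trial RTs (median 0.45 s) with
  per-section log-SD 0.1·(1 + rt_effect·mw_z), floored at 0.02.
* **Artifacts.** Each 1-s window independently receives, with probability
  `artifact_rate`, a 0.2-s raised-cosine burst (peak 400 µV = 2× the
  rejection threshold) on 2–5 random channels; contaminated window indices
  are recorded for test introspection.

Default effect gains (effect_linear 0.25, effect_nonlinear 0.3) were
calibrated once so that the strongest planted feature's pooled |r| lands in
the 0.35–0.55 range — the regime the method is designed for — with the
remaining planted features graded below it; they are study conditions, not
tuning knobs. Cohort size defaults to 15 subjects, which after the
one-third split yields roughly 420 training and 210 test rows, a compact
scale proportioned like a realistic cohort.

### What the generator does and does not emulate

It emulates: the session structure and annotation layout; correlated
background with slow state drift; planted, recoverable linear and
non-linear MW pathways; between-subject scale and expression differences;
artifact contamination; Likert reporting noise. It does not emulate: 1/f
spectra, eye-movement or muscle waveform morphology, volume-conduction
geometry, electrode impedance drift, or task-evoked potentials. Passing
tests therefore demonstrate that the *pipeline* recovers effects of the
planted kind under realistic feature-correlation structure — not that any
specific real EEG dataset contains such effects.

## Numerical choices and degenerate inputs

* Population-SD convention everywhere a z-score is taken.
* Zero-variance columns: set to 0 (normalization), assigned |r| = 0
  (screen), dropped (training-statistics scaling) — always with a warning.
* Ties: grid search and model selection take the first candidate in
  enumeration order; the single-best screen feature ties break
  lexicographically.
* Coherence requires ≥ 2 clean epochs; sections below the minimum clean
  count are dropped with a logged reason.
* |r| = 1 in the correlation test reports the underflow floor (1e-300) with
  a warning rather than 0.
* Problem sizes in the test and acceptance runs (cohorts of 5–15 subjects,
  threshold step 0.02–0.04, 3×2 to 4×3 hyperparameter grids, k = 4–10
  folds) are the package's documented compact study scale; all structural
  counts (1,224 predictors, 840 s, 35 threshold sets) are invariant to it.

## Known limitations

* The correlation filter is computed on the full training partition before
  cross-validation, mirroring the target protocol; CV scores at low
  thresholds are therefore optimistically biased. The sweep's interior
  optimum emerges despite, not because of, this bias.
* Row-level CV folds ignore subject boundaries (the protocol's "divided
  into groups as equally as possible"); subject-level folds would give more
  conservative CV scores.
* The dependent r-difference test assumes joint normality of the two
  prediction series and the measured response.
* The generator's pathways are low-dimensional by design; real EEG carries
  many more partially informative features.
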