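# Methods

`frontoboost` re-implements, as a tested library, a sideline concussion
screening analysis: two-channel frontopolar EEG plus a short symptom
questionnaire, reduced to 20 observational variables and classified by
totally-corrective boosting, with leave-one-out cross-validation and a
class-prior-swept ROC family as the evaluation.  This note records the
models, the defaults and their rationale, the numerical choices, and
what the synthetic-cohort tests do and do not establish.

## Signal model and feature pipeline

Recordings are the voltage differences AF7–FpZ and AF8–FpZ at
fs = 256 Hz, about one minute of eyes-closed rest delimited by event
markers.  Preprocessing is zero-phase 4th-order Butterworth bandpass
(0.1–100 Hz), applied forward–backward so 1-s bin alignment is
preserved.  Artifact handling is removal, not correction: each detector
marks 1-s bins for exclusion.

* **Saturation / excursion / spike** — runs of ≥ 3 samples at the
  recorder rail (default ±400 µV); any sample ≥ 200 µV; single-sample
  steps > 100 µV.  Flagged samples are dilated by ±0.5 s before binning.
* **EMG** — per-bin power in the 70–128 Hz and 35–40 Hz monitor bands,
  flagged above `median + 5·MAD` of the segment with an absolute floor
  of 0.01 µV² (the floor keeps numerically silent monitor bands from
  registering as outliers).  Detection runs on the *unfiltered* signal:
  the 70–128 Hz monitor band lies above the 100 Hz low-pass corner.
* **Blink** — a simplified amplitude detector standing in for published
  template methods: the 0.5–5 Hz band's 500-ms peak-to-peak, thresholded
  at max(60 µV, `median + 5·MAD`).  The adaptive part prevents subjects
  with genuinely strong slow activity from being wholly masked.

No published cutoffs exist for these detectors; the MAD rules were
chosen so thresholds need no calibration data.  Manual inspection of
flags — inherently irreproducible — is replaced by an override table
(per-bin force-include / force-exclude, logged).

Spectra are per-second Hann-windowed periodograms (density scaling) at
exactly 1 Hz resolution, kept over 1–40 Hz; each bin is then averaged
with its two neighbouring bins (boundary and masked neighbours are
skipped).  Rectangular windows are used in tests where closed forms
exist (Parseval, sinusoid power); Hann is the analysis default because
it limits leakage into adjacent 1-Hz bins.  Band powers sum the 1-Hz
bins under a half-open `[lo, hi)` convention — delta 1–3, theta 3–7,
alpha 8–13, beta 13–30, sigma 12–15, gamma 25–40 Hz, with the printed
shared edges (3, 13, 25 Hz) resolved to the lower band's exclusive top.
Sigma deliberately overlaps alpha and beta.  The per-subject feature is
`log10(mean band power over valid bins)` — log of mean, reading the
averaging as preceding the logarithm; a mean-of-log option exists.
With 6 bands × 2 channels this yields 12 EEG features (`{band}_{L|R}`,
AF7 = left by the usual 10–10 convention).

The questionnaire contributes 8 variables: seven yes/no items (loss of
consciousness, headache, nausea/vomiting, light sensitivity, sound
sensitivity, confusion, memory dysfunction) coded 1/0, and the mean of
the seven 0–6 severities — divided by all 7 items, including
unendorsed ones (a mean-over-endorsed option exists).  A consistency
screen drops subjects contradicting their label (controls endorsing
≥ 5 items; mTBI subjects endorsing none), generalizing the cohort
cleaning a clinical study would do ad hoc into a reproducible rule.

## Classifier

The classifier is totally-corrective boosting over axis-aligned
depth-1 stumps (thresholds at midpoints of sorted unique values).
Round t selects the stump maximizing the weighted edge
γ_t = Σᵢ dᵢ yᵢ h(xᵢ), then replaces d with the minimum-relative-entropy
distribution (reference: the class-weighted prior d⁰) satisfying
*all* accumulated edge constraints ≤ γ_min − ν, where γ_min is the
smallest selection-time edge so far and ν (default 0.01) the edge
slack.  The constraint bound tightens every time the best edge fails
to violate it, so termination is by *projection infeasibility*: the
chosen stumps then certify the bound has crossed the best achievable
margin, and the multipliers of the last feasible projection are the
margin-maximizing stump coefficients.  Secondary stops: no stump with
edge > ν (no weak learner left), or the 200-learner budget.

The projection is solved on its smooth convex dual,
min_{α≥0} log Σᵢ d⁰ᵢ exp(−(Uᵀα)ᵢ) + bound·Σα, by a damped projected-
Newton iteration with the explicit t×t Hessian, warm-started across
rounds, with an L-BFGS-B fall-back if Newton stalls; tolerance 1e-8 on
constraint violation.  An infeasible primal shows up as the dual
running to −∞ (detected at −60 in log units, i.e. primal mass below
e⁻⁶⁰).  A stump that separates perfectly (edge 1) makes even the first
projection infeasible; it alone is then the model.  The fit contains
no randomness: equal-edge ties break lexicographically by (variable
index, threshold), so all cross-validation results are exactly
reproducible and independent of subject order.

Scores are the normalized ensemble vote Σ αₜhₜ(x)/Σ αₜ ∈ [−1, 1]; the
class boundary is 0, and an exact 0 counts as an mTBI prediction
(fail-safe toward removal from play; configurable).  Class priors
enter as the reference distribution of the projection, which is how
the ROC stage sweeps class weights.  Parity-style label patterns
(XOR) are outside the hypothesis class — nonnegative combinations of
axis stumps are additive functions — and the fit then correctly stops
with an empty ensemble.

Evaluation: leave-one-out cross-validation (one fold per subject;
folds are deterministic; a fold whose training half loses a class is
skipped with a warning), resubstitution accuracy on the full-data
model, and the exhaustive symptom-subset search (all 2⁸ = 256 symptom
subsets joined to the 12 EEG variables, each scored by LOOCV).

## ROC family

Because deployment priors are unknown, the classifier is re-run under
19 relative class weightings — the distinct ratios {1:k} ∪ {k:1},
k = 1..10, which is the unique reading of an integer 1–10 sweep that
yields 19 members.  Each weighting's held-out scores give one ROC
member (threshold sweep; AUC = the Mann–Whitney statistic; ties step
diagonally).  The family is summarized by vertical averaging — TPR
interpolated onto a common 101-point FPR grid, pointwise mean/min/max
— and by the member AUCs' mean/min/max; both the envelope curves and
the AUC range are emitted because either convention is defensible.
The randomization control permutes whole EEG feature rows across
subjects (preserving within-EEG correlation structure) and re-measures
the combined family AUC; if the EEG block contributes through its
within-subject pairing with class and symptoms, the permuted combined
AUC falls back to the symptoms-only AUC.

## Synthetic cohort generator

No public dataset accompanies this kind of analysis, so the package
ships a generator whose defaults are the study conditions the
analysis assumes: 38 mTBI + 47 controls, 60 s at 256 Hz.  Each subject
is a sum of per-band narrowband Gaussian processes (4th-order
Butterworth-filtered white noise, unit-RMS, scaled by a subject-level
amplitude) plus 1/f-amplitude background noise (5 µV RMS, flat below
1 Hz).  Subject band amplitudes are log-normal around an eyes-closed
frontopolar profile (RMS µV: delta 6, theta 4, alpha 6, beta 3,
sigma 2, gamma 1.5; SD 0.2 dex; draws truncated at ±2.5 SD because
unbounded log-normal tails produce physiologically absurd amplitudes),
shared across channels up to a 0.05-dex left/right jitter so the L/R
features correlate.  The class enters the EEG as a *downward* shift of
all band log-amplitudes for mTBI subjects by `eeg_class_effect`
within-class SDs — band powers are weakly anti-correlated with the
class vector, as the variable screen shows.  A pure-sinusoid
oscillator mode exists for closed-form tests (band power = A²/2).

Symptom answers are Bernoulli with class-dependent endorsement
probabilities, and severities are truncated-geometric on 1–6 (zero
when unendorsed).  The default endorsement/severity parameters were
calibrated once so the symptoms-only classifier operates in the
regime the analysis assumes — LOOCV accuracy near 0.8 — rather than at
ceiling; with the default weak EEG effect (0.35 SD) the EEG block
alone is near chance on short recordings and mildly informative at
the full 60 s.  Artifacts are injected at `round(rate × minutes)`
events per kind with seeded placement and morphology (biphasic
Gaussian-derivative blinks 300–500 ms / 50–150 µV on both channels;
35–128 Hz EMG bursts at ~25 µV RMS; rail plateaus; 250–350 µV slow
excursions; ±150–300 µV single-sample spikes), every event recorded
as ground truth, so detector recall and false-flag rates are exact.

What the generator does *not* model: real scalp EEG nonstationarity,
age/sex covariates, volume-conduction structure, or within-class
correlation between EEG amplitudes and symptom severity.  The last
point matters for interpretation: in this generator the EEG and
symptom blocks are conditionally independent given the class, so a
combined-model advantage appears only when the EEG block carries class
signal of its own ("informative" cohorts, `eeg_class_effect ≈ 1`).
Passing tests therefore show the pipeline's machinery is correct and
directionally faithful, not that real frontopolar EEG carries the
effect sizes reported on any particular clinical cohort.

## Problem sizes used in tests

Simulation-heavy checks run at reduced scale, chosen as the smallest
sizes at which the tested property is stable: 12–20 s recordings for
feature tests; 26-subject cohorts with `eeg_class_effect = 1.0`,
16 s recordings and a 40-learner / ν = 0.02 configuration for the
family-AUC directionality and randomization checks (10 seeds, sign
test); 60-subject cohorts for the class-effect monotonicity property;
full 85-subject, 60 s, 200-learner cohorts for resubstitution
saturation.  The acceptance script runs the full default conditions.

## Known limitations

* The boosting oracle equivalence is verified for n ≤ 8, d ≤ 2; for
  larger problems only invariants (determinism, monotone training
  error, score bounds) are checked.
* EDF support writes 16-bit files with a fixed epoch date and requires
  whole-second recordings; reading goes through `mne`.
* The symptom-subset search reruns full LOOCV per subset (256 ×
  n fits); at the full 85-subject scale this is minutes of compute,
  so tests exercise it on small cohorts.
* The weight-swept family reuses the same LOOCV fold structure per
  weighting; members are therefore correlated, which is intrinsic to
  the design, not a defect.
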