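# Methods

`wearhrv` models a laboratory wearable-sensing protocol: subjects wearing a
single-lead chest ECG (256 Hz) and a wrist accelerometer (128 Hz) perform
six activities — sitting (SI), standing (ST), walking (WK), ascending (AS),
running (RU) and post-exercise rest (REST) — in 5-minute static and
10-minute dynamic sessions, with a REST session after each dynamic one.
Every stage below operates per minute, the common window that ECG-derived
heart-rate variability (HRV) needs and accelerometer features tolerate.

## Synthetic cohort

No public recordings exist for this protocol, so the package ships a
generator whose defaults *are* the study conditions and which carries its
own ground truth (true R-peak times, true per-minute covariates, known EE
coefficients) so that every downstream stage can be checked against truth.

**Cardiac model.** RR intervals follow a stationary per-activity mean plus
one LF-band (0.095 Hz) and one HF-band (0.25 Hz) sinusoidal modulation plus
white jitter. Two sinusoids are the simplest mechanism that gives a
controllable spectral-domain truth for the frequency-analysis stage.
Class-conditional window-mean statistics (mean ± SD of per-minute mean RR,
seconds) are SI 0.86 ± 0.12, ST 0.77 ± 0.10, WK 0.61 ± 0.08, AS 0.47 ±
0.07. RU (0.40 ± 0.05) is an extrapolation continuing the intensity trend,
and REST is modelled as exponential recovery from the preceding dynamic
activity's RR toward the subject's SI baseline with τ = 90 s — a stand-in
for post-exercise physiology, not a measured value. Mean heart rate follows
as 60/RR; by the delta method the implied class HR statistics (e.g. SI
69.8 ± 9.7, ST 77.9 ± 10.1 bpm) closely track the RR parameterization.
The class SD is split 0.8 : 0.6 (in quadrature) into a between-subject
offset — one standard-normal draw per subject, so a slow heart is slow in
every activity — and window-to-window wander.

**ECG waveform.** One Ricker (Mexican-hat) pulse per beat, σ = 15 ms,
truncated at ±40 ms, so each beat has a single unambiguous maximum exactly
at the R time; configurable baseline wander (0.25 Hz) and white noise on
top. P/T waves, respiration coupling and electrode artifacts are
deliberately out of scope: the waveform exists to exercise the detector,
not to fool a cardiologist.

**Movement model.** Static activities are gravity plus low-amplitude white
noise; dynamic activities add a gait sinusoid with a second harmonic,
dominantly on the gravity-aligned axis (vertical impact dominates
locomotion, and this keeps the gait fundamental visible in the magnitude
signal), with amplitudes ordered WK (0.35 g at 1.8 Hz) < AS (0.60 g at
2.0 Hz) < RU (1.10 g at 2.5 Hz), jittered ±10–15 % per subject.

**Energy expenditure.** Reference EE (kcal/min) is a known linear function
of true per-minute covariates, separate for the static and dynamic
categories, plus homoscedastic Gaussian noise (0.30 / 0.80 kcal/min) —
matching the assumptions of the OLS stage it feeds. The default static
model uses height, weight, spectral energy and mean HR; the dynamic model
weight, movement rms and mean HR. A second constructor builds a static
truth on the variable set {height, weight, energy, mHR, LF, Lmean, REC}
for coefficient-recovery experiments. In the raw-signal path the movement
covariate is an analytic proxy (0.73 × gait amplitude + noise floor); its
mismatch with the extracted rms is linear-ish and absorbed by regression.

**Two fidelity levels.** `generate_cohort` produces raw waveforms and is
the substrate for end-to-end runs; `simulate_minute_table` draws the
per-minute feature table directly from the same class-conditional truth
(mRR from the class statistics, mHR = 60000/mRR plus 1 bpm jitter, the
other 29 HRV features class-independent noise with physiologically typical
levels, movement features from overlapping class distributions). The fast
path exists because the Monte-Carlo suites need hundreds of cohorts;
conclusions that depend on detector or windowing behaviour are always
checked on the raw path.  The two paths emphasise different realism: the
raw path produces movement classes cleaner than real wrist data (so
recognition on it sits near ceiling and the configured amplitude ordering
is strictly preserved), while the fast path draws overlapping SI/ST and
WK/AS movement distributions to reproduce the confusable-pair structure
that motivates adding HRV features. What passing tests on either path shows is that
the *pipeline machinery* is correct under the modelled conditions; neither
path models sensor dropout, motion artifacts in the ECG, non-stationary
gait, or inter-subject HRV differences beyond mean level, so accuracy
figures on synthetic cohorts are not predictions for real wearables.

## ECG → RR

Pan-Tompkins-style detection: 5–30 Hz zero-phase Butterworth band-pass,
derivative, squaring, 150 ms moving-window integration, adaptive
signal/noise threshold (running 0.125/0.875 updates), 250 ms refractory
period; each detection is refined to the band-passed local maximum, making
clean-signal peak times sample-exact. There is no search-back stage; on
the clean synthetic signals it would never fire. Intervals outside
300–2000 ms are dropped without interpolation (the count is recorded) —
a simpler artifact dialect than commercial HRV software's correction
levels. Minute windows are anchored at session start; an interval belongs
to the window containing its terminating peak; a trailing partial window
is discarded.

## HRV parameters (31 per window)

Time domain: mRR, SDRR, mHR, SDHR, RMSSD, NN50 (|ΔRR| > 50 ms), pNN50 =
100·NN50/N. Sample SDs (ddof = 1) everywhere; pNN50 divides by the number
of intervals in the window.

Frequency domain: the tachogram (RR vs terminating-peak time) is resampled
at 4 Hz by cubic spline, mean-removed, and Welch-estimated (32-s Hann
segments, 50 % overlap). Band powers integrate the PSD over VLF (0–0.04],
LF (0.04–0.15], HF (0.15–0.4] Hz by trapezoid with edge-interpolated PSD
values (so a band containing a single bin still has finite power); band
peaks are the argmax frequency. Relative powers use the band-limited total
pVLF+pLF+pHF (full-spectrum denominator selectable), hence prcVLF + prcLF
+ prcHF = 100 by construction. nLF = pLF/(pLF+pHF), nHF its complement,
LF/HF = pLF/pHF. A one-minute window holds at most ~2.4 VLF periods, so
the VLF triple is always flagged `unreliable-window` at this window
length. Zero-power windows return flagged zeros, never silent ones.

Nonlinear: Poincaré SD1/SD2 are the sample SDs of (RR_{n+1} ∓ RR_n)/√2;
the exact relation SD1² = M/(M−1)·(RMSSD² − d̄²)/2 (M successive
differences, d̄ their mean) is asserted in tests. ApEn/SampEn use m = 2,
r = 0.2·SDRR, Chebyshev distance, self-matches included/excluded
respectively; degenerate windows return flagged conventions (0 for
constant series; a −ln(2/((N−m−1)(N−m))) ceiling when no matches). DFA
integrates the centred series and fits log F(n) against log n over boxes
4–16 (Alpha1) and 17–64 (Alpha2); box sizes must fit twice, and Alpha2 on
windows below 70 beats is estimated from the usable sizes but flagged
`short-window`. D2 is the Grassberger–Procaccia slope (embedding m = 10,
delay 1, Euclidean) over the central half of a log-spaced radius grid
spanning the 5th–95th distance percentiles. RQA (m = 10, delay 1, radius
√m·SDRR, lmin = 2) reports REC over the M(M−1) off-diagonal pairs and
diagonal-line statistics excluding the line of identity; note that on a
finite matrix DET < 100 even for a constant series, because the two
single-point corner diagonals can never join a line of length ≥ lmin.

## Movement features (4 per minute)

Vector magnitude → non-overlapping 2-s windows (256 samples) → per window:
rms of the raw magnitude (gravity included — on the mean-removed signal
rms and SD would be exactly proportional and the feature set degenerate),
then on the mean-removed magnitude the sample SD, dominant frequency
(largest non-DC FFT bin; 0 for a silent window) and spectral energy
Σ_{k≠0}|X_k|²/N, which equals the time-domain sum of squares by Parseval.
The 30 window vectors of a minute are averaged; minutes with fewer than 25
windows are flagged missing. The magnitude combination (rather than
per-axis features) gives exactly four orientation-robust features;
per-axis extraction would triple the dimension and is not needed by any
consumer here.

## Recognition

Five scenarios: movement only (4 features), movement + all HRV (35), movement +
selected HRV, HRV only (31), selected HRV only. Classes are the five
non-REST activities. Cross-validation is leave-one-subject-out with a
validation subject: test subject i, validation subject i+1 (cyclic) —
deterministic and leakage-free — and the remaining n−2 train. Per fold,
the z-scaler (sample SD; zero-variance features get unit scale; flagged-
missing values are imputed at the training mean), the Mann-Whitney feature
ranking, and the classifier are fit on training subjects only; the
validation subject picks hyperparameters (C ∈ 4^{0..10}·2⁻⁵, γ ∈
4^{0..9}·2⁻¹⁵, kNN k ∈ {1,3,5,7,9}) and, in selected-feature scenarios,
the feature count k (default grid 1–5). Ties prefer fewer features, then
smaller hyperparameters, making the whole driver deterministic.

Feature selection scores each HRV parameter by the *larger* of its two
Mann-Whitney p-values for SI-vs-ST and WK-vs-AS — the two pairs movement
features cannot separate — so a selected feature must discriminate both.
Under the default generator this ranks mRR and mHR first. The U test uses
exact enumeration for untied samples of ≤ 8 each, else the tie-corrected
normal approximation.

Classifiers: linear-kernel and RBF-kernel SVMs and kNN come from
scikit-learn; linear discriminant analysis is implemented in closed form
(pooled within-class covariance with a 10⁻⁸·tr(S)/p ridge) so one
classifier in the comparison is fully transparent to hand verification.

Metrics: per-class recall and precision (flagged NaN for never-predicted
classes) and overall accuracy from the pooled confusion matrix, reported
in the RC-column / PR-row table layout.

## Energy expenditure

OLS with intercept, coefficients by the normal-equations solution
(computed via an orthogonal decomposition), classical t-based p-values and
R². Variable selection is backward elimination: drop the largest-p
variable while any p ≥ 0.05 (forward selection available). Note that with
α = 0.05 the *exact* planted-support recovery rate is bounded by
(1−α)^{#nulls}; tests assert containment of the true support plus the
binomial false-positive expectation. Four families: single vs
activity-specific (separate static {SI, ST, REST} and dynamic {WK, AS, RU}
fits, routed by true category) × movement-only (6 candidates: height,
weight, 4 movement) vs movement+HRV (37). EE folds have no validation
subject (n−1 train, 1 test). Regression uses raw (unnormalized) features
by default so coefficients stay in interpretable units. Performance is
RMSE per activity per fold; the four families are compared by a balanced
two-way fixed-effects ANOVA (factors data type and model type, with
interaction) over the fold × activity RMSE cells — 13 folds × 6 activities
× 4 models gives error df 308.

## Problem sizes and determinism

Default cohorts are 13 subjects × 55 labelled minutes (40 of them over the
five recognition classes, 520 pooled across folds). Monte-Carlo suites use
the minute-feature path with 20 seeds (scenario ordering) and 100 seeds
(EE ordering, feature-selection recovery); oracle-equivalence tests use
series of ≤ 200 beats where the O(N²) brute-force references are exact.
Every random quantity flows from one integer seed through
`numpy.random.default_rng`; identical (config, seed) pairs reproduce
byte-identical cohorts, reports and artifacts.

## Known limitations

* The ECG morphology is a single symmetric pulse; detector performance on
  real ECG (muscle noise, ectopy, electrode motion) is untested here.
* REST recovery kinetics and the RU cardiac statistics are modelling
  choices, not measurements.
* Spectral HRV values depend on the estimator; a different PSD method
  (autoregressive, Lomb-Scargle) would shift band powers, and the VLF
  triple is structurally unreliable at one-minute windows.
* The activity-specific EE models are evaluated with true category
  routing; routing by predicted activity is available but couples the two
  task's errors and is not part of the evaluated contract.
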