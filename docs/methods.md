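# Methods

## Problem setting

Six mobility activities — Sitting, Lying, Standing, Stairs Up, Stairs Down,
Walking — are classified from a waist-worn smartphone's accelerometer and
gyroscope (~60 samples/s, irregular) and barometer (6 samples/s). Subjects
self-label activity bouts; the pouch position on the waist is
unconstrained, so the phone's orientation relative to the body is arbitrary
and varies between sessions. The analyses compare training sources:
healthy vs stroke cohorts (population designs), stroke test subjects
stratified by gait impairment from 10-meter-walk-test speed (mild
> 0.8 m/s, moderate 0.4–0.8 m/s, severe < 0.4 m/s), and lab vs home
sessions (environmental designs).

No recordings from the original study are available, so the package ships a
generative stand-in and evaluates the pipeline's *qualitative* behaviour on
it. Every coefficient below is a design choice for plausibility, not an
estimate from human data.

## Generative model (`synthetic_data`)

Signals are synthesized in a body-fixed frame and rotated by a per-subject
random orientation; each session re-draws a small orientation wobble
(SD 8°, scaled by the home-variability multiplier) to mimic pouch
repositioning. Timestamps carry 2 ms Gaussian jitter around the nominal
60 Hz (5 ms at 6 Hz for the barometer), so downstream resampling is always
exercised on irregular input.

* **Stationary activities**: gravity (9.81 m/s²) along a posture-specific
  direction (standing upright, sitting reclined ~25°, lying near-horizontal)
  plus low-pass-filtered sway (2nd-order Butterworth at 1.5 Hz; SD 0.02–0.045
  m/s² by posture) and white sensor noise (SD 0.002 m/s²).
* **Gait**: cadence `f = 0.5 + 1.2·v` Hz and vertical amplitude `a = 2.0·v`
  m/s² for gait speed `v` (m/s), with a second harmonic at 0.4·a, reduced
  anterior-posterior and mediolateral components, and smooth cycle-to-cycle
  frequency/amplitude modulation whose relative SD falls with speed
  (`clip(0.18 − 0.10·v, 0.03, 0.18)`). Stair gait uses factors 0.95
  (cadence) and 0.85 (amplitude) relative to level walking — deliberately
  close, since stairs and walking are near-identical inertially and are
  separated mainly by the barometer. Because amplitude and cadence shrink
  toward the standing model as `v → 0`, severely impaired walking is
  intrinsically close to stationary signal: this single mechanism produces
  the impairment-graded ambulatory-as-stationary confusion the evaluation
  designs measure.
* **Barometer**: baseline 1013 hPa with slow ambient drift and noise
  SD 0.03 hPa; stairs add a linear trend of 0.115 hPa per vertical meter
  (pressure-lapse approximation) at a climb speed `0.08 + 0.22·v` m/s —
  negative during ascent, positive during descent; altitude persists after
  the bout.
* **Data pathologies**: with configurable rates per bout — phone-handling
  artifacts (1–3 s of broadband noise, SD 6 m/s² accel / 2.5 rad/s gyro, at
  both bout edges; rate 0.25), label swaps to a random other activity
  (rate 0.03), and whole-bout drop (rate 0.05). Ground truth for all three
  is carried on the in-memory bouts and the cohort manifest for testing.
* **Cohorts**: healthy gait speeds ~ N(1.3, 0.1) m/s truncated at 0.9;
  stroke speeds uniform within stratum ranges (mild 0.85–1.20, moderate
  0.45–0.78, severe 0.18–0.38). Stroke subjects record Lab1, Home, Lab2
  sessions; healthy subjects record at home with doubled bout counts. Home
  sessions multiply sway/variability/noise SDs by 1.5, slow gait by ×0.92,
  and use a different bout mix (more sitting and walking). Bout durations
  (26–44 s) give every activity comfortable margin over the 60 s
  environmental-eligibility rule even when one bout is lost.

What the generator does **not** emulate: real biomechanics (double support,
asymmetric hemiparetic gait, turning), sensor saturation and temperature
drift, posture transitions inside bouts, GPS/community movement, and
free-living label noise beyond whole-bout swaps. Passing the qualitative
acceptance checks therefore shows the *pipeline* responds correctly to the
encoded mechanisms — not that it would attain any particular recall on real
stroke data.

## Preprocessing

Streams are resampled by linear interpolation onto uniform grids (inertial
50 Hz, barometer 6 Hz; grid anchored at the first sample, no
extrapolation). Duplicate timestamps keep the first occurrence; NaN and
non-monotone rows are dropped with a logged count.

**Entropy trimming.** Self-labeling requires handling the phone, which
pollutes bout edges with broadband noise. Sample entropy
`SampEn(m, r) = −ln(A/B)` of the accelerometer norm separates signal
regimes: quasi-periodic gait ≈ 0.3, smooth stationary signal ≈ 0.3–1.1,
broadband handling noise ≈ 2.2 (m = 2, r = 0.2·SD, both template lengths
counted over the same n−m positions). Each bout end is scanned with a 1-s
subwindow sliding at 0.1 s; the trim extends to the end of the last window
exceeding the activity's threshold (stationary 1.3, ambulatory 0.8), capped
at 5 s per end. Two numerical guards matter: (i) the tolerance uses
`r = 0.2·max(SD_window, 0.02 m/s²)` — without the floor, near-still windows
are scored against their own sensor-noise floor and read as irregular;
(ii) the window must be no longer than the shortest artifact (hence 1 s,
not 2 s), because a window whose SD is inflated by partial artifact content
matches almost everything within its tolerance and reads as *regular*.
Measured on the generator: 0/96 clean bouts trimmed; mean artifact removal
100%, mean clean-signal loss 0.07 s.

**Mislabel filter.** Ambulatory-labeled bouts whose accelerometer-norm SD
over the bout is below 0.05 m/s² cannot be genuine gait (generated walking
at even 0.2 m/s has SD ≈ 0.4 m/s²) and are removed; stationary labels are
never dropped by this rule.

**Segmentation.** Trimmed bouts are cut into 10-s clips starting every 1 s
(90% overlap), `floor(T − 10) + 1` clips for duration T ≥ 10 s. Clips are
resampled onto grids anchored at the trimmed bout start: exactly 500
samples × 3 axes per inertial sensor and 60 barometer samples per clip.
Clips never span bout boundaries.

## Feature catalogue

Per inertial axis (×3 axes × 2 sensors): mean, range, IQR; population SD,
skew, non-excess kurtosis; fractions of z-scores in [−2,−1), [−1,0), [0,1),
[1,2]; first-difference derivative moments (mean, SD, skew, kurtosis);
periodogram moments; and mean power in twenty 0.5 Hz bands over 0–10 Hz —
38 per axis. Cross-axis per sensor: Pearson r for xy/xz/yz; raw mean cross
products `mean(a·b)` and normalized `mean(a·b)/(rms(a)·rms(b))` (bounded in
[−1,1], not mean-centered — distinct from Pearson r); absolute variants
with `|a·b|`; mean squared norm; sum of axial SDs. Total 131 per inertial
sensor. Barometer: derivative moments, SD, range, IQR, OLS slope vs time —
8. Grand total 270.

Conventions decided here (the source tables name the statistics but not
these details): the periodogram is the one-sided DFT periodogram of the
mean-removed 500-sample clip (0.1 Hz resolution; band power = mean ordinate
in [b, b+0.5) Hz; spectrum moments over all ordinates to 25 Hz);
derivatives are first differences divided by the sample period; z-score
histogram counts are reported as fractions of clip length; degenerate
(zero-variance) channels define skew, kurtosis, z-scores and correlations
as 0 rather than NaN, with variance compared against a relative tolerance
so that numerically constant signals behave like constants.

Feature selection ranks features by out-of-bag permutation importance in a
bagged-tree ensemble whose per-tree training sets are class-balanced
bootstrap undersamples (drawn with replacement so OOB sets exist even on
balanced data); importance is the mean OOB error increase under
single-feature permutation, normalized by its SD across trees. The default
selection size k = 151 mirrors the reference analysis, but the surviving
set is data-dependent and not a stable artifact.

## RUSBoost

AdaBoost.M2 over CART trees (Gini, exhaustive splits, no depth limit,
minimum leaf 5). Weights live on (instance, wrong-label) pairs. Each
iteration draws a class-balanced undersample (default target: minority
count; with replacement only when a class is smaller than the target; a
class exactly at the target contributes all its instances), fits a tree
with the current instance weights, computes the pseudo-loss ε on the full
weighted set, stops if ε ≥ 0.5, updates weights by `β^(lr·0.5·(1+h_true−h))`
with `β = ε/(1−ε)`, and records learner weight `lr·ln(1/β)`. ε = 0 assigns
a capped weight ln(1e10) and stops. Prediction is the argmax of the
weighted sum of tree class-probability outputs, normalized to sum to 1;
ties break to the alphabetically first class. With one iteration, balanced
data and a full-size undersample, the procedure reduces exactly to a single
decision tree — an equivalence the tests assert. The plain random-forest
baseline delegates to a standard bagged forest with the same leaf size.

Models persist as a documented JSON format (node arrays per tree plus
learner weights); loading reconstructs prediction without the original
training environment.

## Evaluation designs

* **Population**: LOSO within a cohort; Healthy-to-Stroke trains once on
  the full healthy pool and scores each stroke subject. Mean recall is the
  unweighted mean over classes present in the test set (absent classes are
  omitted, not scored 0), and cohort-level values average per-subject mean
  recalls — matching the per-subject t-tests.
* **Impairment**: the per-subject confusions of a population design pooled
  within mild/moderate/severe strata; rates from the pooled matrices.
* **Environmental**: subjects with ≥ 60 s of every activity in every
  session (computed from trimmed bout durations); classes merged to four
  (Sitting+Lying → Sedentary, the two stair classes → Stairs). Personal
  models: Lab1→Lab2, Lab1→Home, and Home-to-Home via four chronological
  contiguous folds where any clip whose 10-s span overlaps a clip of
  another fold is dropped, so no raw sample crosses a fold boundary.
  Global models: LOSO over the eligible pool per session pairing.
* **Learning curve**: for each training-pool size, sample subjects, draw
  exactly 1200 instances from their pooled clips, train, and score held-out
  subjects; mean and percentile 95% CI over repetitions (default 100).
* **Ablation**: identical LOSO with and without the 8 barometer features.
* **Statistics**: paired t (shared subjects), two-sample t (different
  cohorts), one-way ANOVA with Tukey HSD across strata, Pearson r between
  gait speed and per-subject metrics; α = 0.05.

## Problem sizes and runtime choices

The desk-scale study (`pipelines.desk_cohort_spec`) uses 8 healthy and 6
stroke subjects per stratum (18 stroke), ~45 bouts per stroke subject
across three sessions, ≈ 30,000 instances per cohort — enough for stable
qualitative effects on one CPU in ~1 minute per seed. The evaluation
designs at this scale run RUSBoost with 50 trees and an undersampling
target of min(minority, 150); `ModelConfig` defaults remain the reference
configuration (200 trees, minority-count target). The learning-curve
default is 100 repetitions. Acceptance checks average the qualitative
designs over five generator seeds (tests) or three (`scripts/acceptance.py`).

## Known limitations

* Generator coefficients are stand-ins; absolute recalls have no clinical
  meaning, only the ordered/contrast effects do.
* The entropy-trimmer thresholds are calibrated to the generator's
  separation (clean ≤ ~1.2 vs artifact ~2.2) and would need re-tuning for
  real hardware.
* Sum-of-axial-SDs is not rotation invariant (only the sum of variances
  is); it is retained as catalogued, and orientation-robustness is carried
  by the norm-based features.
* Chronological Home-to-Home folds come from a single home session, so
  personal Home models see temporally adjacent (though sample-disjoint)
  behaviour and may flatter home training slightly.
* The mislabel filter only catches ambulatory labels over stationary
  signal — the one direction detectable from signal flatness alone.

One fold-level pragmatic rule: if a training fold contains fewer than
`min_leaf` instances of some class (possible in the short chronological
Home folds), that class is dropped from that fold's training set and its
test instances necessarily score as errors; the model itself always
enforces at least `min_leaf` instances per trained class.
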