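# Methods

This note documents the models, defaults and design choices behind
`gaitspeed`, what the synthetic data generator does and does not emulate,
and the limitations a user should keep in mind.

## Signal model and preprocessing

Recordings are tri-axial acceleration in G at 50 Hz with strictly
increasing timestamps. The mounting convention fixes the device Z axis
roughly anterior (thigh, shank) or posterior (sacrum); rotation about Z
(yaw) is unconstrained, which is why all in-plane information enters the
pipeline only through the magnitude XY = √(X² + Y²). XY is computed after
filtering so the magnitude nonlinearity cannot fold high-frequency content
into the pass band.

Filtering uses a 4th-order Butterworth applied forward-backward
(`scipy.signal.sosfiltfilt`), i.e. zero phase, because phase distortion
would corrupt the time-domain features. Two variants are kept per axis:

| channel | band | carries |
|---|---|---|
| low-pass | ≤ 12 Hz | gait dynamics plus the gravity component |
| band-pass | 0.25–12 Hz | gait dynamics only (DC/gravity removed) |

The 12 Hz cutoff retains the frequency content of human gait; the 0.25 Hz
lower edge removes gravity and posture drift. The filter family and order
are this package's choice — they are standard in gait analysis, and both
are configurable (`filter_order`, `lowpass_cutoff_hz`, `band_hz`).

Filtering runs over the whole recording before windowing to avoid
per-window edge transients; the first and last 2 s of each filtered
recording are excluded from any window because forward-backward filtering
distorts the edges (recordings are expected to carry a run-in margin, e.g.
the treadmill ramp, around the annotated test). Windows are 5 s
(250 samples), non-overlapping, aligned to the annotated test start, with
the trailing remainder dropped — ⌊duration/5 s⌋ windows per test, so a
360 s test yields exactly 72. Windows overlapping a sampling gap larger
than 2/fs are dropped because the features assume contiguous 250-sample
blocks.

## Feature set

Each window yields 32 features per device location, in a fixed registry
(exported by `gaitspeed.features.export_registry`):

* slots 1–20: {mean, range, excess kurtosis, signal entropy, autocovariance
  range} × {z_lp, xy_lp, z_bp, xy_bp};
* slots 21–22: Pearson r of XY with Z, per filter;
* slots 23–30: {spectral entropy, dominant frequency, dominant-frequency
  power, energy ratio} × {z_bp, xy_bp};
* slots 31–32: spectral entropy of z_lp and xy_lp.

Dominant-frequency statistics are not computed on low-pass channels (their
spectra are DC-dominated and the statistics would be uninformative);
spectral entropy, which is scale-invariant, is retained for them. Several
32-slot assignments of the named statistic families are possible; the
registry is configurable so an alternative can be swapped in.

Numerical conventions, chosen for boundedness and degenerate safety:

* **kurtosis** — population excess kurtosis (normal → 0); a constant
  window maps to 0.
* **signal entropy** — Shannon entropy in bits of a 20-bin histogram over
  the window's own min–max range, with 0·log 0 := 0; range [0, log₂20],
  constant window → 0.
* **autocovariance** — biased (1/N) estimator over lags 0–125 (0–2.5 s at
  50 Hz), guaranteeing a positive-semidefinite sequence; 2.5 s covers at
  least one stride at all speeds of interest; the feature is max − min.
* **correlation** — Pearson r, defined 0 when either window is constant.
* **spectrum** — single-segment Hamming periodogram zero-padded to 512
  points (grid ≈ 0.098 Hz); 5 s windows are too short for multi-segment
  averaging at useful resolution. Band mask 0.25–12 Hz inclusive.
  Dominant-frequency ties break toward the lowest frequency; an all-zero
  band maps to (0, 0, 0, 0). "Energy ratio" is single-bin power over total
  band power; note that zero-padding spreads a pure tone's main lobe over
  several grid bins, so even a noiseless sinusoid has an energy ratio of
  about 0.33, versus ≤ 0.1 for white noise — the contrast, not the
  absolute value, is what carries information.

All 32 entries are finite by construction; non-finite values are treated
as errors, never silently repaired.

## Regression model

An ε-support-vector regression (scikit-learn `SVR`) maps the concatenated
feature vectors of an ordered location combination (32·|combo| columns) to
window speed. Features are standardized to zero mean / unit variance using
statistics from the training rows only — kernel methods need comparable
scales, and computing the statistics inside each cross-validation fold
avoids leakage. Hyperparameters default to the common regime for
standardized features: RBF kernel, C = 1.0, ε = 0.1 m/s, bandwidth
γ = 1/(M · pooled feature variance) (`gamma="scale"`); all are
configurable, and no hyperparameter search is performed. Quiet-standing
windows enter training labelled 0 m/s, anchoring the low end of the
regression; predictions are floored at 0 m/s since speed is non-negative.
Test-level estimates are the median across the test's windows, which is
robust to occasional outlier windows.

The fit is deterministic given the data and configuration; design rows are
put in a canonical (subject, test, window) order before fitting so results
do not depend on input row order. Windows missing any location of the
combination are dropped (logged).

## Evaluation

* **LOSO** — every subject is held out once; the fold model (including
  standardization) never sees the held-out subject's rows. The impaired
  cohort is evaluated by a single model trained on the full normal cohort,
  with no per-subject refitting.
* **Error convention** — error = estimate − truth; positive bias means
  overestimation.
* **RMSE** over test-level medians; satisfies RMSE² = bias² + population
  variance of the errors.
* **Bland-Altman LOA** — mean difference ± 1.96 × sample SD of the
  differences; the 95% interval for the disagreement between the two
  measurements, read as the minimal detectable change.
* **Agreement regression** — OLS of truth on estimate; the 95% confidence
  band is a percentile bootstrap over test pairs (default 1000 resamples,
  seeded). Degenerate resamples with zero estimate variance fall back to
  the point fit.
* **Clinical validity** — Pearson r with two-sided p from the t
  distribution (n − 2 df); zero-variance inputs are reported as
  undefined rather than coerced. Impairment groups follow the
  Timed-25-Foot-Walk comfortable-speed thresholds (Mild ≥ 1.1 m/s,
  Severe ≤ 0.7 m/s, Moderate between); subjects without that speed are
  excluded from grouped analyses with a warning. The fall comparison uses
  a two-sided Mann-Whitney U, exact when the smaller group has ≤ 8
  subjects and no ties, otherwise the tie-corrected normal approximation.

## Synthetic data generator

The generator produces the statistical structure the features measure, not
biomechanics. A shared stride phase drives K = 4 harmonics of the step
frequency on each channel, on top of a static gravity projection and white
Gaussian noise (SD 0.02 G), with:

* cadence: step frequency = 0.8 + 0.9·speed Hz (1.7 Hz at 1.0 m/s), plus a
  per-subject offset (SD 0.05 Hz);
* amplitude: ∝ location gain (sacrum 0.18, thigh 0.35, shank 0.55 G) ×
  per-subject lognormal multiplier (SD 0.15) × speed^0.8; zero when
  standing;
* arbitrary per-placement yaw, exercising orientation invariance end to
  end;
* impairment severity ∈ [0, 1]: smooth cycle-time jitter
  (SD 0.02 + 0.12·severity), alternate-step amplitude asymmetry
  (25%·severity) and harmonic attenuation (30%·severity).

Default study conditions are 17 normal subjects, six-minute tests at 0.5,
0.75, 1.0, 1.25 and 1.5 m/s plus six 30 s standing bouts; the impaired
cohort is 30 subjects with three 6MWTs at a comfortable speed (1.4 −
0.9·severity m/s plus noise) and ±20%. Clinical scores are monotone noisy
functions of severity (MSWS = 0.2 + 0.7·severity, EDSS_SR = 7.5·severity,
T25FW speed ≈ comfortable speed; fall probability 0.15 + 0.55·severity),
chosen to exercise the concurrent-validity code paths — they are synthetic
and not calibrated to the clinical literature. Each trial recording
carries a 10 s lead-in/lead-out (the treadmill ramp), so annotated windows
sit clear of filter edge transients. All randomness flows from one master
seed through `numpy.random.SeedSequence` spawning (subject → trial →
location), so cohorts are bit-reproducible.

What the generator does **not** emulate: joint kinematics and
ground-reaction dynamics, overground or free-living gait, sensor dropout
and clipping at the ±4/±8 G ranges, and realistic between-subject feature
correlations. Passing tests on synthetic cohorts therefore demonstrate
that the pipeline is implemented correctly and can recover speed from
signals with the assumed structure (typical synthetic-cohort LOSO RMSE is
≈ 0.13–0.14 m/s with agreement slope ≈ 1.05, as recomputed by
`scripts/acceptance.py`); they do not establish accuracy on real
recordings, for which the deposited per-window feature files can be
imported via `gaitspeed.io.import_external_feature_table`.

## Problem sizes

The test suite and `scripts/acceptance.py` use the full default study
conditions for the parameter-recovery surface (17 subjects × 5 six-minute
walks + standing, three locations; 30 impaired subjects × 3 six-minute
walks) and small cohorts (3–5 subjects, 30–60 s tests) for unit and
pipeline tests, which keeps a full run to a few minutes on one CPU while
preserving the study's sampling structure where it matters.

## Known limitations

* The SVR hyperparameters are a fixed default regime, not tuned; with
  undocumented hyperparameters any reproduction of published error tables
  is approximate.
* The 32-slot feature registry is one defensible assignment of the named
  statistic families; alternative assignments also reach 32.
* The external feature importer requires a user-supplied column map
  because the layout of deposited supplementary files varies.
* Only integer-factor relationships to 50 Hz are supported; there is no
  resampling of arbitrary rates, gravity-vector estimation, or
  orientation tracking.
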