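# Methods

This note documents the models, conventions, parameter choices and
limitations behind `footmotion`, in the spirit of a model-description
appendix.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Frames and conventions

* **Sensor (body) frame**: axes fixed to the shoe-mounted IMU.  The
  sensor's y-axis is assumed mounted along the foot's forward
  direction, so mounting misalignment is pitch/roll only.
* **User frame**: Right(x)–Forward(y)–Up(z), fixed to the wearer.
* **Navigation frame**: local-level; for this short-window, low-speed
  application it coincides with the user frame up to yaw.
* **Gravity**: the reference vector is the specific force at rest,
  `a_n = (0, 0, +g)` with `g = 9.80665 m/s²`.  All filter equations are
  written under this single convention; the attitude-error sign
  convention follows from it (the bias coupling in the error dynamics
  is `ψ̇ = −C_b^n ε_b` with `ε_b` the residual bias, true minus
  estimated).
* **Euler angles**: intrinsic Z-X-Y — yaw about up, pitch about right,
  roll about forward.  The singularity at pitch ±90° is avoided
  structurally: the measurement is the acceleration residual, never an
  accelerometer-derived angle.
* **Units**: rad/s and m/s² internally; the CSV reader optionally
  converts deg/s on ingest.

## Sensor error model

Compensation inverts the standard deterministic model exactly,
`x = (I + S + N)⁻¹(x̃ − b)`, rather than using the first-order
approximation `(I − S − N)` — the cost difference is nil and the
inversion is exact for any invertible calibration.  The printed forward
model applies `S` and `N` to the true quantity; we invert that stated
form.  The stochastic term is deliberately left in the signal: it is
what the smoother and the filter's measurement covariance model.
Calibration estimation itself (e.g. one-minute hand-rotation schemes)
is out of scope; parameters arrive as a YAML config with identity
defaults.

## Attitude filter

Error state `[ψ, ε_b]` (attitude error, gyro bias).  The bias is
first-order Gauss–Markov with correlation time `tau_b = 100 s`; a
printed recursion that repeats the derivative on both sides of the bias
equation is treated as a typo for the standard form
`ε̇_b = −ε_b/τ_b + ω_b`.

* `ω_in^n` (Earth rate + transport rate) is set to zero: Earth rate
  (≈7.3e−5 rad/s) is two orders below MEMS bias for this application.
* **Process noise**: `Q = diag(q_gyro, q_bias)·dt` with defaults
  `q_gyro = 1.25e−7 rad²/s` (per-sample gyro sigma 0.005 rad/s at
  200 Hz) and `q_bias = 1e−6 rad²/s³`, chosen so the static-convergence
  and bias-recovery properties in the acceptance suite hold with
  margin; both are config fields.
* **Measurement covariance**: `R0 = diag(σ_x², σ_y², σ_z²)` from the
  accelerometer per-sample sigmas (default 0.05 m/s² per axis).
* **Thresholds**: `Thres1` defaults to the stated rule
  `3·(σ_x²+σ_y²+σ_z²)`.  That expression is dimensionally a variance,
  not an acceleration; it is implemented verbatim as the default, with
  an RMS alternative `3·sqrt(σ_x²+σ_y²+σ_z²)` selectable
  (`thres1_rule="rms"`) and the scalar directly overridable.
  `Thres2 = 2g`.  The low-acceleration inflation is isotropic,
  `R = R0 + k·ε²·I`, `k = 1`.
* **Initialisation**: pitch/roll by accelerometer leveling over the
  first 0.5 s (assumed static), yaw = 0 by the user-frame definition;
  initial sigmas 5° attitude, 0.05 rad/s bias.
* **Mechanics**: rotation kept as a quaternion (scipy `Rotation`), so
  the small-angle feedback `R(ψ̂)·C` is exactly orthonormal; covariance
  updates use the Joseph form and are symmetrised; a non-PSD innovation
  covariance raises instead of silently continuing.
* **Projection**: only pitch/roll rotate data into the user frame; yaw
  is stripped each sample.  Yaw is unobservable without a magnetometer
  and irrelevant — the user frame is defined yaw-free.

## Segmentation

The detector runs on a *causal* moving average (length `N = 10` at
200 Hz, i.e. 50 ms) of the acceleration norm — long enough to suppress
sensor noise, short enough not to merge the push-off and heel-strike
bumps of one cycle.  A peak is a strict-then-non-strict local maximum
(`s[i−1] < s[i] ≥ s[i+1]`) at least `min_peak_height = g + 2 m/s²`
high and `refractory = 40` samples (0.2 s) after the previous accepted
peak; both unstated in the source method and config-exposed.  The
causal smoother delays peaks by `(N−1)/2 ≈ 4.5` samples; this constant
group delay is accepted (it shifts the window, not the decision) and is
subtracted when comparing detections against ground truth.

Only the push-off peak triggers classification.  A detected peak cuts
a closed 31-sample window `[peak−20, peak+10]` (0-based indexing
everywhere); peaks closer than 20 samples to the start or 10 to the end
of the stream are dropped and logged.  Features are computed on
compensated, user-frame signals; the smoothed norm is used for
detection only.  The offline and streaming segmenters are independent
implementations of one contract and must produce identical windows —
a tested invariant, not an accident.

## Features

Ordered, versioned schema of 30 features (see
`footmotion.features.FEATURE_NAMES`): per-axis mean and *population*
variance (Σ/N, exactly as the defining equation prints) of
accelerometer and gyroscope; accelerometer SMA; displacement; and the
ratio triples of displacement, accelerometer mean, accelerometer
variance and SMA.  Gyro SMA/displacement analogues are not included by
default (the method selects accelerometer signals for these).

Integrals (SMA and the double integration for displacement) use the
trapezoidal rule on actual timestamps, falling back to the nominal
rate.  Over the 31-sample window that is a 30-interval horizon
(0.15 s); e.g. a constant unit-magnitude signal has SMA 0.15 m/s.
Displacement starts from v₀ = p₀ = 0 with zero azimuth; gravity is
subtracted in the user frame.  MEMS double-integration drift is
negligible on a 0.15 s horizon, which is precisely why position is
never computed outside the window.

A zero-norm ratio triple returns (0,0,0) rather than raising:
degenerate windows must not kill a real-time stream.

## Classifier bank and arbitration

One binary classifier per motion (five total), sharing one backend:

* decision tree: Gini impurity, depth cap 10, balanced class weights;
* kNN: k = 5, Euclidean, uniform votes, standardised features;
* SVM: RBF kernel, C = 1, `gamma="scale"`, balanced class weights,
  standardised features.

All hyperparameters are defaults of this package (the source method
names the three families without settings) and are config-exposed.
Standardisation statistics come from the training set only.  Each
binary problem is ≈1:4 imbalanced, hence the class weights where the
backend supports them.

Arbitration is this package's plumbing: exactly one firing classifier
wins; none firing yields `none`; several firing resolve by the largest
decision score, ties broken by the fixed order jump, left, right,
forward, backward.  Arbitration is pure — a tested invariant.

Model bundles serialise as a directory: `meta.json` (format version,
backend, seed, feature schema version) plus a joblib payload; a bank
refuses feature vectors from a different schema version.

## Evaluation

Accuracy, precision and recall from TP/TN/FP/FN; zero-denominator
metrics are flagged `undefined`, never silently zero.  10-fold CV
validates each observation exactly once and pools per-fold counts into
one table (so a count table over the full sample is reported, as in
the reference benchmark); the 25% holdout is stratified by default
(config-off to mimic a plain random choice).  Error profiles attribute
a classifier's misclassified events to their true motions and split
them into corresponding-motion vs other-motions shares summing to
100%.

The bundled reference counts (`footmotion.benchmarks`) carry three
documented inconsistencies, verified numerically and asserted as such
in the tests rather than silently passed: two accuracy cells print
99.09% where their own counts give 99.02%, and one error-profile row
prints percentages implying 39 events while its counts sum to 37.

## Synthetic data generator

The generator emulates the documented *morphology* of shoe-mounted
gait data — it is not a biomechanically validated gait model:

* four phases per cycle with fractions (stance 0.25, push-off 0.20,
  swing 0.35, heel-strike 0.20) of a 0.8 s cycle;
* raised-cosine pulses; per-cycle horizontal and vertical velocity
  balance is exact (discrete sums), so each cycle ends at rest;
* the swing-phase vertical dip approximates free fall, and the
  heel-strike impact is a modest bump (1 m/s² at unit strength) — a
  *visible second local maximum* in the smoothed norm that stays below
  the default trigger threshold, so exactly one classification fires
  per cycle.  Real landings are sharper and can re-trigger detectors;
  handling that would need a per-cycle state machine, noted as future
  work;
* direction signatures: push-off pulse of 9 m/s² along the motion's
  horizontal direction plus a 4.5 m/s² lift (13 m/s² vertical for
  jumps), and a single-axis gyro pulse pair (pitch for
  forward/backward/jump, roll for left/right) with exactly zero net
  rotation, so the mounting attitude is restored each cycle;
* accelerometer and gyro are kinematically consistent: specific force
  is expressed in the sensor frame through the *integrated* true
  orientation (closed form — each cycle rotates about one axis);
* wearer variation: per-step strength U(0.7, 1.3) and cycle duration
  U(0.7, 0.95) s; per-session gyro bias N(0, 0.01 rad/s) per axis;
  Gaussian sensor noise (0.05 m/s², 0.005 rad/s per sample);
* mounting misalignment rotates data into the sensor frame *after*
  content generation and noise is drawn in one block afterwards, so the
  same seed yields the identical user-frame truth under any mounting —
  the property that makes misalignment-invariance testable;
* all amplitudes live in one constants table (`GAIT_AMPLITUDES`); they
  are invented plausible values, and the pipeline's acceptance
  properties are additionally exercised across a ±50% amplitude sweep
  so tests do not overfit the defaults.

What passing tests on this generator do show: the filter cancels
mounting tilt, segmentation finds every injected push-off once,
features separate the five directions, and the pipeline is
deterministic and streaming-consistent.  What they do not show:
performance on real gait, with its impact spectra, soft-tissue
artefacts, inter-subject biomechanics and labelling noise.

## Benchmark problem sizes

The synthetic benchmark uses ten simulated wearers with 20 steps per
motion each (≥ 200 windows per motion, ≈ 230k samples end to end) —
large enough for stable holdout estimates while keeping the whole suite
fast on a laptop-class CPU.  The attitude parameter-recovery check uses
a 30 s static stream; oracle-equivalence checks use 10⁴ random inputs.

## Known limitations

* Cross-wearer generalisation requires training data from several
  wearers: a single simulated session has near-constant gyro bias and
  narrow strength spread, and distance-based backends then treat an
  unseen wearer's windows as outliers (the `none` event).  The original
  data-collection protocol — many testers, varied strengths — is the
  remedy, and the multi-session `--data` interface encodes it.
* Yaw is undefined by construction; motions that differ only by
  heading cannot be distinguished.
* Gyro z-bias is unobservable on static data (it drives yaw only);
  the recovery guarantee applies to the levelled axes.
* The five-motion label set is closed; anything else is either `none`
  or a false positive, and no rejection threshold tuning is provided.
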