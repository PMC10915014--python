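# Methods

This note documents the models, conventions and design choices behind
harloc, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Signal model of the synthetic generator

The generator (`harloc.synthio`) emulates a waist-worn smartphone during a
session of labeled activity episodes:

* **Static postures** are constant gravity orientations plus white Gaussian
  noise: standing puts gravity on z, sitting splits it between y and z,
  lying puts it on x. The magnitude of every posture is `g = 9.81 m/s²`,
  so classes are *not* separable from the fused magnitude alone — the
  per-axis feature bank (AR intercepts, spectral content) is what carries
  the class.
* **Walking** adds a vertical oscillation
  `a_z = g + A·(−cos(2πf(t−t₀)))` with amplitude `A = 2 m/s²` and step
  frequency `f` (default 1 Hz). Exactly one acceleration-magnitude peak
  occurs per cycle, at known times; the per-episode step count recorded in
  the ground truth is the number of those maxima, computed analytically.
* **Magnetometer**: `M_x = cos(heading)`, `M_y = sin(heading)` (+ noise),
  so `atan2(M_y, M_x)` recovers the heading exactly in the noiseless case.
* **Ambient channel**: a distinct constant level per activity (+ noise).
* **Audio** is a pure tone (optionally per-episode tones, e.g. 400 Hz
  indoor / 1600 Hz outdoor) plus Gaussian noise at its own rate (default
  8 kHz, independent of the 10 Hz IMU rate, as on real devices).
* **GPS** is a constant-velocity flat-earth track along the heading
  (bearing measured from north), with optional per-episode speeds and
  Gaussian jitter.

Default study conditions: 480 s sessions, 10 Hz IMU sampling (chosen so a
50-sample window spans 5 s), 30 s episodes cycling
sitting → standing → walking → lying, per-channel noise sd 0.1 (5% of the
gait amplitude). All randomness flows through `numpy.random.default_rng`
seeded from the scenario seed, so identical specs produce bit-identical
recordings.

**What this does not emulate:** biomechanically realistic gait (no
double-support phases, arm swing, or stride variability), sensor bias and
temperature drift, magnetic disturbances, GPS multipath, or transitions
between activities (episodes switch instantaneously). Passing tests
therefore demonstrate that each stage implements its definition correctly
and that the chain recovers known structure — not that the trained models
would reach comparable accuracy on field recordings.

## Denoising

IMU and ambient channels are low-passed with a third-order Butterworth
filter (bilinear-transform design, normalized cutoff `Wn = 0.1` of
Nyquist); GPS and audio channels get a kernel-3 median filter, applied
independently to latitude, longitude and altitude. The closed-form
magnitude response `|H(f)| = (1 + (f/f_c)^{2n})^{-1/2}` is kept as the
analytic oracle for the designed filter. Filtering is zero-phase
(forward–backward) by default because features are aligned to time
windows and phase lag would shift them; a causal single-pass mode is
available by flag. Axes are filtered first and fused into the magnitude
afterwards. Edge handling is reflect padding throughout.

One interaction deserves note: at the 10 Hz default rate the standard
cutoff (`0.1 × 5 Hz = 0.5 Hz`) lies *below* a 1 Hz step frequency, so the
default denoiser attenuates gait harmonics roughly eightfold. The
locomotion feature bank is unaffected (its features are relative), but
step detection is not: the localization branch therefore applies its own
gait-preserving low-pass (`Wn = 0.6`, i.e. 3 Hz) to the acceleration
before peak picking, configured via `features.localization.step_filter_wn`.

## Segmentation

Windows are `N = 50` samples with 25% overlap. Since 25% of 50 is
fractional, the hop is `round(0.75·N) = 38`, so consecutive windows share
12 samples (24%, the closest integer realization). Each window is
multiplied by the Blackman taper with coefficients (0.42, 0.5, 0.08); a
`--no-overlap` mode steps by a full window instead. Window labels are the
majority vote over the window's per-sample labels, with ties broken in
favour of the class occurring earliest inside the window; windows crossing
unlabeled samples are dropped (or rejected, configurably). A trailing
remainder shorter than one window is discarded.

Localization windows are cut from the *untapered* signal: step and stride
estimation rely on peak geometry that an amplitude taper would distort,
while the MFCC chain applies its own per-frame Hann taper.

## Locomotion feature bank

Per channel of a tapered segment: FFT min/max magnitude, spectral Shannon
entropy, skewness, excess kurtosis, an AR(4) fit (intercept, coefficients,
residual variance), and the LPC(4) prediction error energy per sample; for
the accelerometer triple, the three inter-axis phase-angle series are
summarized by their dominant-bin value and circular mean. Conventions:

* **FFT**: unnormalized forward transform of the mean-removed window;
  positive-frequency bins only. Bin probabilities are normalized powers,
  `0·log 0 := 0`, so `0 ≤ H ≤ log₂(n_bins)`.
* **Moments**: the `(N−1)·s^k` denominator convention with the ddof-1
  standard deviation, and kurtosis as *excess* kurtosis (−3). These match
  the printed feature definitions rather than the `n·m₂^{3/2}` textbook
  estimator; both are affine-invariant, which is what matters downstream.
* **Phase angles** are computed on *magnitude* spectra,
  `arctan(|FFT(b)|/|FFT(a)|) ∈ [0, π/2]` — the ratio of complex spectra
  has no real-valued arctangent; this is the major interpretive choice of
  the bank. Bins where both spectra vanish are set to 0.
* **AR and LPC** share one conditional least-squares fit on the lagged
  design with intercept (they differ only in which summary is exported:
  coefficients + residual variance vs error energy). Order 4 on 50-sample
  windows leaves 46 equations for 5 unknowns; a warning is logged below
  the 10·p rule of thumb and fitting refuses below 5·p. The fit is
  cross-checked against `statsmodels` AutoReg in the tests.
* Degenerate windows (zero variance on any configured channel) are
  excluded from the matrix with a logged count rather than imputed.

The default locomotion bank over (ax, ay, az, ambient) yields 54 columns;
the accelerometer triple alone yields 42.

## Localization feature bank

Per segment bundle (IMU + magnetometer + audio + GPS slices):

* **Step count**: magnitude, shifted to min 0, thresholded at its mean;
  strict local maxima above threshold are steps. An optional refractory
  period (0.25 s default in the pipeline) keeps only the larger of two
  peaks closer than the gap — without it, sensor noise near a flat peak
  creates double counts. Counting is invariant under positive scaling and
  offsets by construction.
* **Stride lengths**: velocity and position by cumulative trapezoidal
  integration of the (mean-removed) magnitude; the position curve is
  linearly detrended by default before valley picking, because double
  integration of any residual bias grows quadratically and hides the
  oscillatory valleys; Δt between successive valleys times a configurable
  speed constant (default 1.0 m/s — deliberately neutral, as no reference
  value exists) gives the stride length.
* **Heading**: `atan2(M_y, M_x)` per sample, degrees in [0, 360);
  segment summaries are the circular mean and circular sd. Samples with
  `M_x = M_y = 0` are flagged and set to 0.
* **MFCC**: 25 ms frames, 10 ms hop, periodic Hann taper, power spectrum
  zero-padded to the next power of two, 26 triangular mel filters between
  0 and Nyquist, energies floored at 1e−10 before the log, and the DCT
  `c_k = Σ_{n=1..N} log MF(n)·cos(πk(n−0.5)/N)` keeping k = 0..12.
  Per-segment features are the per-coefficient mean and sd over frames.
* **GPS**: haversine distances between consecutive fixes on a spherical
  earth (R = 6371 km), mean/max speed, net displacement.
* Missing modalities fill their columns with 0 and set a presence flag to
  0; the full bank is 39 columns.

## Yeo-Johnson feature optimization

Each column's λ maximizes the Gaussian profile log-likelihood of the
transformed values, `−(n/2)·log σ̂² + (λ−1)·Σ sign(y)·log(|y|+1)`, by
bounded scalar search on [−5, 5] with absolute tolerance 1e−5 (verified
against a grid search and against scikit-learn's PowerTransformer in the
tests). Transformed columns are z-standardized with the fitted mean/sd —
an addition motivated by the mixed units feeding the networks. Constant
columns pass through untransformed and flagged. Parameters are fitted on
training-fold rows only and applied unchanged to held-out rows; the CV
driver records exactly which rows every fitted object saw, and the tests
assert the train/test disjointness from those records.

## Models

No reference architecture exists for this chain, so the defaults are
deliberately small, CPU-friendly and fully specified:

* **LSTM (locomotion)**: sequences of T = 5 consecutive segment feature
  rows (≈19 s of context at the default hop), one LSTM layer of 64 units
  (forget-gate bias 1), softmax output. Sequence labels are the majority
  over the window with the earliest-occurring class breaking ties.
* **CNN (localization)**: per-row 1-D stack of two conv-ReLU-maxpool
  blocks (32 filters, kernel 3), a 64-unit ReLU dense layer (the
  penultimate representation), softmax output.
* Both train with Adam (lr 1e−2, batch 32) for 50 epochs on softmax
  cross-entropy. They are implemented as small numpy networks with exact
  gradients (verified against finite differences) and are bit-reproducible
  for a fixed seed on CPU.
* **Hybrid fusion** concatenates the transformed handcrafted row with the
  penultimate activations of the trained network and retrains a
  multinomial-logistic softmax head; column provenance is recorded via
  `hand__`/`deep__` prefixes.

## Evaluation protocol

Blocked k-fold cross-validation (k = 5 default): time-ordered rows are
split into k contiguous blocks of sizes differing by at most one; each
block is the test set exactly once, and the Yeo-Johnson parameters and
model weights are refitted per fold on the training rows only. Confusion
matrices are pooled by summation over folds. Metrics: per-class precision,
recall, F1 with a zero-denominator policy of "0 + flag"; macro averages
are unweighted means over classes with defined values; one-vs-rest ROC
with trapezoidal AUC on softmax scores. A `truncate2` presentation helper
floors values to two decimals, matching the convention of the reference
study's metric tables (several of whose printed F1 cells are
arithmetically inconsistent with their own precision/recall pairs; the
consistent cells are reproduced in the tests, the inconsistent ones are
catalogued there as source errata).

## Numerical choices and degenerate inputs

* Strict local extrema everywhere (plateaus produce no peaks/valleys).
* `arctan2` conventions: phase angles on non-negative magnitudes land in
  [0, π/2]; headings are wrapped to [0, 360).
* All-zero windows: entropy 0 with a warning; phase angles 0; degenerate
  feature rows excluded, not imputed.
* Recordings shorter than one window segment to an empty list with a
  warning rather than an error; fewer than two position valleys yield an
  empty stride list.
* WAV I/O is 16-bit PCM; round trips are exact to the quantization bound
  (RMS error < 1e−4). Feature CSVs store 12 significant digits.

## Problem sizes

The shipped scenarios are desk-scale by design: 480 s sessions give 126
windows per branch, enough for 5-fold blocked CV with every class present
in every training fold, while the whole test suite and the acceptance
script each complete in well under a minute on one CPU. Accuracy on these
fixtures reflects their engineered separability; it is a correctness
check of the chain, not a claim about field performance.

## Known limitations

* The per-bin phase-angle and AR-prediction series are reduced to scalar
  summaries (dominant bin, circular mean, residual variance); other
  reductions are plausible.
* Heading has no tilt compensation and the stride model is not a full
  pedestrian dead-reckoning system (out of scope).
* The networks are intentionally minimal; no hyperparameter search was
  performed, and small fixtures dominated by uninformative columns can
  overfit (the tests exercise this boundary explicitly).
* Loaders for specific public benchmark datasets are limited to the
  generic CSV reader plus user-supplied channel maps.
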