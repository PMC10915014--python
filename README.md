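# harloc

Multisensor **h**uman **a**ctivity **r**ecognition for **loc**omotion and
localization: a tested Python re-implementation of a smartphone/wearable
sensor-processing chain that classifies body postures and motion (sitting,
standing, walking, lying) from IMU + ambient channels, and environmental
context (indoor vs outdoor) from IMU + magnetometer + audio + GPS.

The package is aimed at researchers in digital health and human-movement
analysis who want each stage of such a pipeline — denoising, windowing,
handcrafted feature banks, feature optimization, sequence models and a
leakage-free evaluation protocol — as separately testable, composable
library functions, exercisable end-to-end on synthetic sensor data with
analytically known ground truth (no dataset downloads required).

## The processing chain

1. **Denoising** — third-order Butterworth low-pass for IMU and ambient
   channels, with the analytic magnitude response
   `|H(f)| = 1 / sqrt(1 + (f/f_c)^(2n))` (`f_c` = 10% of Nyquist by
   default); kernel-3 median filter for GPS and audio. Tri-axial channels
   fuse into a magnitude `sqrt(Sx² + Sy² + Sz²)`.
2. **Segmentation** — 50-sample windows (5 s at 10 Hz) with 25% overlap,
   each multiplied by the Blackman taper
   `W(n) = 0.42 − 0.5·cos(2πn/(N−1)) + 0.08·cos(4πn/(N−1))` to limit
   spectral leakage.
3. **Locomotion features** (per channel, per segment) — FFT min/max
   magnitude, Shannon spectral entropy `H = −Σ p(f_i) log₂ p(f_i)`,
   skewness `Σ(x_i−x̄)³/((N−1)s³)` and excess kurtosis
   `Σ(x_i−x̄)⁴/((N−1)s⁴) − 3`, an AR(p) fit
   `x_t = c + Σ φ_i x_{t−i} + ε_t`, the linear-prediction error energy,
   and inter-axis spectral phase angles
   `φ_ab[k] = arctan(|FFT(b)[k]| / |FFT(a)[k]|)`.
4. **Localization features** — step count (mean-threshold peak picking on
   the shifted acceleration magnitude), stride lengths Δt·v from valley
   points of the doubly-integrated acceleration, heading
   `θ = atan2(M_y, M_x)` in degrees, MFCCs
   `c_k = Σ_n log MF(n)·cos(πk(n−0.5)/N)`, and GPS haversine kinematics.
5. **Yeo-Johnson optimization** — per feature column, the power-transform
   parameter λ is fitted by profile likelihood and the transformed column
   z-standardized; parameters are fitted on training folds only.
6. **Models** — a single-layer LSTM over short sequences of segment
   feature rows (locomotion) and a small 1-D CNN over the feature vector
   (localization), both as compact seeded numpy networks, plus a hybrid
   head that concatenates handcrafted features with the network's
   penultimate activations.
7. **Evaluation** — blocked k-fold cross-validation over contiguous time
   blocks, confusion matrices, per-class and macro precision/recall/F1,
   one-vs-rest ROC/AUC.

## Worked example

Run the whole locomotion chain on the default synthetic four-class
scenario (480 s at 10 Hz, 30 s activity episodes, noise sd 0.1):

```sh
$ harloc pipeline --task locomotion --seed 7 --output out/
pooled accuracy: 0.953
macro F1: 0.952
artifacts in out/
```

`out/report.json` then contains the pooled confusion matrix over the five
test blocks (rows = true class, in the order lying, sitting, standing,
walking):

```
[[23, 1, 0, 1],
 [ 1, 25, 0, 0],
 [ 0,  0, 27, 0],
 [ 1,  0, 1, 26]]
```

i.e. 101 of 106 test sequence instances are classified correctly
(pooled accuracy 0.953), with macro precision/recall/F1 all ≈ 0.95 and
per-class one-vs-rest AUC between 0.996 and 1.0. Misclassifications sit at
episode boundaries, where windows mix two activities. The same command with
`--task localization` runs the indoor/outdoor CNN branch on synthetic IMU +
audio + GPS data.

Every stage is also a subcommand (`synth`, `preprocess`, `segment`,
`features`, `transform`, `train`, `evaluate`) operating on plain CSV/WAV/
JSON artifacts, configurable through a schema-validated YAML file
(`harloc validate-config --config my.yaml` echoes the resolved defaults,
e.g. `window.n = 50`).

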