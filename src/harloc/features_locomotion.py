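"""Per-segment locomotion feature bank for IMU and ambient channels.

For every configured channel of a segment the bank yields: FFT min/max
magnitude and Shannon spectral entropy, skewness and excess kurtosis (with
the (N-1)*s^k denominator convention), an autoregressive fit (intercept,
coefficients, residual variance) and the linear-prediction error energy per
sample.  For the accelerometer triple, inter-axis spectral phase angles
phi_xy, phi_xz, phi_yz = arctan(|FFT(b)|/|FFT(a)|) are summarized by their
dominant-bin value and circular mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .io_formats import FeatureMatrix
from .segment import Segment

log = logging.getLogger(__name__)

DEFAULT_AR_ORDER = 4
DEFAULT_LPC_ORDER = 4


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class SpectrumFeatures:
    fft_min: float
    fft_max: float
    entropy_bits: float
    bin_probs: np.ndarray
    n_bins: int


@dataclass
class PhaseAngles:
    """Per-bin inter-axis angle series (radians in [0, pi/2]) and summaries."""

    phi_xy: np.ndarray
    phi_xz: np.ndarray
    phi_yz: np.ndarray
    dominant: dict[str, float]
    mean: dict[str, float]


@dataclass
class ARFit:
    order: int
    intercept: float
    coefficients: np.ndarray
    residual_variance: float
    prediction_mse: float


@dataclass
class LPCFit:
    order: int
    intercept: float
    coefficients: np.ndarray
    prediction_error_energy: float  # total squared error over predicted samples

    @property
    def error_per_sample(self) -> float:
        n_pred = max(1, getattr(self, "_n_pred", 1))
        return self.prediction_error_energy / n_pred


@dataclass
class MomentFeatures:
    skewness: float
    kurtosis: float  # excess
    mean: float
    sd: float
    n: int


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _pos_freq_magnitudes(x: np.ndarray) -> np.ndarray:
    """Magnitudes of positive-frequency bins of the mean-removed signal."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    spectrum = np.fft.rfft(x)
    return np.abs(spectrum[1:])


def spectrum_features(x) -> SpectrumFeatures:
    """FFT min/max magnitude and Shannon entropy of the normalized power.

    The mean is removed, an unnormalized forward FFT taken, and only the
    positive-frequency bins used.  ``p(f_i) = |X(f_i)|^2 / sum_j |X(f_j)|^2``
    and ``H = -sum p log2 p`` (0 log 0 := 0), so 0 <= H <= log2(n_bins).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise ValidationError("need at least 8 samples for spectrum features")
    mags = _pos_freq_magnitudes(x)
    power = mags ** 2
    total = power.sum()
    if total <= 0:
        log.warning("all-zero signal after mean removal: entropy set to 0")
        probs = np.zeros_like(power)
        return SpectrumFeatures(0.0, 0.0, 0.0, probs, len(power))
    probs = power / total
    nz = probs[probs > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return SpectrumFeatures(
        fft_min=float(mags.min()),
        fft_max=float(mags.max()),
        entropy_bits=entropy,
        bin_probs=probs,
        n_bins=len(power),
    )


def phase_angles(ax, ay, az) -> PhaseAngles:
    """Inter-axis spectral angles on magnitude spectra.

    ``phi_ab[k] = arctan(|FFT(b)[k]| / |FFT(a)[k]|)`` per positive-frequency
    bin; bins where both spectra vanish are set to 0.  The dominant angle is
    taken at the bin with the largest combined power of the pair, the mean is
    a circular mean.
    """
    ax, ay, az = (np.asarray(v, dtype=float) for v in (ax, ay, az))
    if not (len(ax) == len(ay) == len(az)):
        raise ValidationError("axes have unequal lengths")
    if len(ax) < 8:
        raise ValidationError("need at least 8 samples for phase angles")
    mags = {name: _pos_freq_magnitudes(v) for name, v in (("x", ax), ("y", ay), ("z", az))}
    if all(m.max() == 0 for m in mags.values()):
        log.warning("all-zero accelerometer axes: phase angles set to 0")
    series: dict[str, np.ndarray] = {}
    dominant: dict[str, float] = {}
    mean: dict[str, float] = {}
    for pair, (a, b) in {"xy": ("x", "y"), "xz": ("x", "z"), "yz": ("y", "z")}.items():
        ma, mb = mags[a], mags[b]
        phi = np.zeros_like(ma)
        nz = (ma > 0) | (mb > 0)
        with np.errstate(divide="ignore"):
            phi[nz] = np.arctan2(mb[nz], ma[nz])  # equals arctan(mb/ma) on [0, pi/2]
        series[pair] = phi
        power = ma ** 2 + mb ** 2
        if power.max() > 0:
            dominant[pair] = float(phi[int(np.argmax(power))])
        else:
            dominant[pair] = 0.0
        if nz.any():
            mean[pair] = float(
                np.arctan2(np.sin(phi[nz]).mean(), np.cos(phi[nz]).mean())
            )
        else:
            mean[pair] = 0.0
    return PhaseAngles(
        phi_xy=series["xy"], phi_xz=series["xz"], phi_yz=series["yz"],
        dominant=dominant, mean=mean,
    )


def _lagged_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix [1, x_{t-1}, ..., x_{t-p}] and targets x_t for t >= p."""
    n = len(x)
    cols = [np.ones(n - p)]
    for i in range(1, p + 1):
        cols.append(x[p - i:n - i])
    return np.column_stack(cols), x[p:]


def _fit_linear_predictor(x, p: int, min_factor: int = 5):
    x = np.asarray(x, dtype=float)
    if p < 1:
        raise ValidationError("order must be >= 1")
    if len(x) < min_factor * p:
        raise ValidationError(
            f"series of length {len(x)} too short for order {p} "
            f"(need >= {min_factor * p})"
        )
    if len(x) < 10 * p:
        log.warning("series length %d < 10*p; coefficient variance is high", len(x))
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series: linear predictor undefined")
    design, target = _lagged_design(x, p)
    coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    return float(coef[0]), coef[1:], resid


def ar_fit(x, p: int = DEFAULT_AR_ORDER) -> ARFit:
    """Least-squares autoregressive fit ``x_t = c + sum_i phi_i x_{t-i} + e_t``."""
    c, phi, resid = _fit_linear_predictor(x, p)
    return ARFit(
        order=p,
        intercept=c,
        coefficients=phi,
        residual_variance=float(np.mean(resid ** 2)),
        prediction_mse=float(np.mean(resid ** 2)),
    )


def ar_predict(fit: ARFit, history) -> float:
    """One-step prediction ``c + sum_i phi_i x_{t-i}`` (noise term excluded).

    ``history`` lists the most recent values first: ``[x_{t-1}, ..., x_{t-p}]``.
    """
    history = np.asarray(history, dtype=float)
    if len(history) != fit.order:
        raise ValidationError(f"history must have length p = {fit.order}")
    return float(fit.intercept + fit.coefficients @ history)


def linear_prediction(x, p: int = DEFAULT_LPC_ORDER) -> LPCFit:
    """Least-squares linear predictor; the exported feature is the
    minimized prediction error energy per predicted sample."""
    c, a, resid = _fit_linear_predictor(x, p)
    fit = LPCFit(
        order=p,
        intercept=c,
        coefficients=a,
        prediction_error_energy=float(np.sum(resid ** 2)),
    )
    fit._n_pred = len(resid)
    return fit


def moments(x) -> MomentFeatures:
    """Skewness and excess kurtosis with the (N-1)*s^k denominator.

    ``skew = sum (x_i - xbar)^3 / ((N-1) s^3)`` and
    ``kurt = sum (x_i - xbar)^4 / ((N-1) s^4) - 3`` with ``s`` the ddof-1
    standard deviation.  Zero variance raises."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 samples for moments")
    mean = x.mean()
    s = x.std(ddof=1)
    if s == 0:
        raise DegenerateInputError("zero-variance input: moments undefined")
    dev = x - mean
    skew = float(np.sum(dev ** 3) / ((n - 1) * s ** 3))
    kurt = float(np.sum(dev ** 4) / ((n - 1) * s ** 4) - 3.0)
    return MomentFeatures(skewness=skew, kurtosis=kurt, mean=float(mean), sd=float(s), n=n)


# ---------------------------------------------------------------------------
# Row assembly
# ---------------------------------------------------------------------------

def _channel_features(name: str, x: np.ndarray, ar_order: int, lpc_order: int) -> dict[str, float]:
    spec = spectrum_features(x)
    mom = moments(x)
    ar = ar_fit(x, ar_order)
    lpc = linear_prediction(x, lpc_order)
    row = {
        f"{name}__fft_min": spec.fft_min,
        f"{name}__fft_max": spec.fft_max,
        f"{name}__entropy": spec.entropy_bits,
        f"{name}__skewness": mom.skewness,
        f"{name}__kurtosis": mom.kurtosis,
        f"{name}__ar_c": ar.intercept,
    }
    for i, phi in enumerate(ar.coefficients, start=1):
        row[f"{name}__ar_phi{i}"] = float(phi)
    row[f"{name}__ar_resid_var"] = ar.residual_variance
    row[f"{name}__lpc_error"] = lpc.error_per_sample
    return row


def locomotion_feature_row(
    segment: Segment,
    channels: list[str] | None = None,
    accel_channels: tuple[str, str, str] = ("ax", "ay", "az"),
    ar_order: int = DEFAULT_AR_ORDER,
    lpc_order: int = DEFAULT_LPC_ORDER,
) -> dict[str, float]:
    """One named feature row for a segment over the configured channels.

    Column naming is ``<channel>__<feature>`` plus ``phase__<pair>_dominant``
    and ``phase__<pair>_mean`` for the accelerometer triple.  Raises on
    degenerate channels; callers exclude such rows and log them.
    """
    if channels is None:
        channels = list(segment.channels)
    row: dict[str, float] = {}
    for name in channels:
        if name not in segment.channels:
            raise ValidationError(f"segment has no channel {name!r}")
        row.update(_channel_features(name, segment.channels[name], ar_order, lpc_order))
    if all(c in segment.channels for c in accel_channels):
        angles = phase_angles(*(segment.channels[c] for c in accel_channels))
        for pair in ("xy", "xz", "yz"):
            row[f"phase__{pair}_dominant"] = angles.dominant[pair]
            row[f"phase__{pair}_mean"] = angles.mean[pair]
    return row


def build_locomotion_matrix(
    segments: list[Segment],
    channels: list[str] | None = None,
    accel_channels: tuple[str, str, str] = ("ax", "ay", "az"),
    ar_order: int = DEFAULT_AR_ORDER,
    lpc_order: int = DEFAULT_LPC_ORDER,
) -> FeatureMatrix:
    """Assemble the locomotion feature matrix, excluding failed rows."""
    rows: list[dict[str, float]] = []
    labels: list[str] = []
    n_excluded = 0
    for seg in segments:
        try:
            row = locomotion_feature_row(seg, channels, accel_channels, ar_order, lpc_order)
        except (DegenerateInputError, ValidationError) as exc:
            n_excluded += 1
            log.info("excluded segment at %d: %s", seg.start_index, exc)
            continue
        rows.append(row)
        labels.append(seg.label if seg.label is not None else "")
    if n_excluded:
        log.warning("excluded %d degenerate segments from locomotion features", n_excluded)
    df = pd.DataFrame(rows)
    return FeatureMatrix(values=df, labels=np.asarray(labels), branch="locomotion")
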