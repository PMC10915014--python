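"""Localization feature bank: steps, strides, heading, MFCC, GPS kinematics.

Step counting thresholds the (shifted) acceleration magnitude at its mean
and counts strict local maxima above it.  Stride timing comes from valley
points of the doubly-integrated acceleration (position-time curve); each
inter-valley interval times a configurable speed constant gives a stride
length.  Heading is ``atan2(My, Mx)`` in degrees [0, 360).  MFCCs follow the
classic chain FFT power spectrum -> triangular mel filterbank -> log ->
DCT ``c_k = sum_n log MF(n) cos(pi k (n - 0.5) / N)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.integrate
import scipy.signal

from .errors import ValidationError
from .io_formats import AudioRecording, GpsTrack
from .preprocess import TriaxialSignal, magnitude

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6371000.0


# ---------------------------------------------------------------------------
# Step count
# ---------------------------------------------------------------------------

@dataclass
class StepDetection:
    magnitude: np.ndarray
    shift_offset: float
    threshold: float
    peak_indices: np.ndarray
    count: int


def _strict_local_maxima(x: np.ndarray) -> np.ndarray:
    interior = np.arange(1, len(x) - 1)
    mask = (x[interior] > x[interior - 1]) & (x[interior] > x[interior + 1])
    return interior[mask]


def detect_steps(
    accel: TriaxialSignal,
    rate_hz: float,
    min_gap_s: float | None = None,
) -> StepDetection:
    """Count steps as mean-exceeding strict local maxima of the magnitude.

    The composite magnitude ``A = sqrt(x^2+y^2+z^2)`` is shifted so its
    minimum is zero, thresholded at the mean of the shifted signal, and
    strict local maxima above the threshold are counted.  ``min_gap_s``
    optionally enforces a refractory period: of any two peaks closer than
    the gap, only the larger survives.
    """
    if len(accel) < 3:
        raise ValidationError("need at least 3 samples to detect steps")
    a = magnitude(accel)
    offset = float(a.min())
    shifted = a - offset
    threshold = float(shifted.mean())
    peaks = _strict_local_maxima(shifted)
    peaks = peaks[shifted[peaks] > threshold]
    if min_gap_s is not None and len(peaks) > 1:
        gap = min_gap_s * rate_hz  # in samples, fractional comparison
        kept: list[int] = []
        for p in peaks:
            if kept and p - kept[-1] < gap:
                if shifted[p] > shifted[kept[-1]]:
                    kept[-1] = int(p)
            else:
                kept.append(int(p))
        peaks = np.asarray(kept, dtype=int)
    return StepDetection(
        magnitude=a,
        shift_offset=offset,
        threshold=threshold,
        peak_indices=np.asarray(peaks, dtype=int),
        count=int(len(peaks)),
    )


# ---------------------------------------------------------------------------
# Stride length
# ---------------------------------------------------------------------------

@dataclass
class StrideEstimate:
    velocity: np.ndarray
    position: np.ndarray
    valley_indices: np.ndarray
    delta_t_s: np.ndarray
    speed_const_mps: float
    stride_lengths_m: np.ndarray


def estimate_strides(
    accel_forward,
    rate_hz: float,
    speed_const_mps: float = 1.0,
    detrend: bool = True,
) -> StrideEstimate:
    """Stride lengths from valleys of the doubly-integrated acceleration.

    Velocity is the cumulative trapezoidal integral of the acceleration,
    position that of the velocity.  Valley points of the position-time curve
    mark successive same-foot ground contacts; each inter-valley interval
    delta-t times ``speed_const_mps`` is one stride length.  A linear detrend
    of the position (default on) removes the quadratic drift that double
    integration of a biased signal produces.
    """
    a = np.asarray(accel_forward, dtype=float)
    if len(a) < 3 * rate_hz:
        raise ValidationError("need at least 3 s of data for stride estimation")
    dt = 1.0 / rate_hz
    v = scipy.integrate.cumulative_trapezoid(a, dx=dt, initial=0.0)
    p = scipy.integrate.cumulative_trapezoid(v, dx=dt, initial=0.0)
    p_for_valleys = scipy.signal.detrend(p, type="linear") if detrend else p
    valleys = _strict_local_maxima(-p_for_valleys)
    if len(valleys) < 2:
        log.warning("fewer than 2 position valleys: no strides estimated")
        delta = np.empty(0)
    else:
        delta = np.diff(valleys) * dt
    return StrideEstimate(
        velocity=v,
        position=p,
        valley_indices=np.asarray(valleys, dtype=int),
        delta_t_s=delta,
        speed_const_mps=speed_const_mps,
        stride_lengths_m=delta * speed_const_mps,
    )


# ---------------------------------------------------------------------------
# Heading
# ---------------------------------------------------------------------------

@dataclass
class HeadingSeries:
    theta_deg: np.ndarray
    undefined: np.ndarray  # samples where Mx = My = 0 (theta set to 0)


def heading_angles(mag: TriaxialSignal) -> HeadingSeries:
    """Per-sample heading ``theta = atan2(My, Mx)`` in degrees [0, 360)."""
    if len(mag) < 1:
        raise ValidationError("need at least one magnetometer sample")
    undefined = (mag.x == 0) & (mag.y == 0)
    theta = np.degrees(np.arctan2(mag.y, mag.x)) % 360.0
    theta[undefined] = 0.0
    return HeadingSeries(theta_deg=theta, undefined=undefined)


def circular_mean_deg(theta_deg: np.ndarray) -> float:
    rad = np.radians(np.asarray(theta_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360.0)


def circular_sd_deg(theta_deg: np.ndarray) -> float:
    """Circular standard deviation sqrt(-2 ln R) in degrees."""
    rad = np.radians(np.asarray(theta_deg, dtype=float))
    r = float(np.hypot(np.sin(rad).mean(), np.cos(rad).mean()))
    r = min(max(r, 1e-12), 1.0)
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

@dataclass
class MfccSpec:
    """Mel-cepstrum configuration (26 filters, 13 kept coefficients)."""

    n_filters: int = 26
    n_coeffs: int = 13
    frame_s: float = 0.025
    hop_s: float = 0.010
    fmin_hz: float = 0.0
    fmax_hz: float | None = None  # None -> Nyquist
    energy_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_coeffs > self.n_filters:
            raise ValidationError("n_coeffs must be <= n_filters")
        if self.frame_s <= 0 or self.hop_s <= 0:
            raise ValidationError("frame and hop must be positive")


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, rate_hz: float,
                   fmin_hz: float = 0.0, fmax_hz: float | None = None) -> np.ndarray:
    """Triangular mel filters as a (n_filters, n_fft//2 + 1) weight matrix."""
    fmax_hz = rate_hz / 2.0 if fmax_hz is None else fmax_hz
    if fmax_hz > rate_hz / 2.0 + 1e-9:
        raise ValidationError("fmax above Nyquist")
    mels = np.linspace(hz_to_mel(fmin_hz), hz_to_mel(fmax_hz), n_filters + 2)
    hz = mel_to_hz(mels)
    bins = np.floor((n_fft + 1) * hz / rate_hz).astype(int)
    fb = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        left, center, right = bins[i], bins[i + 1], bins[i + 2]
        for k in range(left, center):
            if center > left:
                fb[i, k] = (k - left) / (center - left)
        for k in range(center, right):
            if right > center:
                fb[i, k] = (right - k) / (right - center)
    return fb


def filter_center_freqs_hz(spec: MfccSpec, rate_hz: float) -> np.ndarray:
    fmax = rate_hz / 2.0 if spec.fmax_hz is None else spec.fmax_hz
    mels = np.linspace(hz_to_mel(spec.fmin_hz), hz_to_mel(fmax), spec.n_filters + 2)
    return np.asarray(mel_to_hz(mels[1:-1]), dtype=float)


def mel_energies(frame: np.ndarray, fb: np.ndarray, n_fft: int) -> np.ndarray:
    spectrum = np.fft.rfft(frame, n=n_fft)
    power = np.abs(spectrum) ** 2
    return fb @ power


def _dct_log_energies(log_e: np.ndarray, n_coeffs: int) -> np.ndarray:
    n = len(log_e)
    ks = np.arange(n_coeffs)[:, None]
    ns = np.arange(1, n + 1)[None, :]
    basis = np.cos(np.pi * ks * (ns - 0.5) / n)
    return basis @ log_e


def mfcc(audio: AudioRecording, spec: MfccSpec | None = None) -> np.ndarray:
    """Per-frame MFCC matrix of shape (n_frames, n_coeffs).

    Frames are Hann-tapered, zero-padded to the next power of two, passed
    through the power spectrum and the triangular mel filterbank; filter
    energies are floored at ``energy_floor`` before the log, and the DCT
    ``c_k = sum_{n=1..N} log MF(n) cos(pi k (n - 0.5)/N)`` keeps k = 0..K-1.
    """
    spec = spec or MfccSpec()
    rate = audio.sample_rate_hz
    frame_len = int(round(spec.frame_s * rate))
    hop = int(round(spec.hop_s * rate))
    x = audio.samples
    if frame_len >= len(x):
        raise ValidationError("audio shorter than one frame")
    n_fft = 1
    while n_fft < frame_len:
        n_fft *= 2
    window = scipy.signal.get_window("hann", frame_len, fftbins=True)
    fb = mel_filterbank(spec.n_filters, n_fft, rate, spec.fmin_hz, spec.fmax_hz)
    n_frames = 1 + (len(x) - frame_len) // hop
    out = np.empty((n_frames, spec.n_coeffs))
    silent = True
    for j in range(n_frames):
        frame = x[j * hop:j * hop + frame_len] * window
        energies = mel_energies(frame, fb, n_fft)
        if energies.max() > spec.energy_floor:
            silent = False
        log_e = np.log(np.maximum(energies, spec.energy_floor))
        out[j] = _dct_log_energies(log_e, spec.n_coeffs)
    if silent:
        log.warning("silent audio: all mel energies at the floor")
    return out


# ---------------------------------------------------------------------------
# GPS kinematics
# ---------------------------------------------------------------------------

def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres on a spherical earth."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


@dataclass
class GpsKinematics:
    distances_m: np.ndarray
    speeds_mps: np.ndarray
    mean_speed_mps: float
    max_speed_mps: float
    net_displacement_m: float
    defined: bool


def gps_kinematics(track: GpsTrack) -> GpsKinematics:
    """Consecutive-fix haversine distances, speeds and net displacement."""
    if track.n_fixes < 2:
        log.warning("single GPS fix: kinematics undefined, zeros returned")
        return GpsKinematics(np.empty(0), np.empty(0), 0.0, 0.0, 0.0, False)
    d = haversine_m(track.lat_deg[:-1], track.lon_deg[:-1],
                    track.lat_deg[1:], track.lon_deg[1:])
    dt = np.diff(track.times_s)
    if np.any(dt <= 0):
        raise ValidationError("GPS timestamps must be strictly increasing")
    speeds = d / dt
    net = float(haversine_m(track.lat_deg[0], track.lon_deg[0],
                            track.lat_deg[-1], track.lon_deg[-1]))
    return GpsKinematics(
        distances_m=d,
        speeds_mps=speeds,
        mean_speed_mps=float(speeds.mean()),
        max_speed_mps=float(speeds.max()),
        net_displacement_m=net,
        defined=True,
    )


# ---------------------------------------------------------------------------
# Row assembly
# ---------------------------------------------------------------------------

@dataclass
class SegmentBundle:
    """Time-aligned per-segment slices of every localization modality."""

    imu: TriaxialSignal | None
    imu_rate_hz: float
    mag: TriaxialSignal | None = None
    audio: AudioRecording | None = None
    gps: GpsTrack | None = None
    label: str | None = None


def localization_feature_row(
    bundle: SegmentBundle,
    speed_const_mps: float = 1.0,
    mfcc_spec: MfccSpec | None = None,
    step_min_gap_s: float | None = 0.25,
    detrend: bool = True,
) -> dict[str, float]:
    """One named localization feature row; missing modalities fill with 0
    and set their presence flag to 0.  All modalities absent is an error."""
    mfcc_spec = mfcc_spec or MfccSpec()
    if bundle.imu is None and bundle.mag is None and bundle.audio is None and bundle.gps is None:
        raise ValidationError("all modalities missing from segment bundle")
    row: dict[str, float] = {}

    if bundle.imu is not None:
        steps = detect_steps(bundle.imu, bundle.imu_rate_hz, min_gap_s=step_min_gap_s)
        duration = len(bundle.imu) / bundle.imu_rate_hz
        row["step_count"] = float(steps.count)
        row["step_rate_hz"] = steps.count / duration
        a = magnitude(bundle.imu)
        try:
            strides = estimate_strides(a - a.mean(), bundle.imu_rate_hz,
                                       speed_const_mps, detrend=detrend)
            lengths = strides.stride_lengths_m
        except ValidationError:
            lengths = np.empty(0)
        row["stride_mean_m"] = float(lengths.mean()) if len(lengths) else 0.0
        row["stride_sd_m"] = float(lengths.std()) if len(lengths) > 1 else 0.0
    else:
        row.update(step_count=0.0, step_rate_hz=0.0, stride_mean_m=0.0, stride_sd_m=0.0)

    if bundle.mag is not None:
        heading = heading_angles(bundle.mag)
        row["heading_mean_deg"] = circular_mean_deg(heading.theta_deg)
        row["heading_sd_deg"] = circular_sd_deg(heading.theta_deg)
    else:
        row.update(heading_mean_deg=0.0, heading_sd_deg=0.0)

    if bundle.audio is not None and len(bundle.audio.samples) > int(
        round(mfcc_spec.frame_s * bundle.audio.sample_rate_hz)
    ):
        coeffs = mfcc(bundle.audio, mfcc_spec)
        means = coeffs.mean(axis=0)
        sds = coeffs.std(axis=0)
        for k in range(mfcc_spec.n_coeffs):
            row[f"mfcc{k}_mean"] = float(means[k])
            row[f"mfcc{k}_sd"] = float(sds[k])
        audio_present = 1.0
    else:
        for k in range(mfcc_spec.n_coeffs):
            row[f"mfcc{k}_mean"] = 0.0
            row[f"mfcc{k}_sd"] = 0.0
        audio_present = 0.0

    if bundle.gps is not None and bundle.gps.n_fixes >= 2:
        kin = gps_kinematics(bundle.gps)
        row["gps_mean_speed_mps"] = kin.mean_speed_mps
        row["gps_max_speed_mps"] = kin.max_speed_mps
        row["gps_net_displacement_m"] = kin.net_displacement_m
        gps_present = 1.0
    else:
        row.update(gps_mean_speed_mps=0.0, gps_max_speed_mps=0.0,
                   gps_net_displacement_m=0.0)
        gps_present = 0.0

    row["imu_present"] = 1.0 if bundle.imu is not None else 0.0
    row["mag_present"] = 1.0 if bundle.mag is not None else 0.0
    row["audio_present"] = audio_present
    row["gps_present"] = gps_present
    return row
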