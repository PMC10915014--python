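"""Deterministic generator of labeled multisensor recordings with ground truth.

The generator emulates the structure of wearable-sensor activity datasets:
a subject cycles through posture/motion episodes (sitting, standing, walking,
lying) or indoor/outdoor contexts while a waist-worn IMU, a magnetometer, an
ambient scalar channel, a microphone and a GPS receiver record.  Every signal
property that downstream stages estimate (step count, stride contacts,
heading, per-sample class) is known analytically, so every pipeline stage is
testable without external datasets.

Signal model
------------
* Static postures: constant gravity orientation per posture plus white
  Gaussian noise (sitting tilts gravity into y/z, lying into x).
* Walking: vertical-axis oscillation ``g + amp * (-cos(2*pi*f*(t - t0)))`` at
  the configured step frequency; one acceleration-magnitude peak per step
  cycle, at known times.
* Magnetometer: ``Mx = cos(heading)``, ``My = sin(heading)`` (+ noise), so
  ``atan2(My, Mx)`` recovers the heading exactly in the noiseless case.
* Ambient channel: a distinct constant level per activity class (+ noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import AudioRecording, GpsTrack, SensorRecording

GRAVITY = 9.81
WALK_AMP = 2.0  # m/s^2 vertical oscillation amplitude during walking

# Constant accelerometer orientation per static posture (m/s^2).
POSTURE_ACCEL = {
    "sitting": (0.0, GRAVITY / math.sqrt(2.0), GRAVITY / math.sqrt(2.0)),
    "standing": (0.0, 0.0, GRAVITY),
    "lying": (GRAVITY, 0.0, 0.0),
    "indoor": (0.0, GRAVITY / math.sqrt(2.0), GRAVITY / math.sqrt(2.0)),
}

# Distinct ambient levels (arbitrary units) per activity class.
AMBIENT_LEVEL = {
    "sitting": 1.0,
    "standing": 2.0,
    "walking": 3.0,
    "lying": 0.5,
    "indoor": 1.0,
    "outdoor": 3.0,
}

WALKING_LABELS = {"walking", "outdoor"}

EARTH_RADIUS_M = 6371000.0
M_PER_DEG_LAT = EARTH_RADIUS_M * math.pi / 180.0


@dataclass
class ScenarioSpec:
    """Full description of one synthetic session.

    ``activities`` is an ordered list of ``(label, start_s, end_s)`` episodes
    that must tile ``[0, duration_s]`` without overlap.  ``step_freq_hz`` is
    the step rate during walking episodes; ``stride_period_s`` the interval
    between same-foot ground contacts (two steps); ``heading_deg`` the travel
    bearing in [0, 360).
    """

    duration_s: float = 480.0
    sample_rate_hz: float = 10.0
    activities: list[tuple[str, float, float]] = field(default_factory=list)
    step_freq_hz: float = 1.0
    stride_period_s: float = 2.0
    heading_deg: float = 45.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if not self.activities:
            raise ValidationError("activities must be a non-empty interval list")
        if not 0 <= self.heading_deg < 360:
            raise ValidationError("heading_deg must lie in [0, 360)")
        ivals = sorted(self.activities, key=lambda a: a[1])
        cursor = 0.0
        for label, start, end in ivals:
            if end <= start:
                raise ValidationError(f"empty or inverted interval for {label!r}")
            if start < cursor - 1e-9:
                raise ValidationError("activity intervals overlap")
            if abs(start - cursor) > 1e-6:
                raise ValidationError("activity intervals leave a gap")
            cursor = end
        if abs(cursor - self.duration_s) > 1e-6:
            raise ValidationError("activity intervals must cover [0, duration_s]")
        if any(lbl in WALKING_LABELS for lbl, _, _ in self.activities):
            if self.step_freq_hz <= 0:
                raise ValidationError("step_freq_hz must be > 0 for walking episodes")
            if self.stride_period_s <= 0:
                raise ValidationError("stride_period_s must be > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))


@dataclass
class GroundTruth:
    """Analytic truth recorded alongside the generated signals."""

    labels_per_sample: np.ndarray
    true_step_count: list[int]          # one entry per walking episode
    true_valley_times_s: list[float]    # same-foot contact times, all episodes
    true_heading_deg: float

    @property
    def total_steps(self) -> int:
        return int(sum(self.true_step_count))


def _episode_peak_times(start: float, end: float, f: float) -> np.ndarray:
    """Times of the acceleration-magnitude maxima of one walking episode."""
    k_max = int(math.floor((end - start) * f - 0.5))
    ks = np.arange(0, k_max + 1)
    return start + (ks + 0.5) / f


def default_locomotion_scenario(
    duration_s: float = 480.0,
    episode_s: float = 30.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    sample_rate_hz: float = 10.0,
) -> ScenarioSpec:
    """Four-class scenario cycling sitting/standing/walking/lying episodes."""
    order = ["sitting", "standing", "walking", "lying"]
    activities = []
    t = 0.0
    i = 0
    while t < duration_s - 1e-9:
        end = min(t + episode_s, duration_s)
        activities.append((order[i % 4], t, end))
        t = end
        i += 1
    return ScenarioSpec(
        duration_s=duration_s,
        sample_rate_hz=sample_rate_hz,
        activities=activities,
        noise_sd=noise_sd,
        seed=seed,
    )


def indoor_outdoor_scenario(
    duration_s: float = 480.0,
    episode_s: float = 40.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    sample_rate_hz: float = 10.0,
) -> ScenarioSpec:
    """Two-context scenario alternating indoor (static) and outdoor (walking)."""
    activities = []
    t = 0.0
    i = 0
    while t < duration_s - 1e-9:
        end = min(t + episode_s, duration_s)
        activities.append(("indoor" if i % 2 == 0 else "outdoor", t, end))
        t = end
        i += 1
    return ScenarioSpec(
        duration_s=duration_s,
        sample_rate_hz=sample_rate_hz,
        activities=activities,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_recording(spec: ScenarioSpec) -> tuple[SensorRecording, GroundTruth]:
    """Generate the IMU + magnetometer + ambient recording and its truth.

    Identical ``(spec, seed)`` yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate_hz
    ax = np.zeros(n)
    ay = np.zeros(n)
    az = np.zeros(n)
    ambient = np.zeros(n)
    labels = np.empty(n, dtype=object)

    step_counts: list[int] = []
    valley_times: list[float] = []

    for label, start, end in spec.activities:
        mask = (t >= start - 1e-12) & (t < end - 1e-12)
        labels[mask] = label
        if label in WALKING_LABELS:
            f = spec.step_freq_hz
            ax[mask] += 0.0
            ay[mask] += 0.0
            az[mask] += GRAVITY + WALK_AMP * (-np.cos(2 * np.pi * f * (t[mask] - start)))
            step_counts.append(len(_episode_peak_times(start, end, f)))
            contact = start + spec.stride_period_s
            while contact < end - 1e-9:
                valley_times.append(contact)
                contact += spec.stride_period_s
        else:
            gx, gy, gz = POSTURE_ACCEL.get(label, POSTURE_ACCEL["standing"])
            ax[mask] += gx
            ay[mask] += gy
            az[mask] += gz
        ambient[mask] = AMBIENT_LEVEL.get(label, 1.5)

    # Last sample belongs to the final episode (right-open intervals above
    # leave t == duration unassigned only when rounding makes n*dt == end).
    if labels[-1] is None:
        labels[-1] = spec.activities[-1][0]

    heading_rad = math.radians(spec.heading_deg)
    mx = np.full(n, math.cos(heading_rad))
    my = np.full(n, math.sin(heading_rad))
    mz = np.full(n, 0.4)

    if spec.noise_sd > 0:
        ax = ax + rng.normal(0.0, spec.noise_sd, n)
        ay = ay + rng.normal(0.0, spec.noise_sd, n)
        az = az + rng.normal(0.0, spec.noise_sd, n)
        mx = mx + rng.normal(0.0, spec.noise_sd, n)
        my = my + rng.normal(0.0, spec.noise_sd, n)
        mz = mz + rng.normal(0.0, spec.noise_sd, n)
        ambient = ambient + rng.normal(0.0, spec.noise_sd, n)

    rec = SensorRecording(
        channels={
            "ax": ax, "ay": ay, "az": az,
            "mx": mx, "my": my, "mz": mz,
            "ambient": ambient,
        },
        sample_rate_hz=spec.sample_rate_hz,
        sensor_kind="multi",
        labels=labels.astype(str),
        subject_id="synthetic",
    )
    truth = GroundTruth(
        labels_per_sample=labels.astype(str),
        true_step_count=step_counts,
        true_valley_times_s=valley_times,
        true_heading_deg=spec.heading_deg,
    )
    return rec, truth


def generate_audio(
    spec: ScenarioSpec,
    tone_hz: float = 1000.0,
    audio_rate_hz: float = 8000.0,
    amplitude: float = 0.5,
    noise_sd: float = 0.0,
    tone_by_label: dict[str, float] | None = None,
) -> AudioRecording:
    """Pure tone (optionally per-activity tones) plus Gaussian noise.

    With ``tone_by_label`` the tone frequency switches per episode, which
    gives context classes distinct ambient-sound spectra (e.g. indoor vs
    outdoor).  Seeded from ``spec.seed``; a tone at or above Nyquist is
    rejected.
    """
    tones = list(tone_by_label.values()) if tone_by_label else [tone_hz]
    for f in tones:
        if not 0 < f < audio_rate_hz / 2:
            raise ValidationError(
                f"tone {f} Hz outside (0, Nyquist={audio_rate_hz / 2} Hz)"
            )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n = int(round(spec.duration_s * audio_rate_hz))
    t = np.arange(n) / audio_rate_hz
    if tone_by_label is None:
        samples = amplitude * np.sin(2 * np.pi * tone_hz * t)
    else:
        samples = np.zeros(n)
        for label, start, end in spec.activities:
            f = tone_by_label.get(label, tone_hz)
            mask = (t >= start - 1e-12) & (t < end - 1e-12)
            samples[mask] = amplitude * np.sin(2 * np.pi * f * (t[mask] - start))
    if noise_sd > 0:
        samples = samples + rng.normal(0.0, noise_sd, n)
    return AudioRecording(samples=samples, sample_rate_hz=audio_rate_hz)


def generate_gps_track(
    spec: ScenarioSpec,
    speed_mps: float = 1.0,
    gps_rate_hz: float = 1.0,
    jitter_deg: float = 0.0,
    lat0_deg: float = 47.0,
    lon0_deg: float = 8.0,
    speed_by_label: dict[str, float] | None = None,
) -> GpsTrack:
    """Constant-velocity track along ``heading_deg`` (bearing from north).

    ``speed_by_label`` lets the speed depend on the active episode (indoor 0,
    outdoor walking speed, ...).  Jitter is i.i.d. Gaussian in degrees.
    """
    if speed_mps < 0:
        raise ValidationError("speed_mps must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    n = int(round(spec.duration_s * gps_rate_hz)) + 1
    times = np.arange(n) / gps_rate_hz
    theta = math.radians(spec.heading_deg)
    dt = 1.0 / gps_rate_hz

    if speed_by_label is None:
        speeds = np.full(n, speed_mps)
    else:
        speeds = np.zeros(n)
        for label, start, end in spec.activities:
            mask = (times >= start - 1e-12) & (times < end - 1e-12)
            speeds[mask] = speed_by_label.get(label, speed_mps)

    # integrate per-fix speed into north/east displacement
    step_m = np.concatenate([[0.0], speeds[:-1] * dt])
    dist_m = np.cumsum(step_m)
    north_m = dist_m * math.cos(theta)
    east_m = dist_m * math.sin(theta)
    lat = lat0_deg + north_m / M_PER_DEG_LAT
    m_per_deg_lon = M_PER_DEG_LAT * math.cos(math.radians(lat0_deg))
    lon = lon0_deg + east_m / m_per_deg_lon
    if jitter_deg > 0:
        lat = lat + rng.normal(0.0, jitter_deg, n)
        lon = lon + rng.normal(0.0, jitter_deg, n)
    return GpsTrack(times_s=times, lat_deg=lat, lon_deg=lon)
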