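"""Per-sensor denoising and tri-axial fusion.

IMU and ambient channels are low-passed with a third-order Butterworth filter
(cutoff 10% of Nyquist by default); GPS and audio channels get a kernel-3
median filter.  After filtering, tri-axial signals are fused into a single
magnitude via the Pythagorean theorem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .errors import ValidationError
from .io_formats import SensorRecording


@dataclass
class ButterworthSpec:
    """Low-pass Butterworth design: order ``n`` and normalized cutoff ``wn``.

    ``wn`` is a fraction of the Nyquist frequency in (0, 1); the critical
    frequency in Hz for a given sample rate is ``wn * rate / 2``.
    """

    order: int = 3
    wn: float = 0.1

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValidationError("Butterworth order must be >= 1")
        if not 0 < self.wn < 1:
            raise ValidationError("wn must lie in (0, 1)")

    def critical_freq_hz(self, sample_rate_hz: float) -> float:
        return self.wn * sample_rate_hz / 2.0


@dataclass
class MedianSpec:
    """Odd median-filter kernel; half-width k = (kernel - 1) // 2."""

    kernel: int = 3

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValidationError("median kernel must be odd and >= 1")

    @property
    def half_width(self) -> int:
        return (self.kernel - 1) // 2


@dataclass
class TriaxialSignal:
    """Equal-length x/y/z sample sequences in sensor units."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValidationError("tri-axial components have unequal lengths")

    def __len__(self) -> int:
        return len(self.x)


def butterworth_magnitude(f, fc: float | None = None, spec: ButterworthSpec | None = None,
                          sample_rate_hz: float | None = None):
    """Analytic magnitude response |H(f)| = 1 / sqrt(1 + (f/fc)^(2n)).

    Either pass ``fc`` (Hz) directly, or a spec plus sample rate from which
    the critical frequency is derived.  Strictly decreasing in ``f``; equals
    1 at DC and 1/sqrt(2) at ``fc`` for every order.
    """
    spec = spec or ButterworthSpec()
    if fc is None:
        if sample_rate_hz is None:
            raise ValidationError("need fc or sample_rate_hz to derive it")
        fc = spec.critical_freq_hz(sample_rate_hz)
    if fc <= 0:
        raise ValidationError("critical frequency must be > 0")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValidationError("frequency must be >= 0")
    out = 1.0 / np.sqrt(1.0 + (f / fc) ** (2 * spec.order))
    return float(out) if out.ndim == 0 else out


def butterworth_filter(signal, spec: ButterworthSpec | None = None,
                       zero_phase: bool = True) -> np.ndarray:
    """Digital low-pass via bilinear-transform design.

    Zero-phase forward-backward application by default (features are aligned
    to time windows, so phase lag is undesirable); set ``zero_phase=False``
    for a causal single pass.  Output length equals input length.
    """
    spec = spec or ButterworthSpec()
    x = np.asarray(signal, dtype=float)
    min_len = 3 * (spec.order + 1)
    if len(x) <= min_len:
        raise ValidationError(
            f"signal of length {len(x)} too short for order-{spec.order} filter "
            f"(need > {min_len})"
        )
    b, a = scipy.signal.butter(spec.order, spec.wn, btype="low")
    if zero_phase:
        return scipy.signal.filtfilt(b, a, x)
    return scipy.signal.lfilter(b, a, x)


def median_filter(signal, spec: MedianSpec | None = None) -> np.ndarray:
    """Sliding-window median with reflect padding; length preserved."""
    spec = spec or MedianSpec()
    x = np.asarray(signal, dtype=float)
    if len(x) == 0:
        raise ValidationError("signal must be non-empty")
    return scipy.ndimage.median_filter(x, size=spec.kernel, mode="reflect")


def magnitude(sig: TriaxialSignal) -> np.ndarray:
    """Per-sample Euclidean norm sqrt(Sx^2 + Sy^2 + Sz^2)."""
    return np.sqrt(sig.x ** 2 + sig.y ** 2 + sig.z ** 2)


def denoise_recording(
    rec: SensorRecording,
    butterworth: ButterworthSpec | None = None,
    median: MedianSpec | None = None,
) -> SensorRecording:
    """Apply the per-sensor routing to every channel of a recording.

    IMU/ambient/magnetometer channels get the Butterworth low-pass; GPS and
    audio channels get the median filter.  For a ``multi`` recording the
    routing is by channel name (``lat``/``lon``/``alt``/``audio`` median,
    everything else Butterworth).
    """
    butterworth = butterworth or ButterworthSpec()
    median = median or MedianSpec()
    median_kinds = {"gps", "audio"}
    median_channels = {"lat", "lon", "alt", "audio"}
    out: dict[str, np.ndarray] = {}
    for name, x in rec.channels.items():
        if rec.sensor_kind in median_kinds or name in median_channels:
            out[name] = median_filter(x, median)
        else:
            out[name] = butterworth_filter(x, butterworth)
    return SensorRecording(
        channels=out,
        sample_rate_hz=rec.sample_rate_hz,
        sensor_kind=rec.sensor_kind,
        labels=rec.labels,
        subject_id=rec.subject_id,
    )
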