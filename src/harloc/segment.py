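"""Blackman-windowed segmentation into fixed-length overlapping frames.

A 50-sample window represents 5 s at the default 10 Hz rate; consecutive
windows overlap by 25% (hop = round(0.75 * N) = 38 samples), and each
segment is multiplied element-wise by the Blackman taper
``W(n) = 0.42 - 0.5 cos(2 pi n / (N-1)) + 0.08 cos(4 pi n / (N-1))``
to reduce spectral leakage before frequency-domain feature extraction.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io_formats import SensorRecording

log = logging.getLogger(__name__)

BLACKMAN_COEFFS = (0.42, 0.5, 0.08)


@dataclass
class WindowSpec:
    """Window length, overlap fraction and taper coefficients."""

    n: int = 50
    overlap: float = 0.25
    coeffs: tuple[float, float, float] = BLACKMAN_COEFFS
    apply_taper: bool = True

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValidationError("window length must be >= 4")
        if not 0 <= self.overlap < 1:
            raise ValidationError("overlap fraction must lie in [0, 1)")
        if not 1 <= self.hop <= self.n:
            raise ValidationError("derived hop outside [1, N]")

    @property
    def hop(self) -> int:
        # round-half-up so 0.75 * 50 = 37.5 -> 38
        return int(np.floor((1.0 - self.overlap) * self.n + 0.5))


@dataclass
class Segment:
    """One windowed frame of a recording: per-channel values of length N."""

    channels: dict[str, np.ndarray]
    start_index: int
    label: str | None = None
    window_applied: bool = True
    sample_rate_hz: float = 10.0

    @property
    def n(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def start_time_s(self) -> float:
        return self.start_index / self.sample_rate_hz

    @property
    def end_time_s(self) -> float:
        return (self.start_index + self.n) / self.sample_rate_hz


def blackman_window(n: int, coeffs: tuple[float, float, float] = BLACKMAN_COEFFS) -> np.ndarray:
    """Symmetric Blackman taper of length ``n``: endpoints 0, odd-N center 1."""
    if n < 2:
        raise ValidationError("window length must be >= 2")
    a0, a1, a2 = coeffs
    k = np.arange(n)
    return a0 - a1 * np.cos(2 * np.pi * k / (n - 1)) + a2 * np.cos(4 * np.pi * k / (n - 1))


def label_segment(labels_per_sample, start: int, n: int,
                  on_unlabeled: str = "drop") -> str | None:
    """Majority label over ``[start, start+n)``; ties go to the class that
    occurs earliest within the window.

    Samples labelled ``None``/NaN count as unlabeled; a window containing any
    is dropped (returns None) or raises, per ``on_unlabeled``.
    """
    window = np.asarray(labels_per_sample)[start:start + n]
    if len(window) != n:
        raise ValidationError("labels do not cover the window")
    cleaned = [str(v) for v in window if v is not None and str(v) not in ("nan", "None", "")]
    if len(cleaned) != n:
        if on_unlabeled == "error":
            raise ValidationError(f"window at {start} crosses unlabeled samples")
        return None
    counts = Counter(cleaned)
    best = max(counts.values())
    # earliest-occurring tie-break
    for v in cleaned:
        if counts[v] == best:
            return v
    raise AssertionError("unreachable")


def segment_signal(rec: SensorRecording, spec: WindowSpec | None = None,
                   on_unlabeled: str = "drop") -> list[Segment]:
    """Slice a recording into Blackman-weighted segments.

    Segments start at 0, hop, 2*hop, ...; the trailing remainder shorter than
    N is discarded.  Count = floor((L - N)/hop) + 1.  A recording shorter
    than one window yields an empty list and a logged warning.
    """
    spec = spec or WindowSpec()
    length = rec.n_samples
    if length < spec.n:
        log.warning("recording length %d < window %d: no segments", length, spec.n)
        return []
    taper = blackman_window(spec.n, spec.coeffs) if spec.apply_taper else None
    segments: list[Segment] = []
    n_dropped = 0
    for start in range(0, length - spec.n + 1, spec.hop):
        label = None
        if rec.labels is not None:
            label = label_segment(rec.labels, start, spec.n, on_unlabeled)
            if label is None:
                n_dropped += 1
                continue
        channels = {}
        for name, x in rec.channels.items():
            window = x[start:start + spec.n].copy()
            if taper is not None:
                window = window * taper
            channels[name] = window
        segments.append(
            Segment(
                channels=channels,
                start_index=start,
                label=label,
                window_applied=spec.apply_taper,
                sample_rate_hz=rec.sample_rate_hz,
            )
        )
    if n_dropped:
        log.info("dropped %d windows crossing unlabeled samples", n_dropped)
    return segments
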