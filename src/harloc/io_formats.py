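"""Readers and writers for sensor streams, audio, feature matrices and reports.

Conventions: comma-separated CSV with a single header row and ``#``-prefixed
metadata comment lines, UTF-8, ``.`` decimal; 16-bit PCM WAV; JSON for
evaluation reports and fitted transform parameters.  Every reader either
returns a fully validated object or raises with a location-bearing message —
rows are never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io.wavfile

from .errors import FormatError, SchemaError, ValidationError

SENSOR_KINDS = {"imu", "ambient", "magnetometer", "gps", "audio", "multi"}

FEATURE_SCHEMA_VERSION = 1
REPORT_SCHEMA_VERSION = 1

_LABEL_COLUMN = "__label__"


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SensorRecording:
    """A labeled multichannel time series with a common sample rate.

    Parameters
    ----------
    channels
        Mapping of channel name to an equal-length 1-D float array.
    sample_rate_hz
        Samples per second, > 0.  Time is defined by index / rate.
    sensor_kind
        One of ``imu``, ``ambient``, ``magnetometer``, ``gps``, ``audio`` or
        ``multi`` for combined synthetic recordings.
    labels
        Optional per-sample class ids (strings), same length as the channels.
    """

    channels: dict[str, np.ndarray]
    sample_rate_hz: float
    sensor_kind: str = "imu"
    labels: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")
        if self.sensor_kind not in SENSOR_KINDS:
            raise ValidationError(f"unknown sensor_kind {self.sensor_kind!r}")
        if not self.channels:
            raise ValidationError("recording needs at least one channel")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValidationError(f"channels have unequal lengths: {sorted(lengths)}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_samples:
                raise ValidationError("labels length differs from channel length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class AudioRecording:
    """Mono audio samples in [-1, 1] at a known rate."""

    samples: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass
class GpsTrack:
    """Timestamped latitude/longitude/altitude fixes (degrees, metres)."""

    times_s: np.ndarray
    lat_deg: np.ndarray
    lon_deg: np.ndarray
    alt_m: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.lat_deg = np.asarray(self.lat_deg, dtype=float)
        self.lon_deg = np.asarray(self.lon_deg, dtype=float)
        if self.alt_m is None:
            self.alt_m = np.zeros_like(self.times_s)
        else:
            self.alt_m = np.asarray(self.alt_m, dtype=float)
        n = len(self.times_s)
        if not (len(self.lat_deg) == len(self.lon_deg) == len(self.alt_m) == n):
            raise ValidationError("GPS fields have unequal lengths")

    @property
    def n_fixes(self) -> int:
        return len(self.times_s)


@dataclass
class FeatureMatrix:
    """Named per-segment feature values for one task branch.

    ``values`` is a pandas DataFrame with one row per segment; ``labels`` is
    the class id per row; ``branch`` tags which task the bank belongs to
    (``locomotion`` or ``localization``).  No missing values are permitted
    after assembly and column names must be unique.
    """

    values: pd.DataFrame
    labels: np.ndarray
    branch: str = "locomotion"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.values):
            raise ValidationError("labels length differs from row count")
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise SchemaError(f"duplicate feature columns: {dupes}")
        if _LABEL_COLUMN in cols:
            raise SchemaError(f"{_LABEL_COLUMN} is a reserved column name")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Sensor CSV
# ---------------------------------------------------------------------------

def write_sensor_csv(rec: SensorRecording, path: str | Path) -> None:
    """Write a recording as commented CSV (metadata in ``#`` lines)."""
    path = Path(path)
    df = pd.DataFrame(rec.channels)
    if rec.labels is not None:
        df[_LABEL_COLUMN] = rec.labels
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_rate_hz={rec.sample_rate_hz!r}\n")
        fh.write(f"# sensor_kind={rec.sensor_kind}\n")
        fh.write(f"# subject_id={rec.subject_id}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def _read_comment_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_sensor_csv(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    sample_rate_hz: float | None = None,
) -> SensorRecording:
    """Read a delimited sensor stream.

    ``channel_map`` maps channel names to CSV column names; by default every
    non-reserved column becomes a channel under its own name.  The sample
    rate is taken from the argument, else from the file's metadata comments.
    Non-numeric cells in mapped columns and ragged rows are rejected with a
    location-bearing error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta = _read_comment_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas names the offending line
        raise FormatError(f"{path}: {exc}") from exc
    if channel_map is None:
        channel_map = {c: c for c in df.columns if c != _LABEL_COLUMN}
    missing = [col for col in channel_map.values() if col not in df.columns]
    if missing:
        raise SchemaError(f"{path}: header is missing required columns {missing}")
    channels: dict[str, np.ndarray] = {}
    for name, col in channel_map.items():
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna() & df[col].notna()]
        if len(bad) or values.isna().any():
            row = int((values.isna()).idxmax())
            raise FormatError(
                f"{path}: non-numeric or missing value in column {col!r} at data row {row}"
            )
        channels[name] = values.to_numpy(dtype=float)
    labels = df[_LABEL_COLUMN].to_numpy() if _LABEL_COLUMN in df.columns else None
    rate = sample_rate_hz
    if rate is None and "sample_rate_hz" in meta:
        rate = float(meta["sample_rate_hz"])
    if rate is None:
        raise SchemaError(f"{path}: sample rate not given and not stored in file")
    kind = meta.get("sensor_kind", "imu")
    return SensorRecording(
        channels=channels,
        sample_rate_hz=rate,
        sensor_kind=kind,
        labels=labels,
        subject_id=meta.get("subject_id", ""),
    )


# ---------------------------------------------------------------------------
# GPS CSV
# ---------------------------------------------------------------------------

def write_gps_csv(track: GpsTrack, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": track.times_s,
            "lat": track.lat_deg,
            "lon": track.lon_deg,
            "alt": track.alt_m,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_gps_csv(path: str | Path) -> GpsTrack:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    required = ["time_s", "lat", "lon"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing GPS columns {missing}")
    alt = df["alt"].to_numpy(dtype=float) if "alt" in df.columns else None
    return GpsTrack(
        times_s=df["time_s"].to_numpy(dtype=float),
        lat_deg=df["lat"].to_numpy(dtype=float),
        lon_deg=df["lon"].to_numpy(dtype=float),
        alt_m=alt,
    )


# ---------------------------------------------------------------------------
# WAV
# ---------------------------------------------------------------------------

def write_wav(rec: AudioRecording, path: str | Path) -> None:
    """Write mono 16-bit PCM; samples are clipped to [-1, 1] first."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    data = np.round(clipped * 32767.0).astype(np.int16)
    scipy.io.wavfile.write(str(path), int(rec.sample_rate_hz), data)


def read_wav(path: str | Path) -> AudioRecording:
    """Read a PCM WAV; the first channel is used, samples scaled to [-1, 1]."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        rate, data = scipy.io.wavfile.read(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 127.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(float)
    else:
        raise FormatError(f"{path}: unsupported WAV encoding {data.dtype}")
    samples = np.clip(samples, -1.0, 1.0)
    return AudioRecording(samples=samples, sample_rate_hz=float(rate))


# ---------------------------------------------------------------------------
# Feature CSV
# ---------------------------------------------------------------------------

def write_feature_csv(fm: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix losslessly to ~12 significant digits.

    The branch tag and schema version go into header comment lines; labels
    are stored in a reserved column.  Writing is refused if any value is NaN.
    """
    nan_cols = [c for c in fm.columns if fm.values[c].isna().any()]
    if nan_cols:
        raise ValidationError(f"feature matrix contains NaN in columns {nan_cols}")
    path = Path(path)
    df = fm.values.copy()
    df[_LABEL_COLUMN] = fm.labels
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema={FEATURE_SCHEMA_VERSION}\n")
        fh.write(f"# branch={fm.branch}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def read_feature_csv(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta = _read_comment_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if _LABEL_COLUMN not in df.columns:
        raise SchemaError(f"{path}: missing {_LABEL_COLUMN} column")
    labels = df[_LABEL_COLUMN].to_numpy()
    values = df.drop(columns=[_LABEL_COLUMN])
    return FeatureMatrix(values=values, labels=labels, branch=meta.get("branch", "locomotion"))


# ---------------------------------------------------------------------------
# JSON reports and transform parameters
# ---------------------------------------------------------------------------

def write_report(report, path: str | Path) -> None:
    """Serialize an ``evaluate.EvaluationReport`` (or its dict) as JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    payload["schema_version"] = REPORT_SCHEMA_VERSION
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from exc


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
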