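"""Reading, validation and resampling of multi-rate smartphone sensor recordings.

A recording is one subject-session: tri-axial accelerometer and gyroscope
streams sampled at a nominal (jittery) 60 Hz, a barometer stream at 6 Hz,
and a list of self-labeled activity bouts.  Timestamps are seconds relative
to session start.  Bout intervals are half-open ``[start_s, end_s)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ACTIVITIES: tuple[str, ...] = (
    "Sitting", "Lying", "Standing", "StairsUp", "StairsDown", "Walking",
)
STATIONARY: frozenset[str] = frozenset({"Sitting", "Lying", "Standing"})
AMBULATORY: frozenset[str] = frozenset({"StairsUp", "StairsDown", "Walking"})

SESSIONS: tuple[str, ...] = ("Lab1", "Home", "Lab2")
SESSION_ENVIRONMENT: dict[str, str] = {"Lab1": "lab", "Home": "home", "Lab2": "lab"}

SENSORS: tuple[str, ...] = ("accelerometer", "gyroscope", "barometer")
NOMINAL_RATES: dict[str, float] = {"accelerometer": 60.0, "gyroscope": 60.0, "barometer": 6.0}
#: analysis rates: inertial resampled to 50 Hz, barometer to 6 Hz
TARGET_RATES: dict[str, float] = {"accelerometer": 50.0, "gyroscope": 50.0, "barometer": 6.0}

_VALUE_COLUMNS: dict[str, tuple[str, ...]] = {
    "accelerometer": ("x", "y", "z"),
    "gyroscope": ("x", "y", "z"),
    "barometer": ("pressure_hPa",),
}


@dataclass
class SensorStream:
    """One sensor's timestamped samples.

    ``values`` has shape (n, 3) for inertial sensors (m/s^2 or rad/s) and
    (n, 1) for the barometer (hPa).  Timestamps are strictly increasing
    after :func:`validate_stream`.
    """

    sensor: str
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            self.values = self.values.T
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor {self.sensor!r}")
        want = len(_VALUE_COLUMNS[self.sensor])
        if self.values.shape[1] != want:
            raise ValueError(
                f"{self.sensor} expects {want} value column(s), got {self.values.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])


@dataclass
class LabeledBout:
    """One self-labeled activity interval, half-open ``[start_s, end_s)``.

    The ``true_activity`` / ``artifact_*`` fields carry generator ground
    truth when the recording is synthetic; they are ``None``/0 for real data
    and are not part of the on-disk label schema.
    """

    bout_id: str
    activity: str
    start_s: float
    end_s: float
    true_activity: str | None = None
    artifact_lead_s: float = 0.0
    artifact_trail_s: float = 0.0

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.activity!r}")
        if not self.end_s > self.start_s:
            raise ValueError("bout must satisfy end_s > start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def mislabeled(self) -> bool:
        return self.true_activity is not None and self.true_activity != self.activity


@dataclass
class SensorRecording:
    """All streams and labeled bouts for one subject-session."""

    subject_id: str
    session: str
    streams: dict[str, SensorStream]
    bouts: list[LabeledBout] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValueError(f"unknown session {self.session!r}")

    @property
    def environment(self) -> str:
        return SESSION_ENVIRONMENT[self.session]


def validate_stream(stream: SensorStream) -> tuple[SensorStream, int]:
    """Drop NaN rows and rows breaking strict timestamp monotonicity.

    Duplicated timestamps keep the first occurrence.  Returns the cleaned
    stream and the number of dropped rows.
    """
    t, v = stream.timestamps, stream.values
    ok = np.isfinite(t) & np.all(np.isfinite(v), axis=1)
    t, v = t[ok], v[ok]
    keep = np.ones(len(t), dtype=bool)
    last = -np.inf
    for i, ti in enumerate(t):
        if ti > last:
            last = ti
        else:
            keep[i] = False
    dropped = int((~ok).sum() + (~keep).sum())
    if dropped:
        log.info("%s: dropped %d invalid rows", stream.sensor, dropped)
    return (
        SensorStream(stream.sensor, t[keep], v[keep], stream.nominal_rate),
        dropped,
    )


def validate_recording(rec: SensorRecording) -> SensorRecording:
    """Validate all streams and reject bouts outside the stream span or
    overlapping an earlier bout (count logged)."""
    streams = {}
    for name, s in rec.streams.items():
        streams[name], _ = validate_stream(s)
    t0 = max(s.span[0] for s in streams.values())
    t1 = min(s.span[1] for s in streams.values() if s.sensor != "barometer")
    kept: list[LabeledBout] = []
    rejected = 0
    prev_end = -np.inf
    for b in sorted(rec.bouts, key=lambda b: b.start_s):
        if b.start_s < t0 - 1e-6 or b.end_s > t1 + 1e-6 or b.start_s < prev_end - 1e-9:
            rejected += 1
            continue
        kept.append(b)
        prev_end = b.end_s
    if rejected:
        log.warning("%s/%s: rejected %d bout(s) outside span or overlapping",
                    rec.subject_id, rec.session, rejected)
    return SensorRecording(rec.subject_id, rec.session, streams, kept, dict(rec.metadata))


def resample_stream(stream: SensorStream, target_rate: float) -> SensorStream:
    """Resample onto a uniform grid at ``target_rate`` by linear interpolation.

    The grid starts at the first timestamp and never extrapolates beyond the
    last.  Resampling an already grid-aligned stream at the same rate is the
    identity.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if stream.n_samples < 2:
        raise ValueError("cannot resample a stream with fewer than 2 samples")
    t = stream.timestamps
    n = int(np.floor((t[-1] - t[0]) * target_rate + 1e-9)) + 1
    grid = t[0] + np.arange(n) / target_rate
    vals = np.column_stack([np.interp(grid, t, stream.values[:, j])
                            for j in range(stream.values.shape[1])])
    return SensorStream(stream.sensor, grid, vals, target_rate)


# ---------------------------------------------------------------------------
# CSV round trip.  Files per recording:
#   <subject>_<session>_accelerometer.csv   timestamp_s,x,y,z
#   <subject>_<session>_gyroscope.csv       timestamp_s,x,y,z
#   <subject>_<session>_barometer.csv       timestamp_s,pressure_hPa
#   <subject>_<session>_labels.csv          bout_id,activity,start_s,end_s
# ---------------------------------------------------------------------------

def _stream_path(directory: Path, subject: str, session: str, sensor: str) -> Path:
    return Path(directory) / f"{subject}_{session}_{sensor}.csv"


def write_recording(rec: SensorRecording, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for sensor, stream in rec.streams.items():
        df = pd.DataFrame(stream.values, columns=list(_VALUE_COLUMNS[sensor]))
        df.insert(0, "timestamp_s", stream.timestamps)
        path = _stream_path(directory, rec.subject_id, rec.session, sensor)
        df.to_csv(path, index=False, float_format="%.6f")
        written.append(path)
    labels = pd.DataFrame(
        [(b.bout_id, b.activity, b.start_s, b.end_s) for b in rec.bouts],
        columns=["bout_id", "activity", "start_s", "end_s"],
    )
    lp = Path(directory) / f"{rec.subject_id}_{rec.session}_labels.csv"
    labels.to_csv(lp, index=False, float_format="%.6f")
    written.append(lp)
    return written


def read_recording(
    directory: str | Path,
    subject_id: str,
    session: str,
    require_barometer: bool = False,
    metadata: dict | None = None,
) -> SensorRecording:
    """Read one recording from the CSV layout above.

    Missing accelerometer or gyroscope files are hard errors; a missing
    barometer file is allowed unless ``require_barometer`` (its features are
    later emitted as missing).  An empty label file yields zero bouts with a
    warning.
    """
    directory = Path(directory)
    streams: dict[str, SensorStream] = {}
    for sensor in SENSORS:
        path = _stream_path(directory, subject_id, session, sensor)
        if not path.exists():
            if sensor == "barometer" and not require_barometer:
                continue
            raise FileNotFoundError(f"required sensor file missing: {path}")
        df = pd.read_csv(path)
        cols = list(_VALUE_COLUMNS[sensor])
        streams[sensor] = SensorStream(
            sensor, df["timestamp_s"].to_numpy(), df[cols].to_numpy(),
            NOMINAL_RATES[sensor],
        )
    lp = directory / f"{subject_id}_{session}_labels.csv"
    bouts: list[LabeledBout] = []
    if lp.exists():
        labels = pd.read_csv(lp)
        for row in labels.itertuples(index=False):
            bouts.append(LabeledBout(str(row.bout_id), row.activity,
                                     float(row.start_s), float(row.end_s)))
        if not bouts:
            warnings.warn(f"empty label file: {lp}", stacklevel=2)
    else:
        warnings.warn(f"label file missing: {lp}", stacklevel=2)
    rec = SensorRecording(subject_id, session, streams, bouts, metadata or {})
    return validate_recording(rec)


def accel_norm(rec: SensorRecording, rate: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Timestamps and Euclidean norm of the (optionally resampled) accelerometer."""
    s = rec.streams["accelerometer"]
    if rate is not None:
        s = resample_stream(s, rate)
    return s.timestamps, np.linalg.norm(s.values, axis=1)


def resample_recording(rec: SensorRecording) -> SensorRecording:
    """Resample every stream to its analysis rate (inertial 50 Hz, barometer 6 Hz)."""
    streams = {name: resample_stream(s, TARGET_RATES[name]) for name, s in rec.streams.items()}
    return SensorRecording(rec.subject_id, rec.session, streams, list(rec.bouts), dict(rec.metadata))
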