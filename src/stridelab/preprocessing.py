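"""Bout cleaning and clip segmentation.

Self-labeling on the phone requires removing it from its pouch, which
injects high-amplitude broadband noise at the start and end of each labeled
bout.  Sample entropy of the accelerometer norm separates this handling
noise (irregular, high entropy) from genuine activity signal (smooth sway
or quasi-periodic gait, low entropy), so bouts are trimmed from each end
with an activity-dependent entropy threshold.  Obviously mislabeled
ambulatory bouts (near-flat inertial signal) are dropped.  Surviving bouts
are cut into 10-second clips with 90% overlap: 500 samples per inertial
axis at 50 Hz and 60 barometer samples at 6 Hz per clip.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .sensor_io import (
    AMBULATORY,
    ACTIVITIES,
    LabeledBout,
    SensorRecording,
    resample_recording,
)

INERTIAL_RATE = 50.0
BARO_RATE = 6.0
WINDOW_S = 10.0
OVERLAP = 0.9
CLIP_INERTIAL_SAMPLES = 500
CLIP_BARO_SAMPLES = 60

#: default per-activity sample-entropy thresholds on the accelerometer norm.
#: Quasi-periodic gait is highly regular (entropy well below 1); stationary
#: signal is smooth sway plus a sensor-noise floor (up to ~1.1); handling
#: noise is broadband (~2.2).  Thresholds sit between each activity's clean
#: ceiling and the artifact floor.
DEFAULT_ENTROPY_THRESHOLDS: dict[str, float] = {
    "Sitting": 1.3, "Lying": 1.3, "Standing": 1.3,
    "StairsUp": 0.8, "StairsDown": 0.8, "Walking": 0.8,
}


@dataclass
class TrimConfig:
    subwindow_s: float = 1.0     # entropy subwindow; must not exceed the shortest artifact
    step_s: float = 0.1          # slide of the subwindow when locating the boundary
    embedding_m: int = 2
    tolerance_r: float = 0.2     # fraction of the subwindow SD
    tolerance_floor: float = 0.02  # m/s^2; scale floor so near-still windows
                                   # are not scored against their noise floor
    max_trim_s: float = 5.0      # per end
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ENTROPY_THRESHOLDS))

    def __post_init__(self):
        if self.subwindow_s <= 0 or self.step_s <= 0:
            raise ValueError("subwindow_s and step_s must be positive")
        if self.embedding_m < 1:
            raise ValueError("embedding_m must be >= 1")
        if self.tolerance_r <= 0:
            raise ValueError("tolerance_r must be positive")
        missing = set(ACTIVITIES) - set(self.thresholds)
        if missing:
            raise ValueError(f"thresholds missing for {sorted(missing)}")


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Sample entropy SampEn(m, r) of a 1-D series.

    ``-ln(A/B)`` where ``B`` counts pairs of length-``m`` templates within
    Chebyshev distance ``r`` (self-matches excluded) and ``A`` counts
    length-``m+1`` template pairs.  ``r`` is an absolute tolerance.  Returns
    ``inf`` when no (m+1)-matches exist; a constant series returns 0.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    # Both template lengths use the same n - m starting positions (the
    # standard convention, which makes a constant series score exactly 0).
    # Chebyshev distance between templates starting at i and j is the running
    # maximum of |x[i+k] - x[j+k]| along the diagonals of the pointwise
    # distance matrix, so both counts come from one pass.
    d1 = np.abs(x[:, None] - x[None, :])
    nt = n - m

    def _count(mm: int) -> int:
        d = d1[:nt, :nt].copy()
        for k in range(1, mm):
            np.maximum(d, d1[k:k + nt, k:k + nt], out=d)
        # ordered pairs i != j, halved -> unordered
        return int(((d <= r).sum() - nt) // 2)

    b = _count(m)
    a = _count(m + 1)
    if a == 0 or b == 0:
        return float("inf")
    return float(-np.log(a / b))


@dataclass
class TrimReport:
    bout_id: str
    activity: str
    lead_trim_s: float
    trail_trim_s: float
    warning: str | None = None


def _entropy_at(x: np.ndarray, start: int, w: int, m: int, r_frac: float,
                scale_floor: float = 0.0) -> float:
    seg = x[start:start + w]
    scale = max(float(seg.std()), scale_floor)
    if scale == 0.0:
        return 0.0
    return sample_entropy(seg, m=m, r=r_frac * scale)


def _trim_one_end(x: np.ndarray, fs: float, threshold: float, cfg: TrimConfig) -> float:
    """Seconds to trim from the start of ``x`` (pass a reversed array for the end).

    Handling artifacts are anchored at the bout edge, so the trim extends to
    the end of the last sliding subwindow whose entropy exceeds the
    threshold.  Subwindows straddling the artifact/clean boundary can read
    as regular (the artifact inflates the SD-relative tolerance), so the
    scan keeps looking one full subwindow past the last exceedance before
    stopping.
    """
    w = int(round(cfg.subwindow_s * fs))
    step = max(1, int(round(cfg.step_s * fs)))
    max_off = int(round(cfg.max_trim_s * fs))
    patience = max(1, w // step)
    off = 0
    clean_run = 0
    last_dirty_end = 0
    while off + w <= len(x) and off < max_off:
        e = _entropy_at(x, off, w, cfg.embedding_m, cfg.tolerance_r,
                        cfg.tolerance_floor)
        if e > threshold:
            last_dirty_end = off + w
            clean_run = 0
        else:
            clean_run += 1
            if clean_run >= patience:
                break
        off += step
    return min(last_dirty_end, max_off) / fs


def trim_bout(
    rec: SensorRecording,
    bout: LabeledBout,
    cfg: TrimConfig | None = None,
    norm_t: np.ndarray | None = None,
    norm_v: np.ndarray | None = None,
) -> tuple[LabeledBout, TrimReport]:
    """Trim handling artifacts from both ends of one bout.

    Contiguous entropy subwindows above the activity's threshold are removed
    from each end, up to ``max_trim_s`` per end; the interior is never
    touched.  Bouts too short for two subwindows are returned untrimmed with
    a warning in the report.
    """
    cfg = cfg or TrimConfig()
    if norm_t is None or norm_v is None:
        from .sensor_io import accel_norm
        norm_t, norm_v = accel_norm(rec, rate=INERTIAL_RATE)
    if bout.duration_s <= 2 * cfg.subwindow_s:
        return bout, TrimReport(bout.bout_id, bout.activity, 0.0, 0.0,
                                warning="bout shorter than 2*subwindow_s, not trimmed")
    sel = (norm_t >= bout.start_s) & (norm_t < bout.end_s)
    x = norm_v[sel]
    if len(x) < 2 * int(round(cfg.subwindow_s * INERTIAL_RATE)):
        return bout, TrimReport(bout.bout_id, bout.activity, 0.0, 0.0,
                                warning="too few samples, not trimmed")
    thr = cfg.thresholds[bout.activity]
    lead = _trim_one_end(x, INERTIAL_RATE, thr, cfg)
    trail = _trim_one_end(x[::-1], INERTIAL_RATE, thr, cfg)
    # never trim the bout away entirely
    if bout.duration_s - lead - trail < 1.0 / INERTIAL_RATE:
        overshoot = lead + trail - bout.duration_s + 1.0
        lead = max(lead - overshoot / 2, 0.0)
        trail = max(trail - overshoot / 2, 0.0)
    trimmed = replace(bout, start_s=bout.start_s + lead, end_s=bout.end_s - trail)
    return trimmed, TrimReport(bout.bout_id, bout.activity, lead, trail)


@dataclass
class RejectionReport:
    bout_id: str
    activity: str
    reason: str


def drop_mislabeled(
    rec: SensorRecording,
    flatness_threshold: float = 0.05,
    norm_t: np.ndarray | None = None,
    norm_v: np.ndarray | None = None,
) -> tuple[SensorRecording, list[RejectionReport]]:
    """Remove ambulatory-labeled bouts with a near-flat accelerometer norm.

    A "Walking"/"Stairs" bout whose accelerometer-norm SD over the whole
    bout falls below ``flatness_threshold`` (m/s^2) cannot be genuine gait
    and is treated as a labeling mistake.  Stationary labels are never
    dropped by this rule.
    """
    if norm_t is None or norm_v is None:
        from .sensor_io import accel_norm
        norm_t, norm_v = accel_norm(rec, rate=INERTIAL_RATE)
    kept, rejected = [], []
    for b in rec.bouts:
        if b.activity in AMBULATORY:
            sel = (norm_t >= b.start_s) & (norm_t < b.end_s)
            sd = float(norm_v[sel].std()) if sel.any() else 0.0
            if sd < flatness_threshold:
                rejected.append(RejectionReport(
                    b.bout_id, b.activity,
                    f"ambulatory label with flat signal (SD={sd:.4f} m/s^2)"))
                continue
        kept.append(b)
    out = SensorRecording(rec.subject_id, rec.session, rec.streams, kept,
                          dict(rec.metadata))
    return out, rejected


@dataclass
class Clip:
    """One 10-second analysis instance."""

    subject_id: str
    session: str
    environment: str
    activity: str
    start_s: float
    bout_id: str
    accel: np.ndarray           # (500, 3) at 50 Hz
    gyro: np.ndarray            # (500, 3) at 50 Hz
    baro: np.ndarray | None     # (60,) at 6 Hz, None when the sensor is absent
    bout_duration_s: float = np.nan

    def __post_init__(self):
        if self.accel.shape != (CLIP_INERTIAL_SAMPLES, 3):
            raise ValueError(f"accel shape {self.accel.shape}")
        if self.gyro.shape != (CLIP_INERTIAL_SAMPLES, 3):
            raise ValueError(f"gyro shape {self.gyro.shape}")
        if self.baro is not None and self.baro.shape != (CLIP_BARO_SAMPLES,):
            raise ValueError(f"baro shape {self.baro.shape}")

    @property
    def end_s(self) -> float:
        return self.start_s + WINDOW_S


def clip_count(duration_s: float, window_s: float = WINDOW_S,
               overlap: float = OVERLAP) -> int:
    """Number of clips from a bout of the given duration.

    Clips start every ``window_s * (1 - overlap)`` seconds (1 s at the
    defaults): ``floor((T - window) / step) + 1`` for ``T >= window``, else 0.
    """
    if window_s <= 0 or not 0 <= overlap < 1:
        raise ValueError("need window_s > 0 and 0 <= overlap < 1")
    step = window_s * (1 - overlap)
    if duration_s < window_s - 1e-9:
        return 0
    return int(np.floor((duration_s - window_s) / step + 1e-9)) + 1


def _grid_values(stream, t0: float, n: int, rate: float) -> np.ndarray:
    grid = t0 + np.arange(n) / rate
    t, v = stream.timestamps, stream.values
    return np.column_stack([np.interp(grid, t, v[:, j]) for j in range(v.shape[1])])


def segment_bout(
    rec: SensorRecording,
    bout: LabeledBout,
    window_s: float = WINDOW_S,
    overlap: float = OVERLAP,
) -> list[Clip]:
    """Cut one (trimmed) bout into overlapping clips.

    The clip grid is anchored at the bout start; inertial channels are
    interpolated onto a 50 Hz grid and the barometer onto a 6 Hz grid, both
    spanning exactly the clipped portion of the bout.
    """
    n_clips = clip_count(bout.duration_s, window_s, overlap)
    if n_clips == 0:
        return []
    step = window_s * (1 - overlap)
    in_step = int(round(step * INERTIAL_RATE))
    ba_step = int(round(step * BARO_RATE))
    n_in = CLIP_INERTIAL_SAMPLES + (n_clips - 1) * in_step
    n_ba = CLIP_BARO_SAMPLES + (n_clips - 1) * ba_step
    acc = _grid_values(rec.streams["accelerometer"], bout.start_s, n_in, INERTIAL_RATE)
    gyr = _grid_values(rec.streams["gyroscope"], bout.start_s, n_in, INERTIAL_RATE)
    baro = None
    if "barometer" in rec.streams:
        baro = _grid_values(rec.streams["barometer"], bout.start_s, n_ba, BARO_RATE)[:, 0]
    clips = []
    for i in range(n_clips):
        clips.append(Clip(
            subject_id=rec.subject_id, session=rec.session,
            environment=rec.environment, activity=bout.activity,
            start_s=bout.start_s + i * step, bout_id=bout.bout_id,
            accel=acc[i * in_step:i * in_step + CLIP_INERTIAL_SAMPLES],
            gyro=gyr[i * in_step:i * in_step + CLIP_INERTIAL_SAMPLES],
            baro=None if baro is None else baro[i * ba_step:i * ba_step + CLIP_BARO_SAMPLES],
            bout_duration_s=bout.duration_s,
        ))
    return clips


@dataclass
class PreprocessReport:
    trims: list[TrimReport]
    rejections: list[RejectionReport]


def preprocess_recording(
    rec: SensorRecording,
    trim_cfg: TrimConfig | None = None,
    flatness_threshold: float = 0.05,
) -> tuple[list[Clip], PreprocessReport]:
    """Full per-recording pipeline: resample, drop mislabels, trim, segment."""
    trim_cfg = trim_cfg or TrimConfig()
    rec = resample_recording(rec)
    norm_t = rec.streams["accelerometer"].timestamps
    norm_v = np.linalg.norm(rec.streams["accelerometer"].values, axis=1)
    rec, rejections = drop_mislabeled(rec, flatness_threshold, norm_t, norm_v)
    clips: list[Clip] = []
    trims: list[TrimReport] = []
    for bout in rec.bouts:
        trimmed, report = trim_bout(rec, bout, trim_cfg, norm_t, norm_v)
        trims.append(report)
        clips.extend(segment_bout(rec, trimmed))
    return clips, PreprocessReport(trims, rejections)
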