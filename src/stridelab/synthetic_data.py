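"""Synthetic multi-sensor recordings for healthy and stroke cohorts.

No public dataset exists for the waist-worn-smartphone activity study this
package analyses, so this module generates labeled recordings with the
statistical structure the downstream pipeline assumes:

* stationary activities (Sitting, Lying, Standing) dominated by a constant
  gravity component in a posture-specific direction plus low-frequency sway;
* quasi-periodic gait (Walking, stairs) whose cadence and amplitude grow
  with gait speed and whose cycle-to-cycle variability shrinks with it —
  severe impairment therefore produces walking that is close, in signal
  terms, to standing, which is the mechanism behind the
  ambulatory-as-stationary confusion the evaluation designs probe;
* barometric pressure falling during stair ascent and rising during descent;
* phone-handling artifacts (1-3 s of high-amplitude broadband noise) at
  bout edges, occasional label swaps, and bout-level data drop;
* a per-subject random phone orientation, re-drawn with a per-session
  wobble, applied to all body-frame inertial signals;
* larger behavioural variability and a different activity mix at home than
  in the lab.

All coefficients are stand-ins chosen for qualitative realism (documented
in docs/methods.md); none are estimates from real subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .sensor_io import (
    ACTIVITIES,
    AMBULATORY,
    LabeledBout,
    SESSION_ENVIRONMENT,
    SensorRecording,
    SensorStream,
    STATIONARY,
    write_recording,
)

GRAVITY = 9.81  # m/s^2

IMPAIRMENT_LEVELS = ("mild", "moderate", "severe")


def impairment_from_speed(gait_speed: float, cohort: str) -> str:
    """Impairment stratum from 10-meter-walk-test preferred speed.

    Thresholds: mild > 0.8 m/s, moderate in [0.4, 0.8] m/s, severe < 0.4 m/s;
    healthy subjects are 'none'.
    """
    if gait_speed <= 0:
        raise ValueError("gait_speed must be positive")
    if cohort == "healthy":
        return "none"
    if gait_speed > 0.8:
        return "mild"
    if gait_speed >= 0.4:
        return "moderate"
    return "severe"


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    cohort: str  # 'healthy' | 'stroke'
    gait_speed: float  # m/s, 10MWT preferred speed
    environment_variability: float = 1.5  # noise/variability multiplier at home
    phone_orientation: np.ndarray | None = None  # 3x3 rotation, body->phone

    def __post_init__(self):
        if self.cohort not in ("healthy", "stroke"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.gait_speed <= 0:
            raise ValueError("gait_speed must be positive")

    @property
    def impairment(self) -> str:
        return impairment_from_speed(self.gait_speed, self.cohort)


@dataclass(frozen=True)
class ActivityModelParams:
    """Generative parameters for one activity at one gait speed."""

    gravity_dir: np.ndarray  # unit vector, body frame
    sway_sd: float  # m/s^2, low-frequency postural sway
    cadence_hz: float  # step frequency (0 for stationary)
    step_amplitude: float  # m/s^2 vertical oscillation amplitude
    variability_sd: float  # relative cadence/amplitude modulation SD
    baro_trend_hpa_s: float  # negative going up, positive going down
    baro_noise_sd: float  # hPa

    def __post_init__(self):
        g = np.asarray(self.gravity_dir, float)
        object.__setattr__(self, "gravity_dir", g / np.linalg.norm(g))
        if self.cadence_hz < 0 or self.step_amplitude < 0:
            raise ValueError("cadence and amplitude must be nonnegative")


#: generator coefficients (synthetic stand-ins; see docs/methods.md)
DEFAULT_COEFFS: dict[str, float] = {
    "cadence_base_hz": 0.5,        # cadence = base + slope * gait_speed
    "cadence_slope": 1.2,
    "amp_slope": 2.0,              # step amplitude = slope * gait_speed (m/s^2 per m/s)
    "stair_amp_factor": 0.85,
    "stair_cadence_factor": 0.95,
    "gyro_amp_slope": 0.9,         # rad/s per m/s
    "variability_hi": 0.18,        # relative SD at very low speed ...
    "variability_slope": 0.10,     # ... falling linearly with speed
    "variability_lo": 0.03,
    "sensor_noise_sd": 0.002,      # m/s^2 wideband accelerometer noise
    "gyro_noise_sd": 0.005,
    "baro_noise_sd": 0.03,         # hPa
    "baro_base_hpa": 1013.0,
    "pressure_per_m": 0.115,       # hPa per vertical meter (lapse approximation)
    "climb_base": 0.08,            # vertical m/s = base + slope * gait_speed
    "climb_slope": 0.22,
    "artifact_amp": 6.0,           # m/s^2 broadband handling noise
    "artifact_gyro_amp": 2.5,      # rad/s
    "home_speed_factor": 0.92,     # gait slightly slower at home
    "orientation_wobble_deg": 8.0, # per-session pouch placement wobble
}

_SWAY_SD = {"Sitting": 0.030, "Lying": 0.020, "Standing": 0.045,
            "Walking": 0.045, "StairsUp": 0.045, "StairsDown": 0.045}
_GRAVITY_DIR = {
    "Sitting": (0.0, 0.42, 0.91),   # reclined ~25 degrees
    "Lying": (0.0, 0.98, 0.20),     # near-horizontal trunk
    "Standing": (0.0, 0.0, 1.0),
    "Walking": (0.0, 0.0, 1.0),
    "StairsUp": (0.0, 0.10, 0.995),
    "StairsDown": (0.0, -0.10, 0.995),
}


def activity_params(
    activity: str,
    profile: SubjectProfile,
    environment: str = "lab",
    coeffs: dict[str, float] | None = None,
) -> ActivityModelParams:
    """Generative parameters for one activity of one subject in one setting."""
    c = dict(DEFAULT_COEFFS)
    if coeffs:
        c.update(coeffs)
    env_mult = profile.environment_variability if environment == "home" else 1.0
    v = profile.gait_speed
    if environment == "home":
        v *= c["home_speed_factor"]
    sway = _SWAY_SD[activity] * env_mult
    if activity in STATIONARY:
        cadence, amp = 0.0, 0.0
    else:
        cadence = c["cadence_base_hz"] + c["cadence_slope"] * v
        amp = c["amp_slope"] * v
        if activity in ("StairsUp", "StairsDown"):
            cadence *= c["stair_cadence_factor"]
            amp *= c["stair_amp_factor"]
    variability = float(np.clip(c["variability_hi"] - c["variability_slope"] * v,
                                c["variability_lo"], c["variability_hi"]))
    trend = 0.0
    if activity in ("StairsUp", "StairsDown"):
        climb = c["climb_base"] + c["climb_slope"] * v
        trend = c["pressure_per_m"] * climb
        trend = -trend if activity == "StairsUp" else trend
    return ActivityModelParams(
        gravity_dir=np.asarray(_GRAVITY_DIR[activity]),
        sway_sd=sway,
        cadence_hz=cadence,
        step_amplitude=amp,
        variability_sd=variability * env_mult,
        baro_trend_hpa_s=trend,
        baro_noise_sd=c["baro_noise_sd"] * env_mult,
    )


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

#: bouts per session: {activity: (count, min_duration_s, max_duration_s)}
LAB_BOUT_PLAN: dict[str, tuple[int, float, float]] = {
    "Sitting": (3, 32.0, 42.0),
    "Lying": (3, 32.0, 42.0),
    "Standing": (3, 32.0, 42.0),
    "Walking": (3, 28.0, 38.0),
    "StairsUp": (3, 30.0, 40.0),
    "StairsDown": (3, 30.0, 40.0),
}
HOME_BOUT_PLAN: dict[str, tuple[int, float, float]] = {
    "Sitting": (4, 32.0, 44.0),
    "Lying": (3, 32.0, 44.0),
    "Standing": (3, 32.0, 44.0),
    "Walking": (4, 26.0, 38.0),
    "StairsUp": (3, 30.0, 40.0),
    "StairsDown": (3, 30.0, 40.0),
}

_SPEED_RANGES = {"mild": (0.85, 1.20), "moderate": (0.45, 0.78), "severe": (0.18, 0.38)}


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Stroke subjects record three sessions (Lab1, Home, Lab2); healthy
    subjects record at home only, with ``healthy_bout_multiplier`` scaling
    their bout counts (the healthy cohort labeled far more data).
    """

    n_healthy: int = 8
    n_mild: int = 6
    n_moderate: int = 6
    n_severe: int = 6
    lab_bout_plan: dict[str, tuple[int, float, float]] = field(
        default_factory=lambda: dict(LAB_BOUT_PLAN))
    home_bout_plan: dict[str, tuple[int, float, float]] = field(
        default_factory=lambda: dict(HOME_BOUT_PLAN))
    healthy_bout_multiplier: int = 2
    artifact_rate: float = 0.25
    mislabel_rate: float = 0.03
    drop_rate: float = 0.05
    environment_variability: float = 1.5
    healthy_speed_mean: float = 1.3
    healthy_speed_sd: float = 0.1
    gap_range_s: tuple[float, float] = (2.0, 5.0)
    coeffs: dict[str, float] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self):
        for r in (self.artifact_rate, self.mislabel_rate, self.drop_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for plan in (self.lab_bout_plan, self.home_bout_plan):
            for act, (n, lo, hi) in plan.items():
                if act not in ACTIVITIES:
                    raise ValueError(f"unknown activity {act!r}")
                if lo <= 0 or hi < lo:
                    raise ValueError("invalid duration range")

    def bout_plan(self, environment: str) -> dict[str, tuple[int, float, float]]:
        return self.lab_bout_plan if environment == "lab" else self.home_bout_plan

    def prevalence(self, environment: str) -> dict[str, float]:
        """Expected class prevalence (fraction of labeled seconds) per setting."""
        plan = self.bout_plan(environment)
        secs = {a: n * (lo + hi) / 2 for a, (n, lo, hi) in plan.items()}
        tot = sum(secs.values())
        return {a: s / tot for a, s in secs.items()}


def study_scale_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Cohort sized like the original study: 15 healthy, 30 stroke (8/13/9)."""
    kw = dict(n_healthy=15, n_mild=8, n_moderate=13, n_severe=9, rng_seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _small_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    """Small random rotation with per-axis angles ~ N(0, sd_deg)."""
    ax, ay, az = np.deg2rad(rng.normal(0.0, sd_deg, size=3))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _smooth_noise(rng: np.random.Generator, n: int, fs: float,
                  cutoff_hz: float = 1.5, sd: float = 1.0) -> np.ndarray:
    """Low-pass-filtered Gaussian noise rescaled to the requested SD."""
    if n < 30:
        return rng.normal(0.0, sd, n)
    b, a = sps.butter(2, cutoff_hz / (fs / 2), btype="low")
    x = sps.filtfilt(b, a, rng.standard_normal(n))
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _gait_waveform(rng: np.random.Generator, t: np.ndarray,
                   p: ActivityModelParams, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Body-frame accelerometer and gyroscope oscillation for one gait bout."""
    n = len(t)
    # instantaneous cadence with smooth cycle-to-cycle variability
    f_mod = 1.0 + _smooth_noise(rng, n, fs, cutoff_hz=0.6, sd=p.variability_sd)
    phase = 2 * np.pi * np.cumsum(p.cadence_hz * np.clip(f_mod, 0.2, None)) / fs
    amp_mod = 1.0 + _smooth_noise(rng, n, fs, cutoff_hz=0.6, sd=0.5 * p.variability_sd)
    a = p.step_amplitude * np.clip(amp_mod, 0.1, None)
    phi = rng.uniform(0, 2 * np.pi)
    acc = np.zeros((n, 3))
    acc[:, 2] = a * np.sin(phase + phi) + 0.40 * a * np.sin(2 * (phase + phi) + 0.7)
    acc[:, 1] = 0.50 * a * np.sin(phase + phi + np.pi / 2)
    acc[:, 0] = 0.30 * a * np.sin(0.5 * (phase + phi))
    g_amp = a / max(DEFAULT_COEFFS["amp_slope"], 1e-9) * DEFAULT_COEFFS["gyro_amp_slope"]
    gyr = np.zeros((n, 3))
    gyr[:, 0] = g_amp * np.sin(phase + phi + 0.3)
    gyr[:, 1] = 0.6 * g_amp * np.sin(0.5 * (phase + phi) + 1.1)
    gyr[:, 2] = 0.4 * g_amp * np.sin(phase + phi + 2.0)
    return acc, gyr


def _jittered_times(rng: np.random.Generator, duration: float, rate: float,
                    jitter_sd: float) -> np.ndarray:
    n = max(int(round(duration * rate)), 2)
    dt = 1.0 / rate + rng.normal(0.0, jitter_sd, n)
    dt = np.clip(dt, 0.2 / rate, None)
    t = np.cumsum(dt) - dt[0]
    return t * (duration / t[-1]) if t[-1] > 0 else t


@dataclass
class _BoutPlanEntry:
    bout_id: str
    activity: str       # label shown
    true_activity: str  # signal generated
    start_s: float
    end_s: float
    artifact_lead_s: float
    artifact_trail_s: float
    dropped: bool


def _plan_session(rng: np.random.Generator, spec: CohortSpec, environment: str,
                  subject_id: str, session: str, multiplier: int = 1) -> list[_BoutPlanEntry]:
    plan = spec.bout_plan(environment)
    entries: list[tuple[str, float]] = []
    for act, (count, lo, hi) in plan.items():
        for _ in range(count * multiplier):
            entries.append((act, float(rng.uniform(lo, hi))))
    order = rng.permutation(len(entries))
    t = float(rng.uniform(*spec.gap_range_s))
    out: list[_BoutPlanEntry] = []
    for k, idx in enumerate(order):
        true_act, dur = entries[idx]
        label = true_act
        if rng.random() < spec.mislabel_rate:
            others = [a for a in ACTIVITIES if a != true_act]
            label = others[rng.integers(len(others))]
        lead = trail = 0.0
        if rng.random() < spec.artifact_rate:
            lead = float(rng.uniform(1.0, 3.0))
            trail = float(rng.uniform(1.0, 3.0))
        dropped = bool(rng.random() < spec.drop_rate)
        out.append(_BoutPlanEntry(
            bout_id=f"{subject_id}_{session}_b{k:03d}",
            activity=label, true_activity=true_act,
            start_s=t, end_s=t + dur,
            artifact_lead_s=lead, artifact_trail_s=trail, dropped=dropped,
        ))
        t += dur + float(rng.uniform(*spec.gap_range_s))
    return out


def generate_subject(
    profile: SubjectProfile,
    spec: CohortSpec,
    session: str,
    rng: np.random.Generator | None = None,
    bout_multiplier: int = 1,
) -> SensorRecording:
    """Generate one subject-session recording.

    Streams: accelerometer/gyroscope at a jittery ~60 Hz, barometer at 6 Hz.
    Bouts carry ground-truth mislabel and artifact annotations for testing.
    """
    if session not in SESSION_ENVIRONMENT:
        raise ValueError(f"unknown session {session!r}")
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    environment = SESSION_ENVIRONMENT[session]
    c = dict(DEFAULT_COEFFS)
    c.update(spec.coeffs)

    entries = _plan_session(rng, spec, environment, profile.subject_id, session,
                            multiplier=bout_multiplier)
    kept = [e for e in entries if not e.dropped]
    total = (kept[-1].end_s + 5.0) if kept else 10.0

    base_R = profile.phone_orientation
    if base_R is None:
        base_R = _random_rotation(rng)
    wobble = c["orientation_wobble_deg"]
    if environment == "home":
        wobble *= profile.environment_variability
    R = base_R @ _small_rotation(rng, wobble)

    t_acc = _jittered_times(rng, total, 60.0, 0.002)
    t_gyr = _jittered_times(rng, total, 60.0, 0.002)
    t_bar = _jittered_times(rng, total, 6.0, 0.005)

    fs = 60.0
    acc_body = np.zeros((len(t_acc), 3))
    gyr_body = np.zeros((len(t_gyr), 3))
    pressure = np.full(len(t_bar), c["baro_base_hpa"], float)
    # slow ambient pressure drift over the session
    pressure += _smooth_noise(rng, len(t_bar), 6.0, cutoff_hz=0.01, sd=0.05)
    altitude = 0.0

    # idle (standing-like) background everywhere, overwritten inside bouts
    idle = activity_params("Standing", profile, environment, c)
    acc_body += idle.gravity_dir * GRAVITY
    for axis in range(3):
        acc_body[:, axis] += _smooth_noise(rng, len(t_acc), fs, sd=0.5 * idle.sway_sd)
        gyr_body[:, axis] += _smooth_noise(rng, len(t_gyr), fs, sd=c["gyro_noise_sd"])

    bouts: list[LabeledBout] = []
    for e in kept:
        p = activity_params(e.true_activity, profile, environment, c)
        ia = (t_acc >= e.start_s) & (t_acc < e.end_s)
        ig = (t_gyr >= e.start_s) & (t_gyr < e.end_s)
        ib = (t_bar >= e.start_s) & (t_bar < e.end_s)
        na, ng = int(ia.sum()), int(ig.sum())
        acc = np.tile(p.gravity_dir * GRAVITY, (na, 1))
        # per-bout posture wobble
        acc = acc @ _small_rotation(rng, 3.0).T
        gyr = np.zeros((ng, 3))
        for axis in range(3):
            acc[:, axis] += _smooth_noise(rng, na, fs, sd=p.sway_sd)
            gyr[:, axis] += _smooth_noise(rng, ng, fs, sd=2.0 * c["gyro_noise_sd"])
        if e.true_activity in AMBULATORY:
            ta = t_acc[ia] - e.start_s
            dyn_a, _ = _gait_waveform(np.random.default_rng(rng.integers(2**31)),
                                      ta, p, fs)
            tg = t_gyr[ig] - e.start_s
            _, dyn_g = _gait_waveform(np.random.default_rng(rng.integers(2**31)),
                                      tg, p, fs)
            acc += dyn_a
            gyr += dyn_g
        acc_body[ia] = acc
        gyr_body[ig] = gyr
        # barometric trend during stairs; altitude persists afterwards
        if p.baro_trend_hpa_s != 0.0 and ib.any():
            tb = t_bar[ib] - e.start_s
            pressure[ib] += p.baro_trend_hpa_s * tb
            pressure[t_bar >= e.end_s] += p.baro_trend_hpa_s * (e.end_s - e.start_s)
        # phone-handling artifacts at bout edges
        for a0, a1 in ((e.start_s, e.start_s + e.artifact_lead_s),
                       (e.end_s - e.artifact_trail_s, e.end_s)):
            if a1 > a0:
                ja = ia & (t_acc >= a0) & (t_acc < a1)
                jg = ig & (t_gyr >= a0) & (t_gyr < a1)
                acc_body[ja] += rng.normal(0.0, c["artifact_amp"], (int(ja.sum()), 3))
                gyr_body[jg] += rng.normal(0.0, c["artifact_gyro_amp"], (int(jg.sum()), 3))
        bouts.append(LabeledBout(
            bout_id=e.bout_id, activity=e.activity,
            start_s=e.start_s, end_s=e.end_s,
            true_activity=e.true_activity,
            artifact_lead_s=e.artifact_lead_s, artifact_trail_s=e.artifact_trail_s,
        ))

    acc_body += rng.normal(0.0, c["sensor_noise_sd"], acc_body.shape)
    gyr_body += rng.normal(0.0, c["gyro_noise_sd"], gyr_body.shape)
    pressure += rng.normal(0.0, c["baro_noise_sd"], pressure.shape)

    streams = {
        "accelerometer": SensorStream("accelerometer", t_acc, acc_body @ R.T, 60.0),
        "gyroscope": SensorStream("gyroscope", t_gyr, gyr_body @ R.T, 60.0),
        "barometer": SensorStream("barometer", t_bar, pressure[:, None], 6.0),
    }
    meta = {
        "cohort": profile.cohort,
        "gait_speed": profile.gait_speed,
        "impairment": profile.impairment,
        "n_dropped_bouts": sum(e.dropped for e in entries),
        "n_planned_bouts": len(entries),
    }
    return SensorRecording(profile.subject_id, session, streams, bouts, meta)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class Manifest:
    subjects: pd.DataFrame  # subject_id, cohort, impairment, gait_speed, sessions
    bouts: pd.DataFrame     # ground-truth bout table incl. dropped bouts

    @property
    def loss_fraction(self) -> float:
        if len(self.bouts) == 0:
            return 0.0
        return float(self.bouts["dropped"].mean())


def draw_profiles(spec: CohortSpec) -> list[SubjectProfile]:
    """Deterministic subject profiles for a cohort spec."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 91]))
    profiles: list[SubjectProfile] = []
    for i in range(spec.n_healthy):
        speed = float(np.clip(rng.normal(spec.healthy_speed_mean, spec.healthy_speed_sd),
                              0.9, None))
        profiles.append(SubjectProfile(
            subject_id=f"H{i:02d}", cohort="healthy", gait_speed=speed,
            environment_variability=spec.environment_variability,
            phone_orientation=_random_rotation(rng)))
    counts = {"mild": spec.n_mild, "moderate": spec.n_moderate, "severe": spec.n_severe}
    k = 0
    for level in IMPAIRMENT_LEVELS:
        lo, hi = _SPEED_RANGES[level]
        for _ in range(counts[level]):
            profiles.append(SubjectProfile(
                subject_id=f"S{k:02d}", cohort="stroke",
                gait_speed=float(rng.uniform(lo, hi)),
                environment_variability=spec.environment_variability,
                phone_orientation=_random_rotation(rng)))
            k += 1
    return profiles


def subject_sessions(profile: SubjectProfile) -> list[str]:
    return ["Lab1", "Home", "Lab2"] if profile.cohort == "stroke" else ["Home"]


def generate_cohort(spec: CohortSpec) -> tuple[list[SensorRecording], Manifest]:
    """Generate all recordings for a cohort plus a ground-truth manifest."""
    if min(spec.n_healthy, spec.n_mild, spec.n_moderate, spec.n_severe) < 0:
        raise ValueError("stratum sizes must be nonnegative")
    if spec.n_healthy + spec.n_mild + spec.n_moderate + spec.n_severe == 0:
        raise ValueError("cohort is empty")
    profiles = draw_profiles(spec)
    recordings: list[SensorRecording] = []
    subj_rows, bout_rows = [], []
    for si, profile in enumerate(profiles):
        sessions = subject_sessions(profile)
        for sj, session in enumerate(sessions):
            rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, si, sj]))
            mult = spec.healthy_bout_multiplier if profile.cohort == "healthy" else 1
            rec = generate_subject(profile, spec, session, rng=rng, bout_multiplier=mult)
            recordings.append(rec)
            for b in rec.bouts:
                bout_rows.append(dict(
                    subject_id=profile.subject_id, session=session,
                    bout_id=b.bout_id, activity=b.activity,
                    true_activity=b.true_activity,
                    start_s=b.start_s, end_s=b.end_s,
                    artifact_lead_s=b.artifact_lead_s,
                    artifact_trail_s=b.artifact_trail_s,
                    mislabeled=b.mislabeled, dropped=False))
            n_drop = rec.metadata["n_dropped_bouts"]
            for d in range(n_drop):
                bout_rows.append(dict(
                    subject_id=profile.subject_id, session=session,
                    bout_id=f"{profile.subject_id}_{session}_dropped{d}",
                    activity=None, true_activity=None,
                    start_s=np.nan, end_s=np.nan,
                    artifact_lead_s=0.0, artifact_trail_s=0.0,
                    mislabeled=False, dropped=True))
        subj_rows.append(dict(
            subject_id=profile.subject_id, cohort=profile.cohort,
            impairment=profile.impairment, gait_speed=profile.gait_speed,
            sessions=",".join(sessions)))
    manifest = Manifest(
        subjects=pd.DataFrame(subj_rows),
        bouts=pd.DataFrame(bout_rows) if bout_rows else pd.DataFrame(
            columns=["subject_id", "session", "bout_id", "activity", "true_activity",
                     "start_s", "end_s", "artifact_lead_s", "artifact_trail_s",
                     "mislabeled", "dropped"]),
    )
    return recordings, manifest


def write_cohort(recordings: list[SensorRecording], manifest: Manifest,
                 directory) -> None:
    """Write per-sensor/label CSVs and the two manifest CSVs."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording(rec, directory)
    manifest.subjects.to_csv(directory / "manifest_subjects.csv", index=False)
    manifest.bouts.to_csv(directory / "manifest_bouts.csv", index=False)
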