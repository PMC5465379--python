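"""The clip feature catalogue: 131 features per inertial sensor, 8 barometric.

Per inertial axis (x, y, z): mean, range, interquartile range; SD, skew,
kurtosis; four z-score histogram fractions on [-2, 2]; mean/SD/skew/kurtosis
of the first-difference derivative; mean/SD/skew/kurtosis of the one-sided
periodogram; and mean power in twenty 0.5 Hz bands over 0-10 Hz — 38 per
axis, 114 per sensor.  Cross-axis: Pearson r for the three axis pairs; raw
and normalized mean cross products and their absolute variants; plus the
mean squared norm and the sum of axial SDs — 17 more, 131 in total.
Barometer: derivative mean/SD/skew/kurtosis, SD, range, IQR, and the OLS
slope against time — 8.

Conventions (degenerate signals): when a channel has zero SD its z-scores,
skew, kurtosis and correlations are defined as 0.  Skew and kurtosis are
population (biased) moment estimators; kurtosis is non-excess.  The
normalized cross product is mean(a*b) / (rms(a) * rms(b)) — bounded in
[-1, 1] and, unlike Pearson r, not mean-centered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import CLIP_BARO_SAMPLES, CLIP_INERTIAL_SAMPLES, Clip

INERTIAL_FS = 50.0
BARO_FS = 6.0
AXES = ("x", "y", "z")
PAIRS = (("x", "y"), ("x", "z"), ("y", "z"))
N_BANDS = 20
BAND_WIDTH_HZ = 0.5
N_ZBINS = 4
_ZEDGES = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])

META_COLUMNS = ("subject_id", "session", "environment", "activity",
                "cohort", "impairment", "gait_speed",
                "bout_id", "start_s", "bout_duration_s")


def _per_axis_defs() -> list[tuple[str, str]]:
    """(name_suffix, definition_id) for the 38 per-axis features, in order."""
    defs: list[tuple[str, str]] = [
        ("mean", "basic"), ("range", "basic"), ("iqr", "basic"),
        ("sd", "moments"), ("skew", "moments"), ("kurt", "moments"),
    ]
    defs += [(f"zhist{i}", "zscore_hist") for i in range(N_ZBINS)]
    defs += [(f"d_{s}", "deriv_moments") for s in ("mean", "sd", "skew", "kurt")]
    defs += [(f"ps_{s}", "spectrum_moments") for s in ("mean", "sd", "skew", "kurt")]
    defs += [(f"bp{i}", "band_power") for i in range(N_BANDS)]
    return defs


def _cross_defs() -> list[tuple[str, str]]:
    defs: list[tuple[str, str]] = []
    defs += [(f"corr_{a}{b}", "pearson_corr") for a, b in PAIRS]
    for a, b in PAIRS:
        defs += [(f"xprod_raw_{a}{b}", "cross_product"),
                 (f"xprod_norm_{a}{b}", "cross_product")]
    for a, b in PAIRS:
        defs += [(f"absxprod_raw_{a}{b}", "abs_cross_product"),
                 (f"absxprod_norm_{a}{b}", "abs_cross_product")]
    defs += [("msn", "mean_squared_norm"), ("sum_sd", "sum_axial_sd")]
    return defs


_BARO_DEFS: list[tuple[str, str]] = (
    [(f"d_{s}", "deriv_moments") for s in ("mean", "sd", "skew", "kurt")]
    + [("sd", "dispersion"), ("range", "dispersion"), ("iqr", "dispersion")]
    + [("slope", "regression_slope")]
)


@dataclass(frozen=True)
class FeatureCatalog:
    """Ordered, immutable catalogue of all feature names."""

    names: tuple[str, ...]
    sensor_of: dict[str, str]
    definition_of: dict[str, str]

    def by_sensor(self, sensor: str) -> list[str]:
        return [n for n in self.names if self.sensor_of[n] == sensor]

    @property
    def n_features(self) -> int:
        return len(self.names)


def inertial_feature_names(sensor: str) -> list[str]:
    names = []
    for axis in AXES:
        names += [f"{sensor}_{axis}_{suffix}" for suffix, _ in _per_axis_defs()]
    names += [f"{sensor}_{suffix}" for suffix, _ in _cross_defs()]
    return names


def barometer_feature_names() -> list[str]:
    return [f"baro_{suffix}" for suffix, _ in _BARO_DEFS]


def build_catalog() -> FeatureCatalog:
    names: list[str] = []
    sensor_of: dict[str, str] = {}
    definition_of: dict[str, str] = {}
    for sensor in ("acc", "gyr"):
        per_axis = _per_axis_defs()
        for axis in AXES:
            for suffix, did in per_axis:
                n = f"{sensor}_{axis}_{suffix}"
                names.append(n)
                sensor_of[n] = sensor
                definition_of[n] = did
        for suffix, did in _cross_defs():
            n = f"{sensor}_{suffix}"
            names.append(n)
            sensor_of[n] = sensor
            definition_of[n] = did
    for (suffix, did), n in zip(_BARO_DEFS, barometer_feature_names()):
        names.append(n)
        sensor_of[n] = "baro"
        definition_of[n] = did
    assert len(names) == 270
    return FeatureCatalog(tuple(names), sensor_of, definition_of)


DEFAULT_CATALOG = build_catalog()


# ---------------------------------------------------------------------------
# Vectorized feature computation.  All routines take batches: X has shape
# (n_clips, n_samples) per channel.
# ---------------------------------------------------------------------------

def _moments(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Population mean, SD, skew, non-excess kurtosis per row; skew/kurt = 0
    for zero-variance rows."""
    mu = X.mean(axis=-1)
    d = X - mu[..., None]
    d2 = d * d
    sd = np.sqrt(d2.mean(axis=-1))
    # numerically constant rows (centered residue at rounding scale) are
    # treated as exactly degenerate
    sd = np.where(sd <= 1e-12 * np.maximum(1.0, np.abs(mu)), 0.0, sd)
    var = sd * sd
    m3 = (d2 * d).mean(axis=-1)
    m4 = (d2 * d2).mean(axis=-1)
    skew = np.where(sd > 0, m3 / np.where(sd > 0, sd, 1.0) ** 3, 0.0)
    kurt = np.where(var > 0, m4 / np.where(var > 0, var, 1.0) ** 2, 0.0)
    return mu, sd, skew, kurt


def _iqr(X: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(X, [75, 25], axis=-1)
    return q75 - q25


def _zhist(X: np.ndarray) -> np.ndarray:
    """Fractions of samples with z-score in [-2,-1), [-1,0), [0,1), [1,2]."""
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, keepdims=True)
    n = X.shape[-1]
    out = np.zeros(X.shape[:-1] + (N_ZBINS,))
    ok = sd[..., 0] > 1e-12 * np.maximum(1.0, np.abs(mu[..., 0]))
    if np.any(ok):
        z = (X[ok] - mu[ok]) / sd[ok]
        for i in range(N_ZBINS):
            lo, hi = _ZEDGES[i], _ZEDGES[i + 1]
            if i == N_ZBINS - 1:
                mask = (z >= lo) & (z <= hi)
            else:
                mask = (z >= lo) & (z < hi)
            out[ok, i] = mask.sum(axis=-1) / n
    return out


def _periodogram(X: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of each mean-removed row; returns (freqs, P)."""
    n = X.shape[-1]
    mu = X.mean(axis=-1, keepdims=True)
    d = X - mu
    # numerically constant rows carry no power
    flat = np.abs(d).max(axis=-1) <= 1e-12 * np.maximum(1.0, np.abs(mu[..., 0]))
    d[flat] = 0.0
    spec = np.fft.rfft(d, axis=-1)
    p = (np.abs(spec) ** 2) / (fs * n)
    p[..., 1:-1] *= 2.0  # fold negative frequencies; DC/Nyquist not doubled
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, p


def _band_powers(freqs: np.ndarray, p: np.ndarray) -> np.ndarray:
    out = np.empty(p.shape[:-1] + (N_BANDS,))
    for i in range(N_BANDS):
        lo = i * BAND_WIDTH_HZ
        m = (freqs >= lo - 1e-12) & (freqs < lo + BAND_WIDTH_HZ - 1e-12)
        out[..., i] = p[..., m].mean(axis=-1)
    return out


def _rms(X: np.ndarray) -> np.ndarray:
    return np.sqrt((X ** 2).mean(axis=-1))


def _pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row; defined as 0 when either channel is (numerically)
    constant."""
    da = a - a.mean(axis=-1, keepdims=True)
    db = b - b.mean(axis=-1, keepdims=True)
    tiny_a = 1e-12 * np.maximum(1.0, np.abs(a.mean(axis=-1)))
    tiny_b = 1e-12 * np.maximum(1.0, np.abs(b.mean(axis=-1)))
    ok = (np.abs(da).max(axis=-1) > tiny_a) & (np.abs(db).max(axis=-1) > tiny_b)
    denom = np.sqrt((da ** 2).sum(axis=-1) * (db ** 2).sum(axis=-1))
    ok &= denom > 0
    return np.where(ok, (da * db).sum(axis=-1) / np.where(ok, denom, 1.0), 0.0)


def extract_inertial_matrix(data: np.ndarray, fs: float = INERTIAL_FS) -> np.ndarray:
    """All 131 features for a batch of 3-axis clips, shape (n, 500, 3) -> (n, 131).

    Column order matches :func:`inertial_feature_names`.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if data.shape[1:] != (CLIP_INERTIAL_SAMPLES, 3):
        raise ValueError(f"expected (n, {CLIP_INERTIAL_SAMPLES}, 3), got {data.shape}")
    n = data.shape[0]
    cols: list[np.ndarray] = []
    for axis in range(3):
        x = data[:, :, axis]
        mu, sd, skew, kurt = _moments(x)
        rng_ = x.max(axis=-1) - x.min(axis=-1)
        cols += [mu, rng_, _iqr(x), sd, skew, kurt]
        zh = _zhist(x)
        cols += [zh[:, i] for i in range(N_ZBINS)]
        d = np.diff(x, axis=-1) * fs
        dm, dsd, dsk, dku = _moments(d)
        cols += [dm, dsd, dsk, dku]
        freqs, p = _periodogram(x, fs)
        pm, psd, psk, pku = _moments(p)
        cols += [pm, psd, psk, pku]
        bp = _band_powers(freqs, p)
        cols += [bp[:, i] for i in range(N_BANDS)]
    x, y, z = data[:, :, 0], data[:, :, 1], data[:, :, 2]
    for a, b in ((x, y), (x, z), (y, z)):
        cols.append(_pearson(a, b))
    for a, b in ((x, y), (x, z), (y, z)):
        prod = (a * b).mean(axis=-1)
        denom = _rms(a) * _rms(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            norm = np.where(denom > 0, prod / np.where(denom > 0, denom, 1), 0.0)
        cols += [prod, norm]
    for a, b in ((x, y), (x, z), (y, z)):
        aprod = np.abs(a * b).mean(axis=-1)
        denom = _rms(a) * _rms(b)
        with np.errstate(divide="ignore", invalid="ignore"):
            anorm = np.where(denom > 0, aprod / np.where(denom > 0, denom, 1), 0.0)
        cols += [aprod, anorm]
    cols.append((data ** 2).sum(axis=2).mean(axis=1))        # mean squared norm
    cols.append(data.std(axis=1).sum(axis=1))                # sum of axial SDs
    out = np.column_stack(cols)
    assert out.shape == (n, 131)
    return out


def extract_baro_matrix(data: np.ndarray, fs: float = BARO_FS) -> np.ndarray:
    """All 8 barometer features for a batch, shape (n, 60) -> (n, 8)."""
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[None]
    if data.shape[1] != CLIP_BARO_SAMPLES:
        raise ValueError(f"expected (n, {CLIP_BARO_SAMPLES}), got {data.shape}")
    d = np.diff(data, axis=-1) * fs
    dm, dsd, dsk, dku = _moments(d)
    _, sd, _, _ = _moments(data)
    rng_ = data.max(axis=-1) - data.min(axis=-1)
    iqr = _iqr(data)
    t = np.arange(CLIP_BARO_SAMPLES) / fs
    tc = t - t.mean()
    slope = (data - data.mean(axis=-1, keepdims=True)) @ tc / (tc ** 2).sum()
    return np.column_stack([dm, dsd, dsk, dku, sd, rng_, iqr, slope])


def extract_inertial_features(clip_channel: np.ndarray, sensor: str) -> dict[str, float]:
    """The 131 named features of one 3-axis clip (sensor tag 'acc' or 'gyr')."""
    if sensor not in ("acc", "gyr"):
        raise ValueError("sensor tag must be 'acc' or 'gyr'")
    vals = extract_inertial_matrix(np.asarray(clip_channel)[None])[0]
    return dict(zip(inertial_feature_names(sensor), vals))


def extract_barometer_features(baro: np.ndarray | None) -> dict[str, float]:
    """The 8 named barometer features of one clip; NaN when the sensor is absent."""
    names = barometer_feature_names()
    if baro is None:
        return {n: float("nan") for n in names}
    vals = extract_baro_matrix(np.asarray(baro)[None])[0]
    return dict(zip(names, vals))


def build_instance_table(
    clips: list[Clip],
    catalog: FeatureCatalog | None = None,
    feature_set: str | list[str] = "all",
    chunk: int = 4096,
) -> pd.DataFrame:
    """One row per clip: metadata columns plus catalogue-ordered features."""
    catalog = catalog or DEFAULT_CATALOG
    if feature_set == "all":
        selected = list(catalog.names)
    else:
        unknown = set(feature_set) - set(catalog.names)
        if unknown:
            raise KeyError(f"unknown feature names: {sorted(unknown)}")
        selected = [n for n in catalog.names if n in set(feature_set)]
    if not clips:
        return pd.DataFrame(columns=list(META_COLUMNS) + selected)
    blocks = []
    for i in range(0, len(clips), chunk):
        batch = clips[i:i + chunk]
        acc = np.stack([c.accel for c in batch])
        gyr = np.stack([c.gyro for c in batch])
        fa = extract_inertial_matrix(acc)
        fg = extract_inertial_matrix(gyr)
        fb = np.full((len(batch), 8), np.nan)
        has = [j for j, c in enumerate(batch) if c.baro is not None]
        if has:
            fb[has] = extract_baro_matrix(np.stack([batch[j].baro for j in has]))
        blocks.append(np.hstack([fa, fg, fb]))
    feats = pd.DataFrame(np.vstack(blocks), columns=list(catalog.names))
    meta = pd.DataFrame({
        "subject_id": [c.subject_id for c in clips],
        "session": [c.session for c in clips],
        "environment": [c.environment for c in clips],
        "activity": [c.activity for c in clips],
        "cohort": pd.NA, "impairment": pd.NA, "gait_speed": np.nan,
        "bout_id": [c.bout_id for c in clips],
        "start_s": [c.start_s for c in clips],
        "bout_duration_s": [c.bout_duration_s for c in clips],
    })
    return pd.concat([meta.reset_index(drop=True), feats[selected]], axis=1)


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# Out-of-bag permutation importance with per-tree random undersampling
# ---------------------------------------------------------------------------

def rank_features_oob(
    table: pd.DataFrame,
    n_trees: int = 40,
    min_leaf: int = 5,
    undersample_target: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank features by permutation importance in a RUS-bagged tree ensemble.

    Each tree is fit on a class-balanced bootstrap undersample (drawn with
    replacement, so every tree has out-of-bag samples even on balanced
    data); its out-of-bag (OOB) samples are scored once, then re-scored with
    each feature permuted.  A feature's importance is the mean OOB error
    increase across trees, normalized by its SD across trees (0 when the SD
    is 0).  Deterministic given the seed.
    """
    from sklearn.tree import DecisionTreeClassifier

    feats = feature_columns(table)
    X = table[feats].to_numpy(float)
    X = np.nan_to_num(X, nan=0.0)
    y = table["activity"].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes to rank features")
    rng = np.random.default_rng(seed)
    counts = {c: int((y == c).sum()) for c in classes}
    target = undersample_target or min(counts.values())
    deltas = np.zeros((n_trees, len(feats)))
    for t in range(n_trees):
        idx_parts = []
        for c in classes:
            pool = np.flatnonzero(y == c)
            idx_parts.append(rng.choice(pool, size=target, replace=True))
        idx = np.concatenate(idx_parts)
        oob = np.setdiff1d(np.arange(len(y)), idx)
        if len(oob) == 0:
            continue
        tree = DecisionTreeClassifier(min_samples_leaf=min_leaf,
                                      random_state=int(rng.integers(2**31)))
        tree.fit(X[idx], y[idx])
        base_err = float((tree.predict(X[oob]) != y[oob]).mean())
        used = set(tree.tree_.feature[tree.tree_.feature >= 0])
        Xo = X[oob]
        for j in range(len(feats)):
            if j not in used:
                continue  # permuting an unused feature cannot change predictions
            perm = rng.permutation(len(oob))
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            deltas[t, j] = float((tree.predict(Xp) != y[oob]).mean()) - base_err
    mean = deltas.mean(axis=0)
    sd = deltas.std(axis=0)
    importance = np.where(sd > 0, mean / np.where(sd > 0, sd, 1), mean)
    out = pd.DataFrame({"feature": feats, "importance": importance})
    return out.sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class FeatureSet:
    set_id: str
    names: tuple[str, ...]
    provenance: dict


def select_features(ranking: pd.DataFrame, k: int, set_id: str | None = None,
                    provenance: dict | None = None) -> FeatureSet:
    """Top-``k`` features from an importance ranking."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range 1..{len(ranking)}")
    names = tuple(ranking["feature"].head(k))
    return FeatureSet(set_id or f"top{k}", names, provenance or {})
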