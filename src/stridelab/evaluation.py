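"""Evaluation designs, metrics and the statistical test battery.

Designs mirror a three-way comparison of activity-recognition training
sources for a stroke cohort:

* population models — leave-one-subject-out (LOSO) within a cohort
  (Healthy-to-Healthy, Stroke-to-Stroke) and cross-cohort transfer
  (Healthy-to-Stroke: train once on the full healthy pool, test each stroke
  subject);
* gait-impairment models — the cross-cohort per-subject results
  re-aggregated by the test subject's impairment stratum;
* environmental models — per-subject (personal) and LOSO (global)
  Lab1-to-Lab2, Lab1-to-Home, and chronological four-fold Home-to-Home
  comparisons on the subjects with at least 60 s of every activity in every
  setting, with classes merged to four (Sitting+Lying, Stairs up+down).

The primary metric is mean recall (unweighted over the classes present in
the test set); the clinically salient error is cross-confusion between
stationary {Sitting, Lying, Standing} and ambulatory {StairsUp, StairsDown,
Walking} activity groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import feature_columns
from .model import ModelConfig, TrainedEnsemble, train
from .sensor_io import ACTIVITIES, AMBULATORY, STATIONARY

#: four-class merge used by the environmental designs
MERGE_4CLASS: dict[str, str] = {
    "Sitting": "Sedentary", "Lying": "Sedentary",
    "Standing": "Standing",
    "StairsUp": "Stairs", "StairsDown": "Stairs",
    "Walking": "Walking",
}

GROUPING_6CLASS: dict[str, set[str]] = {
    "stationary": set(STATIONARY), "ambulatory": set(AMBULATORY)}
GROUPING_4CLASS: dict[str, set[str]] = {
    "stationary": {"Sedentary", "Standing"}, "ambulatory": {"Stairs", "Walking"}}


@dataclass
class ConfusionMatrix:
    classes: tuple[str, ...]
    counts: np.ndarray  # (true x predicted)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def per_class_recall(self) -> dict[str, float]:
        """Recall per class; classes absent from the test set map to NaN."""
        rows = self.counts.sum(axis=1)
        out = {}
        for i, c in enumerate(self.classes):
            out[c] = float(self.counts[i, i] / rows[i]) if rows[i] > 0 else float("nan")
        return out

    def mean_recall(self) -> float:
        """Unweighted mean recall over classes present in the test set."""
        vals = [v for v in self.per_class_recall().values() if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def add(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.classes != self.classes:
            raise ValueError("class lists differ")
        return ConfusionMatrix(self.classes, self.counts + other.counts)


def confusion_and_recall(
    y_true, y_pred, classes: tuple[str, ...] | None = None,
    class_map: dict[str, str] | None = None,
) -> tuple[ConfusionMatrix, dict[str, float], float]:
    """Confusion matrix, per-class recall, and mean recall.

    ``class_map`` optionally merges labels (e.g. the 4-class grouping)
    before counting.  Unknown labels raise.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences differ in length")
    if class_map:
        y_true = np.array([class_map[v] for v in y_true])
        y_pred = np.array([class_map[v] for v in y_pred])
    if classes is None:
        base = [class_map[a] for a in ACTIVITIES] if class_map else list(ACTIVITIES)
        seen_first = list(dict.fromkeys(base))
        classes = tuple(seen_first)
    idx = {c: i for i, c in enumerate(classes)}
    unknown = (set(y_true) | set(y_pred)) - set(classes)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(counts, (np.array([idx[v] for v in y_true]),
                       np.array([idx[v] for v in y_pred])), 1)
    cm = ConfusionMatrix(classes, counts)
    recalls = cm.per_class_recall()
    return cm, recalls, cm.mean_recall()


def group_misclassification(
    cm: ConfusionMatrix,
    grouping: dict[str, set[str]] | None = None,
) -> dict[str, float]:
    """Cross-group confusion rates between stationary and ambulatory classes.

    Returns ``ambulatory_as_stationary`` = (true-ambulatory instances
    predicted as any stationary class) / (total true-ambulatory), and the
    symmetric ``stationary_as_ambulatory``.  Fractions in [0, 1].
    """
    grouping = grouping or (
        GROUPING_6CLASS if set(cm.classes) <= set(ACTIVITIES) else GROUPING_4CLASS)
    covered = grouping["stationary"] | grouping["ambulatory"]
    missing = set(cm.classes) - covered
    if missing:
        raise ValueError(f"grouping misses classes: {sorted(missing)}")
    is_stat = np.array([c in grouping["stationary"] for c in cm.classes])
    is_amb = np.array([c in grouping["ambulatory"] for c in cm.classes])
    amb_total = cm.counts[is_amb].sum()
    stat_total = cm.counts[is_stat].sum()
    amb_as_stat = cm.counts[np.ix_(is_amb, is_stat)].sum()
    stat_as_amb = cm.counts[np.ix_(is_stat, is_amb)].sum()
    return {
        "ambulatory_as_stationary": float(amb_as_stat / amb_total) if amb_total else float("nan"),
        "stationary_as_ambulatory": float(stat_as_amb / stat_total) if stat_total else float("nan"),
    }


@dataclass
class SubjectResult:
    subject_id: str
    impairment: str | None
    gait_speed: float
    cm: ConfusionMatrix
    mean_recall: float
    misclassification: dict[str, float]

    @property
    def per_class_recall(self) -> dict[str, float]:
        return self.cm.per_class_recall()


@dataclass
class EvaluationReport:
    design: str
    subjects: list[SubjectResult]
    classes: tuple[str, ...]
    config: dict = field(default_factory=dict)

    def pooled_cm(self) -> ConfusionMatrix:
        cm = ConfusionMatrix(self.classes,
                             np.zeros((len(self.classes),) * 2, dtype=np.int64))
        for s in self.subjects:
            cm = cm.add(s.cm)
        return cm

    def mean_recalls(self) -> np.ndarray:
        return np.array([s.mean_recall for s in self.subjects])

    @property
    def mean_recall(self) -> float:
        """Mean over per-subject mean recalls (matches the paired statistics)."""
        return float(np.nanmean(self.mean_recalls()))

    def subject_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(subject_id=s.subject_id, impairment=s.impairment,
                 gait_speed=s.gait_speed, mean_recall=s.mean_recall,
                 **s.misclassification)
            for s in self.subjects])


# ---------------------------------------------------------------------------
# Split helpers
# ---------------------------------------------------------------------------

def _fit(train_tab: pd.DataFrame, cfg: ModelConfig,
         feature_set: list[str] | None,
         class_map: dict[str, str] | None) -> TrainedEnsemble:
    tab = train_tab
    if class_map:
        tab = tab.copy()
        tab["activity"] = tab["activity"].map(class_map)
    # a class too small to form a single leaf cannot be learned in this
    # fold; drop it from training (its test instances score as errors)
    counts = tab["activity"].value_counts()
    trainable = counts[counts >= cfg.min_leaf].index
    if len(trainable) < len(counts):
        tab = tab[tab["activity"].isin(trainable)]
    feats = feature_set or feature_columns(tab)
    return train(tab, cfg=cfg, feature_names=feats)


def _score_subject(model: TrainedEnsemble, test_tab: pd.DataFrame,
                   class_map: dict[str, str] | None,
                   classes: tuple[str, ...]) -> SubjectResult:
    y_true = test_tab["activity"].to_numpy()
    y_pred = model.predict(test_tab)
    if class_map:
        # model may already be trained on merged labels
        y_true = np.array([class_map.get(v, v) for v in y_true])
        y_pred = np.array([class_map.get(v, v) for v in y_pred])
    cm, _, mean_rec = confusion_and_recall(y_true, y_pred, classes=classes)
    mis = group_misclassification(cm)
    row = test_tab.iloc[0]
    return SubjectResult(str(row["subject_id"]),
                         row.get("impairment"), float(row.get("gait_speed", np.nan)),
                         cm, mean_rec, mis)


def _classes_for(class_map: dict[str, str] | None) -> tuple[str, ...]:
    if class_map is None:
        return tuple(ACTIVITIES)
    return tuple(dict.fromkeys(class_map[a] for a in ACTIVITIES))


def loso_population(table: pd.DataFrame, cohort: str, cfg: ModelConfig,
                    feature_set: list[str] | None = None,
                    class_map: dict[str, str] | None = None,
                    design: str | None = None) -> EvaluationReport:
    """Leave-one-subject-out within one cohort."""
    sub = table[table["cohort"] == cohort]
    subjects = sorted(sub["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    classes = _classes_for(class_map)
    results = []
    for s in subjects:
        train_tab = sub[sub["subject_id"] != s]
        test_tab = sub[sub["subject_id"] == s]
        model = _fit(train_tab, cfg, feature_set, class_map)
        results.append(_score_subject(model, test_tab, class_map, classes))
    n_features = len(feature_set) if feature_set else len(feature_columns(sub))
    return EvaluationReport(design or f"{cohort}_loso", results, classes,
                            {"cfg": vars(cfg), "n_features": n_features})


def cross_cohort(table: pd.DataFrame, train_cohort: str, test_cohort: str,
                 cfg: ModelConfig, feature_set: list[str] | None = None,
                 class_map: dict[str, str] | None = None) -> EvaluationReport:
    """Train once on the full source cohort; per-subject reports on the target."""
    train_tab = table[table["cohort"] == train_cohort]
    test_tab = table[table["cohort"] == test_cohort]
    if train_tab.empty or test_tab.empty:
        raise ValueError("empty train or test cohort")
    classes = _classes_for(class_map)
    model = _fit(train_tab, cfg, feature_set, class_map)
    results = [
        _score_subject(model, test_tab[test_tab["subject_id"] == s], class_map, classes)
        for s in sorted(test_tab["subject_id"].unique())
    ]
    return EvaluationReport(f"{train_cohort}_to_{test_cohort}", results, classes,
                            {"cfg": vars(cfg)})


def stratified_rates(report: EvaluationReport) -> pd.DataFrame:
    """Pool per-subject confusions within each impairment stratum.

    Rates are computed from the pooled stratum confusion matrix (instance
    weighting), one row per stratum.
    """
    rows = []
    strata: dict[str, ConfusionMatrix] = {}
    for s in report.subjects:
        key = s.impairment or "none"
        strata[key] = s.cm if key not in strata else strata[key].add(s.cm)
    for key, cm in strata.items():
        mis = group_misclassification(cm)
        rows.append(dict(impairment=key, mean_recall=cm.mean_recall(),
                         n_instances=cm.total, **mis))
    order = {"mild": 0, "moderate": 1, "severe": 2, "none": 3}
    return (pd.DataFrame(rows)
            .sort_values("impairment", key=lambda s: s.map(order))
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# Environmental designs
# ---------------------------------------------------------------------------

def eligible_subjects(table: pd.DataFrame, min_seconds: float = 60.0) -> list[str]:
    """Stroke subjects with >= ``min_seconds`` of every activity in every session.

    Seconds are summed over labeled bout durations (each bout counted once).
    """
    sub = table[table["cohort"] == "stroke"]
    out = []
    for s, g in sub.groupby("subject_id"):
        ok = True
        for session in ("Lab1", "Home", "Lab2"):
            gs = g[g["session"] == session]
            if gs.empty:
                ok = False
                break
            secs = gs.drop_duplicates("bout_id").groupby("activity")["bout_duration_s"].sum()
            for act in ACTIVITIES:
                if secs.get(act, 0.0) < min_seconds:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            out.append(str(s))
    return sorted(out)


def chronological_folds(sub_tab: pd.DataFrame, n_folds: int = 4) -> list[np.ndarray]:
    """Contiguous chronological folds of one subject-session's clips.

    Clips are ordered by start time and split into ``n_folds`` contiguous
    blocks; any clip whose 10-s span overlaps a clip assigned to a different
    fold is dropped from both training and testing, so no raw sample crosses
    a fold boundary.  Returns positional index arrays into ``sub_tab``.
    """
    order = np.argsort(sub_tab["start_s"].to_numpy(), kind="mergesort")
    n = len(order)
    bounds = [int(round(i * n / n_folds)) for i in range(n_folds + 1)]
    fold_of = np.empty(n, dtype=int)
    for f in range(n_folds):
        fold_of[order[bounds[f]:bounds[f + 1]]] = f
    starts = sub_tab["start_s"].to_numpy()
    ends = starts + 10.0
    bout = sub_tab["bout_id"].to_numpy()
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        same_bout = bout == bout[i]
        overlap = same_bout & (starts < ends[i]) & (ends > starts[i]) & (fold_of != fold_of[i])
        if overlap.any():
            keep[i] = False
    return [np.flatnonzero((fold_of == f) & keep) for f in range(n_folds)]


def _personal_transfer(g: pd.DataFrame, train_session: str, test_session: str,
                       cfg: ModelConfig, feature_set, class_map,
                       classes) -> SubjectResult:
    tr = g[g["session"] == train_session]
    te = g[g["session"] == test_session]
    model = _fit(tr, cfg, feature_set, class_map)
    return _score_subject(model, te, class_map, classes)


def _personal_home_cv(g: pd.DataFrame, cfg: ModelConfig, feature_set, class_map,
                      classes, n_folds: int = 4) -> SubjectResult:
    home = g[g["session"] == "Home"].reset_index(drop=True)
    folds = chronological_folds(home, n_folds)
    cm = ConfusionMatrix(classes, np.zeros((len(classes),) * 2, dtype=np.int64))
    for f in range(n_folds):
        test_idx = folds[f]
        train_idx = np.concatenate([folds[j] for j in range(n_folds) if j != f])
        if len(test_idx) == 0 or len(train_idx) == 0:
            raise ValueError("chronological fold with no instances")
        model = _fit(home.iloc[train_idx], cfg, feature_set, class_map)
        res = _score_subject(model, home.iloc[test_idx], class_map, classes)
        cm = cm.add(res.cm)
    mis = group_misclassification(cm)
    row = home.iloc[0]
    return SubjectResult(str(row["subject_id"]), row.get("impairment"),
                         float(row.get("gait_speed", np.nan)),
                         cm, cm.mean_recall(), mis)


def environmental_personal(table: pd.DataFrame, cfg: ModelConfig,
                           feature_set: list[str] | None = None,
                           min_seconds: float = 60.0) -> dict[str, EvaluationReport]:
    """Per-subject Lab1-to-Lab2, Lab1-to-Home and Home 4-fold CV (4-class merge)."""
    pool = eligible_subjects(table, min_seconds)
    if not pool:
        raise ValueError("eligibility filter left no subjects")
    class_map = MERGE_4CLASS
    classes = _classes_for(class_map)
    reports = {name: [] for name in ("lab1_to_lab2", "lab1_to_home", "home_to_home")}
    for s in pool:
        g = table[table["subject_id"] == s]
        reports["lab1_to_lab2"].append(
            _personal_transfer(g, "Lab1", "Lab2", cfg, feature_set, class_map, classes))
        reports["lab1_to_home"].append(
            _personal_transfer(g, "Lab1", "Home", cfg, feature_set, class_map, classes))
        reports["home_to_home"].append(
            _personal_home_cv(g, cfg, feature_set, class_map, classes))
    return {name: EvaluationReport(f"personal_{name}", res, classes,
                                   {"subjects": pool})
            for name, res in reports.items()}


def environmental_global(table: pd.DataFrame, cfg: ModelConfig,
                         feature_set: list[str] | None = None,
                         min_seconds: float = 60.0) -> dict[str, EvaluationReport]:
    """LOSO over the eligible pool for each environment pairing (4-class merge)."""
    pool = eligible_subjects(table, min_seconds)
    if len(pool) < 2:
        raise ValueError("global environmental models need >= 2 eligible subjects")
    class_map = MERGE_4CLASS
    classes = _classes_for(class_map)
    pairings = {"lab1_to_lab2": ("Lab1", "Lab2"), "lab1_to_home": ("Lab1", "Home"),
                "home_to_home": ("Home", "Home")}
    out = {}
    for name, (tr_sess, te_sess) in pairings.items():
        results = []
        for s in pool:
            tr = table[(table["subject_id"].isin(pool)) & (table["subject_id"] != s)
                       & (table["session"] == tr_sess)]
            te = table[(table["subject_id"] == s) & (table["session"] == te_sess)]
            model = _fit(tr, cfg, feature_set, class_map)
            results.append(_score_subject(model, te, class_map, classes))
        out[name] = EvaluationReport(f"global_{name}", results, classes,
                                     {"subjects": pool})
    return out


# ---------------------------------------------------------------------------
# Learning curve and barometer ablation
# ---------------------------------------------------------------------------

def learning_curve(table: pd.DataFrame, train_cohort: str, test_cohort: str,
                   n_subjects_list: list[int], cfg: ModelConfig,
                   n_instances: int = 1200, reps: int = 100,
                   seed: int = 0) -> pd.DataFrame:
    """Mean recall vs number of training subjects at a fixed instance budget.

    For each size: sample that many training subjects, pool their instances,
    draw exactly ``n_instances`` uniformly at random, train, and score each
    held-out test subject; repeated ``reps`` times.  Reports the mean and a
    percentile 95% CI over repetitions.
    """
    rng = np.random.default_rng(seed)
    train_tab = table[table["cohort"] == train_cohort]
    if train_cohort == test_cohort:
        subjects = sorted(train_tab["subject_id"].unique())
        test_subjects = None  # drawn per rep from the complement
    else:
        subjects = sorted(train_tab["subject_id"].unique())
        test_tab = table[table["cohort"] == test_cohort]
        test_subjects = sorted(test_tab["subject_id"].unique())
    rows = []
    for size in n_subjects_list:
        if size > len(subjects) - (0 if test_subjects is not None else 1):
            raise ValueError(f"requested {size} training subjects, "
                             f"only {len(subjects)} available")
        recalls = []
        for _ in range(reps):
            chosen = rng.choice(subjects, size=size, replace=False)
            pool = train_tab[train_tab["subject_id"].isin(chosen)]
            if len(pool) < n_instances:
                raise ValueError("not enough instances in the sampled subjects")
            pick = rng.choice(len(pool), size=n_instances, replace=False)
            sample = pool.iloc[pick]
            cfg_rep = ModelConfig(**{**vars(cfg), "seed": int(rng.integers(2**31))})
            model = _fit(sample, cfg_rep, None, None)
            if test_subjects is None:
                held = [s for s in subjects if s not in set(chosen)]
                te = train_tab[train_tab["subject_id"].isin(held)]
            else:
                te = table[table["cohort"] == test_cohort]
            per_subj = []
            for s, g in te.groupby("subject_id"):
                res = _score_subject(model, g, None, tuple(ACTIVITIES))
                per_subj.append(res.mean_recall)
            recalls.append(float(np.nanmean(per_subj)))
        recalls = np.asarray(recalls)
        rows.append(dict(n_subjects=size, mean_recall=float(recalls.mean()),
                         ci_low=float(np.percentile(recalls, 2.5)),
                         ci_high=float(np.percentile(recalls, 97.5)),
                         reps=reps))
    return pd.DataFrame(rows)


def ablate_barometer(table: pd.DataFrame, cohort: str, cfg: ModelConfig,
                     ) -> dict[str, EvaluationReport]:
    """LOSO with and without the 8 barometer features (all else identical)."""
    feats = feature_columns(table)
    baro = [f for f in feats if f.startswith("baro_")]
    if len(baro) != 8:
        raise ValueError("table must contain the 8 barometer features")
    without = [f for f in feats if not f.startswith("baro_")]
    return {
        "with_barometer": loso_population(table, cohort, cfg, feature_set=feats,
                                          design="ablation_with_baro"),
        "without_barometer": loso_population(table, cohort, cfg, feature_set=without,
                                             design="ablation_without_baro"),
    }


def pairwise_confusion_rate(cm: ConfusionMatrix, true_class: str,
                            predicted_class: str) -> float:
    """Fraction of ``true_class`` instances predicted as ``predicted_class``."""
    i = cm.classes.index(true_class)
    j = cm.classes.index(predicted_class)
    row = cm.counts[i].sum()
    return float(cm.counts[i, j] / row) if row else float("nan")


# ---------------------------------------------------------------------------
# Statistical test battery
# ---------------------------------------------------------------------------

def paired_t(report_a: EvaluationReport, report_b: EvaluationReport) -> dict:
    """Paired t-test on per-subject mean recalls (same subjects, two designs)."""
    ids_a = [s.subject_id for s in report_a.subjects]
    ids_b = [s.subject_id for s in report_b.subjects]
    if ids_a != ids_b:
        raise ValueError("paired comparison requires identical subject sets")
    a, b = report_a.mean_recalls(), report_b.mean_recalls()
    if np.allclose(a, b):
        return {"t": 0.0, "p": 1.0, "n": len(a)}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "n": len(a)}


def two_sample_t(report_a: EvaluationReport, report_b: EvaluationReport) -> dict:
    t, p = stats.ttest_ind(report_a.mean_recalls(), report_b.mean_recalls())
    return {"t": float(t), "p": float(p),
            "n_a": len(report_a.subjects), "n_b": len(report_b.subjects)}


def anova_tukey(values: np.ndarray, groups: np.ndarray, alpha: float = 0.05) -> dict:
    """One-way ANOVA plus Tukey HSD over (e.g.) impairment strata."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("ANOVA needs at least two groups")
    samples = [values[groups == g] for g in uniq]
    f, p = stats.f_oneway(*samples)
    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairs = [
        dict(group1=str(r[0]), group2=str(r[1]), meandiff=float(r[2]),
             p_adj=float(r[3]), reject=bool(r[6]))
        for r in tukey.summary().data[1:]
    ]
    return {"F": float(f), "p": float(p), "tukey": pairs}


def pearson_speed_correlation(report: EvaluationReport,
                              metric: str = "mean_recall") -> dict:
    """Pearson r between per-subject gait speed and a per-subject metric.

    ``metric`` is 'mean_recall' or a key of the misclassification dict.
    """
    speeds, vals = [], []
    for s in report.subjects:
        v = s.mean_recall if metric == "mean_recall" else s.misclassification[metric]
        if not (np.isnan(v) or np.isnan(s.gait_speed)):
            speeds.append(s.gait_speed)
            vals.append(v)
    r, p = stats.pearsonr(speeds, vals)
    return {"r": float(r), "p": float(p), "n": len(vals)}
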