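import numpy as np
import pandas as pd
import pytest

from stridelab import evaluation as ev
from stridelab.model import ModelConfig
from stridelab.sensor_io import ACTIVITIES


def _cm(counts, classes=("a", "b", "c")):
    return ev.ConfusionMatrix(tuple(classes), np.asarray(counts))


class TestConfusionAndRecall:
    def test_perfect_predictions(self):
        y = np.array(["Sitting", "Walking", "Lying"] * 5)
        cm, recalls, mean_rec = ev.confusion_and_recall(y, y)
        present = [c for c in cm.classes if not np.isnan(recalls[c])]
        assert all(recalls[c] == 1.0 for c in present)
        assert mean_rec == 1.0
        assert cm.total == len(y)

    def test_mean_recall_arithmetic(self):
        # recalls 1.0, 0.5, 0.0 -> mean 0.5
        cm = _cm([[4, 0, 0], [2, 2, 0], [3, 1, 0]])
        r = cm.per_class_recall()
        assert (r["a"], r["b"], r["c"]) == (1.0, 0.5, 0.0)
        assert cm.mean_recall() == pytest.approx(0.5)

    def test_hand_computed_three_class(self):
        true = ["a"] * 6 + ["b"] * 4 + ["c"] * 2
        pred = ["a"] * 5 + ["b"] + ["b"] * 3 + ["c"] + ["c", "a"]
        cm, recalls, mean_rec = ev.confusion_and_recall(true, pred,
                                                        classes=("a", "b", "c"))
        assert cm.counts.tolist() == [[5, 1, 0], [0, 3, 1], [1, 0, 1]]
        assert recalls["a"] == pytest.approx(5 / 6)
        assert mean_rec == pytest.approx((5 / 6 + 3 / 4 + 1 / 2) / 3)

    def test_absent_class_omitted_from_mean(self):
        true = ["a", "a", "b", "b"]
        pred = ["a", "a", "b", "a"]
        cm, recalls, mean_rec = ev.confusion_and_recall(true, pred,
                                                        classes=("a", "b", "c"))
        assert np.isnan(recalls["c"])
        assert mean_rec == pytest.approx((1.0 + 0.5) / 2)

    def test_recalls_recomputed_from_matrix_match(self):
        rng = np.random.default_rng(0)
        true = rng.choice(list(ACTIVITIES), 500)
        pred = rng.choice(list(ACTIVITIES), 500)
        cm, recalls, mean_rec = ev.confusion_and_recall(true, pred)
        rows = cm.counts.sum(axis=1)
        manual = {c: cm.counts[i, i] / rows[i] for i, c in enumerate(cm.classes)}
        assert recalls == manual
        assert cm.total == 500

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_and_recall(["a"], ["z"], classes=("a", "b"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_and_recall(["a"], ["a", "b"], classes=("a", "b"))


class TestGroupMisclassification:
    def test_published_ratio(self):
        """10,210 of 33,060 true-ambulatory instances predicted stationary
        is a 30.88% ambulatory-as-stationary rate."""
        counts = np.zeros((6, 6), dtype=int)
        classes = tuple(ACTIVITIES)  # first 3 stationary, last 3 ambulatory
        # distribute 33,060 ambulatory instances; 10,210 predicted stationary
        counts[3, 0], counts[4, 1], counts[5, 2] = 4000, 3000, 3210
        counts[3, 3], counts[4, 4], counts[5, 5] = 8000, 8000, 6850
        cm = ev.ConfusionMatrix(classes, counts)
        rates = ev.group_misclassification(cm)
        assert counts[3:].sum() == 33060
        assert rates["ambulatory_as_stationary"] == pytest.approx(10210 / 33060)
        assert round(100 * rates["ambulatory_as_stationary"], 2) == 30.88

    def test_all_correct_gives_zero(self):
        cm = ev.ConfusionMatrix(tuple(ACTIVITIES), np.diag([5] * 6))
        rates = ev.group_misclassification(cm)
        assert rates == {"ambulatory_as_stationary": 0.0,
                         "stationary_as_ambulatory": 0.0}

    def test_all_ambulatory_predicted_sitting(self):
        counts = np.zeros((6, 6), dtype=int)
        for i in (3, 4, 5):
            counts[i, 0] = 10  # everything ambulatory called Sitting
        cm = ev.ConfusionMatrix(tuple(ACTIVITIES), counts)
        assert ev.group_misclassification(cm)["ambulatory_as_stationary"] == 1.0

    def test_grouping_must_cover_classes(self):
        cm = _cm(np.diag([1, 1, 1]))
        with pytest.raises(ValueError):
            ev.group_misclassification(cm, {"stationary": {"a"}, "ambulatory": {"b"}})


def _toy_table(rng, n_subjects=4, clips_per_class=30, cohort="stroke",
               sessions=("Lab1",), spread=0.4, speeds=None):
    """Small instance table with separable per-class Gaussian features."""
    rows = []
    centers = {a: i * 2.0 for i, a in enumerate(ACTIVITIES)}
    for si in range(n_subjects):
        speed = speeds[si] if speeds else 1.0
        for session in sessions:
            for a in ACTIVITIES:
                for k in range(clips_per_class):
                    rows.append(dict(
                        subject_id=f"T{si:02d}", session=session,
                        environment="lab" if session.startswith("Lab") else "home",
                        activity=a, cohort=cohort,
                        impairment="mild" if speed > 0.8 else "severe",
                        gait_speed=speed, bout_id=f"T{si}_{session}_{a}",
                        start_s=float(k), bout_duration_s=70.0,
                        f0=centers[a] + rng.normal(0, spread),
                        f1=rng.normal(0, 1.0)))
    return pd.DataFrame(rows)


CFG = ModelConfig(n_trees=5, undersample_target=30, seed=0)


class TestDesigns:
    def test_loso_split_contract(self, rng):
        table = _toy_table(rng)
        report = ev.loso_population(table, "stroke", CFG)
        ids = [s.subject_id for s in report.subjects]
        assert ids == sorted(table.subject_id.unique())
        assert len(set(ids)) == len(ids)
        # separable features: every held-out subject classified near-perfectly
        assert report.mean_recall > 0.95

    def test_loso_needs_two_subjects(self, rng):
        table = _toy_table(rng, n_subjects=1)
        with pytest.raises(ValueError):
            ev.loso_population(table, "stroke", CFG)

    def test_cross_cohort_reports_per_test_subject(self, rng):
        healthy = _toy_table(rng, n_subjects=3, cohort="healthy")
        stroke = _toy_table(rng, n_subjects=4, cohort="stroke")
        stroke["subject_id"] = "S" + stroke["subject_id"]
        table = pd.concat([healthy, stroke], ignore_index=True)
        report = ev.cross_cohort(table, "healthy", "stroke", CFG)
        assert len(report.subjects) == 4
        assert report.design == "healthy_to_stroke"

    def test_confusion_conservation(self, rng):
        table = _toy_table(rng)
        report = ev.loso_population(table, "stroke", CFG)
        assert report.pooled_cm().total == len(table)
        for s in report.subjects:
            assert s.mean_recall == pytest.approx(s.cm.mean_recall())


class TestEligibility:
    def test_sixty_second_rule(self, rng):
        table = _toy_table(rng, n_subjects=2, sessions=("Lab1", "Home", "Lab2"))
        # subject T01: only 50 s of StairsUp at Home
        mask = ((table.subject_id == "T01") & (table.session == "Home")
                & (table.activity == "StairsUp"))
        table.loc[mask, "bout_duration_s"] = 50.0
        assert ev.eligible_subjects(table) == ["T00"]

    def test_missing_session_excludes(self, rng):
        table = _toy_table(rng, n_subjects=2, sessions=("Lab1", "Home"))
        assert ev.eligible_subjects(table) == []


class TestChronologicalFolds:
    def test_folds_time_disjoint_after_boundary_drop(self, rng):
        # one subject, one long bout of 90 overlapping clips
        sub = pd.DataFrame(dict(
            subject_id="T00", session="Home", environment="home",
            activity="Walking", bout_id="b0",
            start_s=np.arange(90, dtype=float), bout_duration_s=99.0))
        folds = ev.chronological_folds(sub, n_folds=4)
        starts = sub.start_s.to_numpy()
        for f in range(4):
            for g in range(f + 1, 4):
                for i in folds[f]:
                    for j in folds[g]:
                        # 10-s spans must not share any raw samples
                        assert (starts[i] + 10 <= starts[j]
                                or starts[j] + 10 <= starts[i])

    def test_all_clips_assigned_or_dropped_once(self):
        sub = pd.DataFrame(dict(
            subject_id="T00", session="Home", environment="home",
            activity="Walking", bout_id="b0",
            start_s=np.arange(60, dtype=float), bout_duration_s=69.0))
        folds = ev.chronological_folds(sub, n_folds=4)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == len(set(all_idx))
        assert len(all_idx) < 60  # boundary clips dropped


class TestStatistics:
    def _report(self, values, speeds=None, name="r"):
        subs = []
        for i, v in enumerate(values):
            cm = ev.ConfusionMatrix(("a", "b"), np.array([[1, 0], [0, 1]]))
            subs.append(ev.SubjectResult(
                f"S{i:02d}", "mild", speeds[i] if speeds else 1.0, cm, v,
                {"ambulatory_as_stationary": 0.0, "stationary_as_ambulatory": 0.0}))
        return ev.EvaluationReport(name, subs, ("a", "b"))

    def test_identical_paired_vectors(self):
        a = self._report([0.5, 0.6, 0.7])
        b = self._report([0.5, 0.6, 0.7])
        out = ev.paired_t(a, b)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_paired_requires_same_subjects(self):
        a = self._report([0.5, 0.6])
        b = self._report([0.5, 0.6, 0.7])
        with pytest.raises(ValueError):
            ev.paired_t(a, b)

    def test_two_sample_t_direction(self, rng):
        a = self._report(list(0.8 + 0.01 * rng.standard_normal(8)))
        b = self._report(list(0.5 + 0.01 * rng.standard_normal(8)))
        out = ev.two_sample_t(a, b)
        assert out["t"] > 0 and out["p"] < 1e-6

    def test_pearson_exactly_linear(self):
        speeds = [0.2, 0.5, 0.8, 1.1]
        rep = self._report([0.1, 0.25, 0.4, 0.55], speeds=speeds)
        out = ev.pearson_speed_correlation(rep, "mean_recall")
        assert out["r"] == pytest.approx(1.0)

    def test_anova_tukey_detects_separation(self, rng):
        vals = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(2, 0.1, 10),
                               rng.normal(4, 0.1, 10)])
        groups = np.repeat(["mild", "moderate", "severe"], 10)
        out = ev.anova_tukey(vals, groups)
        assert out["p"] < 1e-9
        assert all(pair["reject"] for pair in out["tukey"])

    def test_anova_type_one_error_rate(self, rng):
        """Equal-mean groups are rejected at roughly the alpha rate."""
        from scipy import stats
        rejections = 0
        sims = 1000
        for _ in range(sims):
            g = rng.standard_normal((3, 10))
            _, p = stats.f_oneway(*g)
            rejections += p < 0.05
        rate = rejections / sims
        assert 0.03 <= rate <= 0.07  # ~3 binomial SDs around 0.05


class TestLearningCurve:
    def test_structure_and_degenerate_ci(self, rng):
        table = _toy_table(rng, n_subjects=5, clips_per_class=20)
        out = ev.learning_curve(table, "stroke", "stroke", [2], CFG,
                                n_instances=200, reps=1, seed=0)
        assert list(out.columns) == ["n_subjects", "mean_recall", "ci_low",
                                     "ci_high", "reps"]
        row = out.iloc[0]
        assert row.ci_low == row.mean_recall == row.ci_high

    def test_size_exceeding_pool_rejected(self, rng):
        table = _toy_table(rng, n_subjects=3, clips_per_class=10)
        with pytest.raises(ValueError):
            ev.learning_curve(table, "stroke", "stroke", [3], CFG,
                              n_instances=50, reps=1, seed=0)

    def test_more_training_subjects_help_under_subject_shift(self, rng):
        """With heterogeneous subjects, training pools covering more subjects
        yield at least comparable mean recall."""
        speeds = [0.3, 0.5, 0.9, 1.1, 0.4, 1.0, 0.7, 0.35]
        table = _toy_table(rng, n_subjects=8, clips_per_class=15, speeds=speeds,
                           spread=1.2)
        # per-subject feature shift so single-subject training generalizes worse
        shift = {f"T{si:02d}": rng.normal(0, 1.0) for si in range(8)}
        table["f0"] = table["f0"] + table["subject_id"].map(shift)
        out = ev.learning_curve(table, "stroke", "stroke", [1, 5], CFG,
                                n_instances=80, reps=8, seed=1)
        assert out.iloc[1].mean_recall >= out.iloc[0].mean_recall - 0.02


class TestAblation:
    def test_feature_sets_differ_by_eight(self, rng):
        table = _toy_table(rng, n_subjects=3, cohort="healthy", clips_per_class=15)
        # add 8 synthetic barometer feature columns, mildly informative
        for i, name in enumerate(
                ["baro_d_mean", "baro_d_sd", "baro_d_skew", "baro_d_kurt",
                 "baro_sd", "baro_range", "baro_iqr", "baro_slope"]):
            table[name] = rng.normal(0, 1, len(table))
        reports = ev.ablate_barometer(table, "healthy", CFG)
        n_with = reports["with_barometer"].config["n_features"]
        n_without = reports["without_barometer"].config["n_features"]
        assert n_with - n_without == 8

    def test_requires_barometer_columns(self, rng):
        table = _toy_table(rng, n_subjects=3, cohort="healthy", clips_per_class=10)
        with pytest.raises(ValueError):
            ev.ablate_barometer(table, "healthy", CFG)
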