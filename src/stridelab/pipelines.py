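"""End-to-end study pipelines at desk scale.

Chains the generator, preprocessing, feature extraction and the evaluation
designs into the study comparisons: population transfer (healthy vs stroke
training), gait-impairment stratification, and lab-vs-home environmental
models.  Problem sizes default to a desk scale that runs on one CPU in
minutes (see docs/methods.md); all randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation as ev
from .features import build_instance_table, feature_columns
from .model import ModelConfig
from .preprocessing import TrimConfig, preprocess_recording
from .synthetic_data import CohortSpec, Manifest, generate_cohort

#: model configuration used by the desk-scale evaluation designs; the
#: ModelConfig defaults (200 trees, minority-count undersampling) remain the
#: reference configuration for full-scale runs.
DESK_MODEL_CFG = dict(n_trees=50, undersample_target=150, min_leaf=5, learn_rate=1.0)


def desk_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """Desk-scale cohort: 8 healthy plus 6 stroke subjects per impairment stratum."""
    kw = dict(n_healthy=8, n_mild=6, n_moderate=6, n_severe=6, rng_seed=seed)
    kw.update(overrides)
    return CohortSpec(**kw)


def recordings_to_table(recordings, manifest: Manifest | None = None,
                        trim_cfg: TrimConfig | None = None) -> pd.DataFrame:
    """Preprocess every recording and assemble the instance table.

    Subject metadata (cohort, impairment, gait speed) is attached from the
    recordings' own metadata.
    """
    all_clips = []
    meta_by_clip = []
    for rec in recordings:
        clips, _ = preprocess_recording(rec, trim_cfg)
        all_clips.extend(clips)
        meta_by_clip.extend([rec.metadata] * len(clips))
    table = build_instance_table(all_clips)
    if len(table):
        table["cohort"] = [m.get("cohort") for m in meta_by_clip]
        table["impairment"] = [m.get("impairment") for m in meta_by_clip]
        table["gait_speed"] = [m.get("gait_speed", np.nan) for m in meta_by_clip]
    return table


def simulate_table(seed: int, spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate a cohort and run it through preprocessing and featurization."""
    spec = spec or desk_cohort_spec(seed)
    recordings, manifest = generate_cohort(spec)
    return recordings_to_table(recordings, manifest)


@dataclass
class QualitativeResult:
    """Key quantities of the population/impairment/environment comparisons."""

    seed: int
    healthy_to_stroke_recall: float
    stroke_to_stroke_recall: float
    amb_as_stat_healthy: dict[str, float]   # stratum -> rate, healthy-trained
    amb_as_stat_stroke: dict[str, float]    # stratum -> rate, stroke-trained
    personal_recall: dict[str, float]       # design -> mean recall
    n_instances: int
    n_eligible: int


def run_qualitative_designs(table: pd.DataFrame, seed: int = 0,
                            model_cfg: dict | None = None) -> QualitativeResult:
    """Run the three design families on one instance table."""
    cfgkw = dict(DESK_MODEL_CFG)
    if model_cfg:
        cfgkw.update(model_cfg)
    cfg = ModelConfig(seed=seed, **cfgkw)

    h2s = ev.cross_cohort(table, "healthy", "stroke", cfg)
    s2s = ev.loso_population(table, "stroke", cfg)
    strat_h = ev.stratified_rates(h2s).set_index("impairment")
    strat_s = ev.stratified_rates(s2s).set_index("impairment")

    personal = ev.environmental_personal(table, cfg)
    return QualitativeResult(
        seed=seed,
        healthy_to_stroke_recall=h2s.mean_recall,
        stroke_to_stroke_recall=s2s.mean_recall,
        amb_as_stat_healthy={k: float(strat_h.loc[k, "ambulatory_as_stationary"])
                             for k in ("mild", "moderate", "severe")},
        amb_as_stat_stroke={k: float(strat_s.loc[k, "ambulatory_as_stationary"])
                            for k in ("mild", "moderate", "severe")},
        personal_recall={k: r.mean_recall for k, r in personal.items()},
        n_instances=len(table),
        n_eligible=len(personal["lab1_to_home"].subjects),
    )


def qualitative_suite(seeds, spec_factory=desk_cohort_spec,
                      model_cfg: dict | None = None) -> list[QualitativeResult]:
    """Full pipeline (generate, preprocess, featurize, evaluate) per seed."""
    out = []
    for seed in seeds:
        table = simulate_table(seed, spec_factory(seed))
        out.append(run_qualitative_designs(table, seed=seed, model_cfg=model_cfg))
    return out


def make_rare_class_benchmark(seed: int, n_train: int = 4000, n_test: int = 2000,
                              rare_frac: float = 0.015, n_features: int = 20,
                              n_informative: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Six-class Gaussian benchmark with two rare (~1.5% prevalence) classes.

    Mimics the class imbalance of free-living activity labels, where stair
    activities are a percent-scale minority: the two rare classes (the stair
    labels) sit close to the dominant Walking cluster so that an unweighted
    learner profitably ignores them.  Returns (train, test) instance tables.
    """
    from .sensor_io import ACTIVITIES

    rng = np.random.default_rng(seed)
    classes = list(ACTIVITIES)
    rare = {"StairsUp", "StairsDown"}
    common = [c for c in classes if c not in rare]
    centers = {}
    for i, c in enumerate(common):
        mu = np.zeros(n_features)
        mu[:n_informative] = 3.0 * rng.standard_normal(n_informative)
        centers[c] = mu
    for c in sorted(rare):
        # rare classes near the Walking cluster, offset by ~1.5 sigma
        off = rng.standard_normal(n_informative)
        off *= 1.5 / np.linalg.norm(off)
        mu = centers["Walking"].copy()
        mu[:n_informative] += off
        centers[c] = mu

    def _draw(n_total):
        n_rare = max(int(round(rare_frac * n_total)), 8)
        counts = {c: n_rare for c in rare}
        n_left = n_total - 2 * n_rare
        for i, c in enumerate(common):
            counts[c] = n_left // len(common) + (1 if i < n_left % len(common) else 0)
        X, y = [], []
        for c in classes:
            X.append(centers[c] + rng.standard_normal((counts[c], n_features)))
            y += [c] * counts[c]
        df = pd.DataFrame(np.vstack(X), columns=[f"f{i}" for i in range(n_features)])
        df.insert(0, "activity", y)
        return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)

    return _draw(n_train), _draw(n_test)


def rare_class_comparison(seed: int, n_trees: int = 50) -> dict:
    """Rare-class mean recall of RUSBoost vs the plain RF baseline, one seed."""
    from . import evaluation as ev
    from .model import train as train_model

    train_tab, test_tab = make_rare_class_benchmark(seed)
    feats = [c for c in train_tab.columns if c != "activity"]
    out = {}
    for algo in ("rusboost", "random_forest"):
        cfg = ModelConfig(n_trees=n_trees, algorithm=algo, seed=seed)
        m = train_model(train_tab[feats].to_numpy(), train_tab["activity"].to_numpy(),
                        cfg, feature_names=feats)
        pred = m.predict(test_tab[feats].to_numpy())
        cm, recalls, _ = ev.confusion_and_recall(test_tab["activity"], pred)
        out[algo] = {
            "rare_mean_recall": float(np.mean([recalls["StairsUp"], recalls["StairsDown"]])),
            "overall_mean_recall": cm.mean_recall(),
        }
    out["advantage"] = (out["rusboost"]["rare_mean_recall"]
                        - out["random_forest"]["rare_mean_recall"])
    return out


def summarize_qualitative(results: list[QualitativeResult]) -> dict:
    """Seed-averaged quantities for the three qualitative comparisons."""
    strata = ("mild", "moderate", "severe")
    amb_h = {k: float(np.mean([r.amb_as_stat_healthy[k] for r in results]))
             for k in strata}
    amb_s = {k: float(np.mean([r.amb_as_stat_stroke[k] for r in results]))
             for k in strata}
    personal = {k: float(np.mean([r.personal_recall[k] for r in results]))
                for k in results[0].personal_recall}
    return {
        "healthy_to_stroke_recall": float(np.mean(
            [r.healthy_to_stroke_recall for r in results])),
        "stroke_to_stroke_recall": float(np.mean(
            [r.stroke_to_stroke_recall for r in results])),
        "amb_as_stat_healthy_trained": amb_h,
        "amb_as_stat_stroke_trained": amb_s,
        "healthy_trained_range": amb_h["severe"] - amb_h["mild"],
        "stroke_trained_range": max(amb_s.values()) - min(amb_s.values()),
        "personal_recall": personal,
        "n_seeds": len(results),
    }
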