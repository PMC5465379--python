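"""RUSBoost for imbalanced multiclass activity recognition.

RUSBoost combines boosting (AdaBoost.M2, with a weight distribution over
(instance, incorrect-label) pairs and pseudo-loss) with random
undersampling: each boosting iteration fits its weak decision tree on a
random class-balanced undersample, while the pseudo-loss and weight updates
use the full weighted training set.  This targets class imbalance — e.g.
rare stair activities amid abundant sitting — without discarding data
permanently.  A plain random-forest baseline is included for comparisons.

Weak learners are axis-aligned CART trees (Gini impurity, exhaustive
threshold search, no depth limit; minimum leaf size is the only
regularizer).  Ties in the final weighted vote break toward the
alphabetically first class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

MAX_LOG_WEIGHT = float(np.log(1e10))  # learner weight cap when pseudo-loss hits 0


@dataclass
class ModelConfig:
    n_trees: int = 200
    learn_rate: float = 1.0
    min_leaf: int = 5
    undersample_target: int | None = None  # None -> minority-class count
    algorithm: str = "rusboost"            # 'rusboost' | 'random_forest'
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0 < self.learn_rate <= 1:
            raise ValueError("learn_rate must be in (0, 1]")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.algorithm not in ("rusboost", "random_forest"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


class _ArrayTree:
    """Decision tree reconstructed from serialized node arrays."""

    def __init__(self, children_left, children_right, feature, threshold, proba,
                 class_idx):
        self.children_left = np.asarray(children_left, dtype=np.int64)
        self.children_right = np.asarray(children_right, dtype=np.int64)
        self.feature = np.asarray(feature, dtype=np.int64)
        self.threshold = np.asarray(threshold, dtype=float)
        self.proba = np.asarray(proba, dtype=float)       # (n_nodes, n_tree_classes)
        self.class_idx = np.asarray(class_idx, dtype=np.int64)

    def predict_proba_full(self, X: np.ndarray, n_classes: int) -> np.ndarray:
        node = np.zeros(len(X), dtype=np.int64)
        while True:
            leaf = self.children_left[node] == -1
            if leaf.all():
                break
            active = ~leaf
            f = self.feature[node[active]]
            go_left = X[active, f] <= self.threshold[node[active]]
            nxt = np.where(go_left, self.children_left[node[active]],
                           self.children_right[node[active]])
            node[active] = nxt
        out = np.zeros((len(X), n_classes))
        out[:, self.class_idx] = self.proba[node]
        return out


def _tree_proba_full(tree, X: np.ndarray, class_to_idx: dict, n_classes: int) -> np.ndarray:
    p = tree.predict_proba(X)
    out = np.zeros((len(X), n_classes))
    cols = [class_to_idx[c] for c in tree.classes_]
    out[:, cols] = p
    return out


@dataclass
class TrainedEnsemble:
    """A trained RUSBoost or random-forest model."""

    algorithm: str
    classes: tuple[str, ...]           # alphabetical
    feature_names: tuple[str, ...]
    trees: list = field(default_factory=list)          # sklearn trees or _ArrayTree
    log_betas: list[float] = field(default_factory=list)  # learn_rate * ln(1/beta_t)
    config: ModelConfig | None = None
    metadata: dict = field(default_factory=dict)
    _rf: RandomForestClassifier | None = None

    @property
    def n_learners(self) -> int:
        return len(self.trees) if self.algorithm == "rusboost" else (
            len(self._rf.estimators_) if self._rf is not None else len(self.trees))

    def _scores(self, X: np.ndarray) -> np.ndarray:
        n_classes = len(self.classes)
        class_to_idx = {c: i for i, c in enumerate(self.classes)}
        if self.algorithm == "random_forest":
            if self._rf is not None:
                p = self._rf.predict_proba(X)
                out = np.zeros((len(X), n_classes))
                cols = [class_to_idx[c] for c in self._rf.classes_]
                out[:, cols] = p
                return out
            total = np.zeros((len(X), n_classes))
            for t in self.trees:
                total += t.predict_proba_full(X, n_classes)
            return total
        total = np.zeros((len(X), n_classes))
        for tree, lb in zip(self.trees, self.log_betas):
            if isinstance(tree, _ArrayTree):
                total += lb * tree.predict_proba_full(X, n_classes)
            else:
                total += lb * _tree_proba_full(tree, X, class_to_idx, n_classes)
        return total

    def predict_scores(self, X) -> np.ndarray:
        """Per-class scores normalized to sum to 1 per instance."""
        X = self._coerce(X)
        s = self._scores(X)
        tot = s.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        return s / tot

    def predict(self, X) -> np.ndarray:
        """argmax of the weighted vote; ties break to the first (alphabetical) class."""
        X = self._coerce(X)
        s = self._scores(X)
        return np.asarray(self.classes)[np.argmax(s, axis=1)]

    def _coerce(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names) - set(X.columns)
            if missing:
                raise KeyError(f"instances lack model features: {sorted(missing)[:5]}")
            X = X[list(self.feature_names)].to_numpy(float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        return np.nan_to_num(X, nan=0.0)

    # -- persistence (documented structured text format) --------------------
    def to_json(self) -> str:
        trees = []
        for t in self.trees:
            if isinstance(t, _ArrayTree):
                trees.append(dict(
                    children_left=t.children_left.tolist(),
                    children_right=t.children_right.tolist(),
                    feature=t.feature.tolist(),
                    threshold=t.threshold.tolist(),
                    proba=t.proba.tolist(),
                    class_idx=t.class_idx.tolist()))
            else:
                tt = t.tree_
                counts = tt.value[:, 0, :]
                proba = counts / counts.sum(axis=1, keepdims=True)
                class_to_idx = {c: i for i, c in enumerate(self.classes)}
                trees.append(dict(
                    children_left=tt.children_left.tolist(),
                    children_right=tt.children_right.tolist(),
                    feature=tt.feature.tolist(),
                    threshold=tt.threshold.tolist(),
                    proba=proba.tolist(),
                    class_idx=[class_to_idx[c] for c in t.classes_]))
        return json.dumps(dict(
            format="stridelab-ensemble-v1",
            algorithm=self.algorithm,
            classes=list(self.classes),
            feature_names=list(self.feature_names),
            log_betas=list(self.log_betas),
            metadata=self.metadata,
            trees=trees))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEnsemble":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "stridelab-ensemble-v1":
            raise ValueError("unrecognized model file format")
        trees = [_ArrayTree(**t) for t in d["trees"]]
        return cls(algorithm=d["algorithm"], classes=tuple(d["classes"]),
                   feature_names=tuple(d["feature_names"]), trees=trees,
                   log_betas=list(d["log_betas"]), metadata=d["metadata"])


def _rus_indices(y_idx: np.ndarray, n_classes: int, target: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Class-balanced undersample: ``target`` per class, with replacement only
    when a class is smaller than the target.  When a class exactly matches the
    target every one of its instances is taken (in index order)."""
    parts = []
    for c in range(n_classes):
        pool = np.flatnonzero(y_idx == c)
        if len(pool) == target:
            parts.append(pool)
        else:
            parts.append(rng.choice(pool, size=target, replace=len(pool) < target))
    return np.concatenate(parts)


def train(table_or_X, y=None, cfg: ModelConfig | None = None,
          feature_names: list[str] | None = None) -> TrainedEnsemble:
    """Train a RUSBoost ensemble (or the RF baseline) on an instance table.

    Accepts either an instance-table DataFrame (features + 'activity' label
    column) or an (X, y) pair.  Deterministic given the config seed.
    """
    cfg = cfg or ModelConfig()
    if isinstance(table_or_X, pd.DataFrame):
        from .features import feature_columns
        feats = feature_names or feature_columns(table_or_X)
        X = table_or_X[feats].to_numpy(float)
        y = table_or_X["activity"].to_numpy()
    else:
        X = np.asarray(table_or_X, dtype=float)
        y = np.asarray(y)
        feats = feature_names or [f"f{i}" for i in range(X.shape[1])]
    X = np.nan_to_num(X, nan=0.0)
    classes = tuple(sorted(np.unique(y)))
    if len(classes) < 2:
        raise ValueError("training requires at least two classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < cfg.min_leaf:
        raise ValueError(
            f"every class needs >= min_leaf={cfg.min_leaf} instances; got {counts}")
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_to_idx[c] for c in y])
    n, k = len(y), len(classes)
    rng = np.random.default_rng(cfg.seed)

    if cfg.algorithm == "random_forest":
        rf = RandomForestClassifier(
            n_estimators=cfg.n_trees, min_samples_leaf=cfg.min_leaf,
            random_state=int(np.random.default_rng(cfg.seed).integers(2**31)))
        rf.fit(X, y)
        return TrainedEnsemble("random_forest", classes, tuple(feats),
                               config=cfg, metadata={"class_counts": counts},
                               _rf=rf)

    target = cfg.undersample_target or min(counts.values())
    # AdaBoost.M2 weights over (instance, wrong label) pairs
    W = np.full((n, k), 1.0 / (n * (k - 1)))
    W[np.arange(n), y_idx] = 0.0
    trees: list[DecisionTreeClassifier] = []
    log_betas: list[float] = []
    for _ in range(cfg.n_trees):
        D = W.sum(axis=1)
        D = D / D.sum()
        idx = _rus_indices(y_idx, k, target, rng)
        tree = DecisionTreeClassifier(
            min_samples_leaf=cfg.min_leaf,
            random_state=int(rng.integers(2**31)))
        sw = D[idx]
        tree.fit(X[idx], y[idx], sample_weight=sw / sw.sum())
        h = _tree_proba_full(tree, X, class_to_idx, k)
        h_true = h[np.arange(n), y_idx]
        # pseudo-loss over the full weighted set
        eps = 0.5 * float((W * (1.0 - h_true[:, None] + h)).sum())
        if eps <= 1e-12:
            trees.append(tree)
            log_betas.append(cfg.learn_rate * MAX_LOG_WEIGHT)
            break
        if eps >= 0.5:
            break
        beta = eps / (1.0 - eps)
        expo = cfg.learn_rate * 0.5 * (1.0 + h_true[:, None] - h)
        W = W * beta ** expo
        W[np.arange(n), y_idx] = 0.0
        W /= W.sum()
        trees.append(tree)
        log_betas.append(cfg.learn_rate * float(np.log(1.0 / beta)))
    if not trees:
        # first learner no better than chance: keep it with zero-ish weight
        trees.append(tree)  # type: ignore[has-type]
        log_betas.append(1e-9)
    return TrainedEnsemble("rusboost", classes, tuple(feats), trees, log_betas,
                           cfg, {"class_counts": counts,
                                 "undersample_target": target})


def predict(ensemble: TrainedEnsemble, X) -> np.ndarray:
    return ensemble.predict(X)
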