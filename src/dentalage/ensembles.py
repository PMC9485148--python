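"""Tree ensembles and KNN for staged-tooth age regression.

All learners share the native CART base from :mod:`dentalage.trees` and are
deterministic given (data, config, seed):

* :func:`fit_gbdt` — gradient boosting on squared loss: start from the mean
  age, then each round fits a tree to the current residuals and adds it
  scaled by the learning rate.
* :func:`fit_forest` — bagging (bootstrap resamples) or the extra-trees
  variant (full sample, randomized split thresholds); prediction is the
  mean over trees.
* :func:`fit_adaboost_r2` — AdaBoost.R2 with linear loss: loss-weighted
  resampling, multiplicative weight updates, and weighted-median
  aggregation.
* :func:`knn_predict` / :class:`KNNModel` — k-nearest-neighbour mean with
  Euclidean distance on the ordinal feature codes.

Every model serializes to a versioned JSON dict whose reload reproduces
identical predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .trees import RegressionTree, TreeConfig, fit_tree

SERIALIZATION_VERSION = 1


@dataclass(frozen=True)
class GBDTConfig:
    n_estimators: int = 100
    learning_rate: float = 0.1
    subsample: float = 1.0
    tree: TreeConfig = field(default_factory=lambda: TreeConfig(min_samples_leaf=1))

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 < self.subsample <= 1.0):
            raise ValueError("subsample must lie in (0, 1]")


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 100
    bootstrap: bool = True  # with-replacement resample per tree
    randomize_splits: bool = False  # extra-trees uniform-threshold splitter
    max_features: float = 1.0  # per-node feature subsampling fraction
    tree: TreeConfig = field(default_factory=lambda: TreeConfig(min_samples_leaf=1))

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.max_features <= 1.0):
            raise ValueError("max_features must lie in (0, 1]")


@dataclass(frozen=True)
class AdaBoostR2Config:
    n_estimators: int = 100
    learning_rate: float = 1.0
    tree: TreeConfig = field(default_factory=lambda: TreeConfig(min_samples_leaf=2))

    def __post_init__(self):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass(frozen=True)
class KNNConfig:
    k: int = 5

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


# ---------------------------------------------------------------------------
# GBDT
# ---------------------------------------------------------------------------

class GBDTModel:
    def __init__(self, base: float, trees: list[RegressionTree], cfg: GBDTConfig,
                 train_mse_path: list[float] | None = None):
        self.base = base
        self.trees = trees
        self.config = cfg
        #: training MSE after each boosting round (round 0 = mean-only model)
        self.train_mse_path = train_mse_path or []

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape[0], self.base)
        for tree in self.trees:
            out += self.config.learning_rate * tree.predict(X)
        return out

    def to_dict(self) -> dict:
        return {
            "version": SERIALIZATION_VERSION,
            "model": "gbdt",
            "base": self.base,
            "learning_rate": self.config.learning_rate,
            "subsample": self.config.subsample,
            "trees": [t.to_dict() for t in self.trees],
            "train_mse_path": self.train_mse_path,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "GBDTModel":
        trees = [RegressionTree.from_dict(t) for t in obj["trees"]]
        tree_cfg = trees[0].config if trees else TreeConfig(min_samples_leaf=1)
        cfg = GBDTConfig(
            n_estimators=max(len(trees), 1),
            learning_rate=obj["learning_rate"],
            subsample=obj["subsample"],
            tree=tree_cfg,
        )
        return cls(obj["base"], trees, cfg, list(obj.get("train_mse_path", [])))


def fit_gbdt(
    X: np.ndarray, y: np.ndarray, cfg: GBDTConfig | None = None, seed: int = 0
) -> GBDTModel:
    """Stagewise residual boosting: F_m = F_{m-1} + lr * tree(residuals)."""
    cfg = cfg or GBDTConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("gradient boosting needs at least 2 samples")
    rng = np.random.default_rng(seed)
    base = float(y.mean())
    current = np.full(y.shape, base)
    trees: list[RegressionTree] = []
    mse_path = [float(np.mean((y - current) ** 2))]
    n = y.size
    for _ in range(cfg.n_estimators):
        residual = y - current
        if cfg.subsample < 1.0:
            m = max(1, int(round(cfg.subsample * n)))
            idx = rng.choice(n, size=m, replace=False)
            tree = fit_tree(X[idx], residual[idx], cfg.tree)
        else:
            tree = fit_tree(X, residual, cfg.tree)
        current = current + cfg.learning_rate * tree.predict(X)
        trees.append(tree)
        mse_path.append(float(np.mean((y - current) ** 2)))
    return GBDTModel(base, trees, cfg, mse_path)


# ---------------------------------------------------------------------------
# Random forest / extra trees
# ---------------------------------------------------------------------------

class ForestModel:
    def __init__(self, trees: list[RegressionTree], cfg: ForestConfig):
        self.trees = trees
        self.config = cfg

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.mean([t.predict(X) for t in self.trees], axis=0)

    def to_dict(self) -> dict:
        return {
            "version": SERIALIZATION_VERSION,
            "model": "forest",
            "bootstrap": self.config.bootstrap,
            "randomize_splits": self.config.randomize_splits,
            "max_features": self.config.max_features,
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "ForestModel":
        trees = [RegressionTree.from_dict(t) for t in obj["trees"]]
        cfg = ForestConfig(
            n_trees=len(trees),
            bootstrap=obj["bootstrap"],
            randomize_splits=obj["randomize_splits"],
            max_features=obj["max_features"],
            tree=trees[0].config,
        )
        return cls(trees, cfg)


def fit_forest(
    X: np.ndarray, y: np.ndarray, cfg: ForestConfig | None = None, seed: int = 0
) -> ForestModel:
    """Averaged tree ensemble.

    bootstrap=True, randomize_splits=False is the random forest;
    bootstrap=False, randomize_splits=True the extra-trees variant.  A
    single tree without bootstrap, randomization or feature subsampling
    degenerates to the plain CART fit.
    """
    cfg = cfg or ForestConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("cannot fit a forest to an empty dataset")
    rng = np.random.default_rng(seed)
    n = y.size
    needs_rng = cfg.randomize_splits or cfg.max_features < 1.0
    trees = []
    for _ in range(cfg.n_trees):
        Xi, yi = X, y
        if cfg.bootstrap:
            idx = rng.integers(0, n, size=n)
            Xi, yi = X[idx], y[idx]
        trees.append(
            fit_tree(
                Xi,
                yi,
                cfg.tree,
                rng=rng if needs_rng else None,
                randomize=cfg.randomize_splits,
                max_features=cfg.max_features,
            )
        )
    return ForestModel(trees, cfg)


# ---------------------------------------------------------------------------
# AdaBoost.R2
# ---------------------------------------------------------------------------

_EPS = 1e-10


class AdaBoostR2Model:
    def __init__(self, trees: list[RegressionTree], log_weights: list[float],
                 cfg: AdaBoostR2Config, stopped_early: bool = False):
        self.trees = trees
        self.log_weights = log_weights  # ln(1/beta) per learner
        self.config = cfg
        self.stopped_early = stopped_early

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Weighted median of the learners' predictions, per query point."""
        X = np.asarray(X, dtype=float)
        preds = np.array([t.predict(X) for t in self.trees])  # (m, n)
        w = np.array(self.log_weights)
        order = np.argsort(preds, axis=0, kind="stable")
        sorted_preds = np.take_along_axis(preds, order, axis=0)
        sorted_w = w[order]
        cum = np.cumsum(sorted_w, axis=0)
        half = 0.5 * w.sum()
        pick = np.argmax(cum >= half, axis=0)
        return sorted_preds[pick, np.arange(X.shape[0])]

    def to_dict(self) -> dict:
        return {
            "version": SERIALIZATION_VERSION,
            "model": "adaboost_r2",
            "learning_rate": self.config.learning_rate,
            "log_weights": list(self.log_weights),
            "stopped_early": self.stopped_early,
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "AdaBoostR2Model":
        trees = [RegressionTree.from_dict(t) for t in obj["trees"]]
        cfg = AdaBoostR2Config(
            n_estimators=len(trees),
            learning_rate=obj["learning_rate"],
            tree=trees[0].config,
        )
        return cls(trees, list(obj["log_weights"]), cfg, obj["stopped_early"])


def fit_adaboost_r2(
    X: np.ndarray, y: np.ndarray, cfg: AdaBoostR2Config | None = None, seed: int = 0
) -> AdaBoostR2Model:
    """AdaBoost.R2 with linear loss and weighted resampling.

    Each round resamples the training set proportionally to the current
    weights, fits a tree, scores it by the weighted average linear loss
    L̄ = Σ wᵢ·|errᵢ|/max|err|, stops early when L̄ ≥ 0.5, and otherwise
    updates wᵢ ← wᵢ·β^(lr·(1−Lᵢ)) with β = L̄/(1−L̄).  A perfect round
    (L̄ → 0) is kept with an epsilon-guarded weight and ends boosting.
    """
    cfg = cfg or AdaBoostR2Config()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("AdaBoost.R2 needs at least 2 samples")
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)
    trees: list[RegressionTree] = []
    log_weights: list[float] = []
    stopped_early = False
    uniform = np.full(n, 1.0 / n)
    for _ in range(cfg.n_estimators):
        if np.array_equal(w, uniform):
            # uniform weights: the weighted resample would be pure noise;
            # fit the raw sample (keeps round 1 identical to the base tree)
            tree = fit_tree(X, y, cfg.tree)
        else:
            idx = rng.choice(n, size=n, replace=True, p=w)
            tree = fit_tree(X[idx], y[idx], cfg.tree)
        err = np.abs(tree.predict(X) - y)
        err_max = err.max()
        if err_max <= _EPS:  # perfect fit: keep it, stop boosting
            trees.append(tree)
            log_weights.append(float(np.log(1.0 / _EPS)))
            stopped_early = True
            break
        loss = err / err_max
        avg_loss = float(np.sum(w * loss))
        if avg_loss >= 0.5:
            if not trees:  # keep a lone weak learner rather than no model
                trees.append(tree)
                log_weights.append(_EPS)
            stopped_early = True
            break
        beta = max(avg_loss / (1.0 - avg_loss), _EPS)
        trees.append(tree)
        log_weights.append(float(cfg.learning_rate * np.log(1.0 / beta)))
        w = w * beta ** (cfg.learning_rate * (1.0 - loss))
        w /= w.sum()
    return AdaBoostR2Model(trees, log_weights, cfg, stopped_early)


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

class KNNModel:
    """Memorized training set; prediction = mean age of the k nearest points.

    Ties at the k-th distance are broken by training-set order (stable sort).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cfg: KNNConfig):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if cfg.k > y.size:
            raise ValueError(f"k={cfg.k} exceeds training size {y.size}")
        self.X = X
        self.y = y
        self.config = cfg

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        for i, q in enumerate(X):
            d = np.sqrt(((self.X - q) ** 2).sum(axis=1))
            nearest = np.argsort(d, kind="stable")[: self.config.k]
            out[i] = self.y[nearest].mean()
        return out

    def to_dict(self) -> dict:
        return {
            "version": SERIALIZATION_VERSION,
            "model": "knn",
            "k": self.config.k,
            "X": self.X.tolist(),
            "y": self.y.tolist(),
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "KNNModel":
        return cls(np.array(obj["X"]), np.array(obj["y"]), KNNConfig(k=obj["k"]))


def knn_predict(
    train: tuple[np.ndarray, np.ndarray], query: np.ndarray, cfg: KNNConfig | None = None
) -> float:
    """Convenience single-query KNN prediction."""
    cfg = cfg or KNNConfig()
    model = KNNModel(train[0], train[1], cfg)
    return float(model.predict(np.atleast_2d(np.asarray(query, dtype=float)))[0])


# ---------------------------------------------------------------------------
# Model file I/O
# ---------------------------------------------------------------------------

class TreeModelWrapper:
    """Uniform serialization facade for a bare regression tree."""

    def __init__(self, tree: RegressionTree):
        self.tree = tree
        self.config = tree.config

    def predict(self, X):
        return self.tree.predict(X)

    def to_dict(self) -> dict:
        return {"version": SERIALIZATION_VERSION, "model": "tree", "tree": self.tree.to_dict()}

    @classmethod
    def from_dict(cls, obj: dict) -> "TreeModelWrapper":
        return cls(RegressionTree.from_dict(obj["tree"]))


_MODEL_CLASSES = {
    "gbdt": GBDTModel,
    "forest": ForestModel,
    "adaboost_r2": AdaBoostR2Model,
    "knn": KNNModel,
    "tree": TreeModelWrapper,
}


def save_model(model, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh)
        fh.write("\n")


def load_model(path):
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    if obj.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model file version {obj.get('version')!r}")
    kind = obj.get("model")
    if kind not in _MODEL_CLASSES:
        raise ValueError(f"unknown model kind {kind!r}")
    return _MODEL_CLASSES[kind].from_dict(obj)
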