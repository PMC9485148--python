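"""Native CART regression trees grown best-first under a leaf budget.

The tree learner is the shared base of every ensemble in
:mod:`dentalage.ensembles`.  Growth is best-first: a priority queue of
frontier nodes ordered by the squared-error impurity decrease of their best
split, so a ``max_leaf_nodes`` budget always spends leaves where they buy
the most — the standard realization of a leaf-capped tree.

Split candidates are midpoints between consecutive distinct feature values;
ties in impurity decrease are broken toward the lower feature index, then
the lower threshold, making fits fully deterministic.  The extra-trees
variant instead draws one uniform random threshold per feature per node.
"""

from __future__ import annotations

import dataclasses
import heapq
from dataclasses import dataclass

import numpy as np

from .staging import TEETH, Cohort, Sex, StagingRecord

FEATURE_NAMES = ["sex"] + [f"t{t.value}" for t in TEETH]


def encode_features(record: StagingRecord) -> np.ndarray:
    """Ordinal feature vector: [sex_code, stage codes of the 7 teeth].

    Sex is 0 (female) / 1 (male); stages are A=1 … H=8 with MISSING=0,
    preserving the developmental ordering that threshold splits exploit.
    """
    codes = [1.0 if record.sex is Sex.MALE else 0.0]
    codes.extend(float(int(record.stages[t])) for t in TEETH)
    return np.array(codes)


def encode_cohort(cohort: Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n x 8) and chronological-age response vector."""
    X = np.array([encode_features(r) for r in cohort.records]).reshape(len(cohort), 8)
    y = cohort.ages()
    return X, y


@dataclass(frozen=True)
class TreeConfig:
    """Growth limits for one regression tree."""

    max_depth: int = 10
    max_leaf_nodes: int = 50
    min_samples_split: int = 2
    min_samples_leaf: int = 1
    min_leaf_weight: float = 0.0
    min_impurity_decrease: float = 0.0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.max_leaf_nodes < 2:
            raise ValueError("max_leaf_nodes must be >= 2")
        if min(self.min_samples_split, self.min_samples_leaf) < 1:
            raise ValueError("min_samples_split / min_samples_leaf must be >= 1")
        if self.min_leaf_weight < 0 or self.min_impurity_decrease < 0:
            raise ValueError("min_leaf_weight / min_impurity_decrease must be >= 0")


@dataclass
class _Node:
    feature: int = -1  # -1 marks a leaf
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0
    n_samples: int = 0
    depth: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.feature < 0


def _best_split(X, y, idx, cfg, rng=None, randomize=False, features=None):
    """Best (feature, threshold, sse_decrease, left_idx, right_idx) or None.

    With ``randomize`` one uniform threshold per feature is drawn instead of
    scanning midpoints (extra-trees split randomization); ``features``
    restricts the candidate features (per-node feature subsampling).
    """
    n = idx.size
    ysub = y[idx]
    total = ysub.sum()
    parent_score = total * total / n
    msl = cfg.min_samples_leaf
    best = None  # (decrease, feature, threshold)
    for j in (range(X.shape[1]) if features is None else features):
        x = X[idx, j]
        if not randomize:
            order = np.argsort(x, kind="stable")
            xs, ys_ = x[order], ysub[order]
            if xs[0] == xs[-1]:
                continue
            csum = np.cumsum(ys_)[:-1]
            nl = np.arange(1, n)
            nr = n - nl
            valid = (xs[1:] != xs[:-1]) & (nl >= msl) & (nr >= msl)
            if not valid.any():
                continue
            score = np.where(valid, csum * csum / nl + (total - csum) ** 2 / nr, -np.inf)
            k = int(np.argmax(score))
            decrease = score[k] - parent_score
            threshold = (xs[k] + xs[k + 1]) / 2.0
        else:
            lo, hi = x.min(), x.max()
            if lo == hi:
                continue
            threshold = float(rng.uniform(lo, hi))
            mask = x <= threshold
            nl_ = int(mask.sum())
            nr_ = n - nl_
            if nl_ < msl or nr_ < msl or nl_ == 0 or nr_ == 0:
                continue
            sl = ysub[mask].sum()
            decrease = sl * sl / nl_ + (total - sl) ** 2 / nr_ - parent_score
        if decrease <= 0:
            continue
        # strict > keeps the first (lowest feature index / threshold) on ties
        if best is None or decrease > best[0]:
            best = (float(decrease), j, float(threshold))
    if best is None:
        return None
    decrease, j, threshold = best
    mask = X[idx, j] <= threshold
    return decrease, j, threshold, idx[mask], idx[~mask]


class RegressionTree:
    """A fitted piecewise-constant regressor (leaf value = mean response)."""

    def __init__(self, root: _Node, cfg: TreeConfig):
        self.root = root
        self.config = cfg

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.value
        return out

    # -- structural audit ---------------------------------------------------
    def leaves(self) -> list[_Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend((node.left, node.right))
        return out

    def depth(self) -> int:
        return max(leaf.depth for leaf in self.leaves())

    def audit(self) -> None:
        """Assert the fitted structure respects its growth limits."""
        leaves = self.leaves()
        cfg = self.config
        if len(leaves) > cfg.max_leaf_nodes:
            raise AssertionError(f"{len(leaves)} leaves exceeds budget {cfg.max_leaf_nodes}")
        if self.depth() > cfg.max_depth:
            raise AssertionError(f"depth {self.depth()} exceeds max_depth {cfg.max_depth}")
        small = [l.n_samples for l in leaves if l.n_samples < cfg.min_samples_leaf]
        if small:
            raise AssertionError(f"leaves with {small} samples violate min_samples_leaf")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        def enc(node: _Node) -> dict:
            if node.is_leaf:
                return {"value": node.value, "n": node.n_samples, "depth": node.depth}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "n": node.n_samples,
                "depth": node.depth,
                "left": enc(node.left),
                "right": enc(node.right),
            }

        return {"config": dataclasses.asdict(self.config), "root": enc(self.root)}

    @classmethod
    def from_dict(cls, obj: dict) -> "RegressionTree":
        cfg = TreeConfig(**obj["config"])

        def dec(d: dict) -> _Node:
            if "feature" not in d:
                return _Node(value=d["value"], n_samples=d["n"], depth=d["depth"])
            return _Node(
                feature=d["feature"],
                threshold=d["threshold"],
                n_samples=d["n"],
                depth=d["depth"],
                left=dec(d["left"]),
                right=dec(d["right"]),
            )

        return cls(dec(obj["root"]), cfg)


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TreeConfig | None = None,
    rng: np.random.Generator | None = None,
    randomize: bool = False,
    max_features: float = 1.0,
) -> RegressionTree:
    """Grow a CART regression tree best-first by impurity decrease.

    ``randomize`` draws one uniform threshold per candidate feature per node
    (extra-trees splitter) instead of scanning midpoints; ``max_features``
    < 1 samples that fraction of features per node.  Both need ``rng``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, p) with matching response length")
    if X.shape[0] == 0:
        raise ValueError("cannot fit a tree to an empty dataset")
    if (randomize or max_features < 1.0) and rng is None:
        raise ValueError("randomized splits / feature subsampling need an rng")
    if not (0.0 < max_features <= 1.0):
        raise ValueError("max_features must lie in (0, 1]")
    cfg = cfg or TreeConfig()
    n = X.shape[0]
    p = X.shape[1]
    n_feat = max(1, int(round(max_features * p)))

    root = _Node(value=float(y.mean()), n_samples=n, depth=0)
    all_idx = np.arange(n)

    # frontier: (-decrease, insertion counter, node, split tuple)
    counter = 0
    frontier: list = []

    def consider(node: _Node, idx: np.ndarray) -> None:
        nonlocal counter
        if node.depth >= cfg.max_depth or idx.size < cfg.min_samples_split:
            return
        features = None
        if n_feat < p:
            features = np.sort(rng.choice(p, size=n_feat, replace=False))
        split = _best_split(X, y, idx, cfg, rng, randomize, features)
        if split is None:
            return
        decrease = split[0]
        if decrease < cfg.min_impurity_decrease * n:
            return
        heapq.heappush(frontier, (-decrease, counter, node, split))
        counter += 1

    consider(root, all_idx)
    n_leaves = 1
    while frontier and n_leaves < cfg.max_leaf_nodes:
        _, _, node, (decrease, j, threshold, left_idx, right_idx) = heapq.heappop(frontier)
        node.feature = j
        node.threshold = threshold
        node.left = _Node(
            value=float(y[left_idx].mean()), n_samples=left_idx.size, depth=node.depth + 1
        )
        node.right = _Node(
            value=float(y[right_idx].mean()), n_samples=right_idx.size, depth=node.depth + 1
        )
        n_leaves += 1
        consider(node.left, left_idx)
        consider(node.right, right_idx)

    return RegressionTree(root, cfg)
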