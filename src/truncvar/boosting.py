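"""Gradient-boosted regression trees, written from scratch.

The scorer is a shrunk sum of regression trees,

    f(x) = sum_{m=1}^{N_tree} eps * T_m(x),

fit by stagewise least squares on 0/1 class targets: starting from f_0 = 0,
tree ``m`` is fit to the residuals ``y - f_{m-1}(X)`` by greedy top-down
variance-reduction splitting (squared-error impurity, midpoint thresholds,
leaf value = mean residual).  Defaults follow the reference protocol:
shrinkage 0.005, 2000 trees, maximum depth 8.

Because the training sets contain roughly twice as many pathogenic as
neutral variants, two models are trained on complementary balanced halves
(each a random half of the pathogenic variants plus all neutral ones); the
reported score is the average of the two, clipped to [0, 1].

Determinism: split ties are broken by lowest feature index, then lowest
threshold, so training is reproducible bit-for-bit given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_SHRINKAGE = 0.005
DEFAULT_N_TREES = 2000
DEFAULT_MAX_DEPTH = 8
DEFAULT_MIN_LEAF = 1


@dataclass
class Hyperparams:
    """Boosting hyperparameters (defaults are the reference protocol's)."""

    shrinkage: float = DEFAULT_SHRINKAGE
    n_trees: int = DEFAULT_N_TREES
    max_depth: int = DEFAULT_MAX_DEPTH
    min_leaf: int = DEFAULT_MIN_LEAF

    @classmethod
    def desk_scale(cls, n_trees: int = 200) -> "Hyperparams":
        """Reduced configuration for small cohorts.

        Shrinkage scales inversely with the tree count so the total
        shrinkage mass ``eps * N_tree`` matches the full protocol (10), and
        ``min_leaf`` is raised to 10 because unpruned depth-8 trees memorize
        protein identity on cohorts of a few hundred variants.
        """
        return cls(
            shrinkage=10.0 / n_trees,
            n_trees=n_trees,
            max_depth=DEFAULT_MAX_DEPTH,
            min_leaf=10,
        )


class RegressionTree:
    """A binary regression tree stored as flat node arrays.

    ``feature[i] < 0`` marks node ``i`` as a leaf with prediction
    ``value[i]``; internal nodes send ``x[feature] <= threshold`` left.
    """

    def __init__(self, feature, threshold, left, right, value):
        self.feature = np.asarray(feature, dtype=np.int32)
        self.threshold = np.asarray(threshold, dtype=float)
        self.left = np.asarray(left, dtype=np.int32)
        self.right = np.asarray(right, dtype=np.int32)
        self.value = np.asarray(value, dtype=float)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def depth(self) -> int:
        depths = np.zeros(self.n_nodes, dtype=int)
        for i in range(self.n_nodes):
            if self.feature[i] >= 0:
                depths[self.left[i]] = depths[i] + 1
                depths[self.right[i]] = depths[i] + 1
        return int(depths.max(initial=0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if self.feature[node] < 0:
                out[idx] = self.value[node]
                continue
            go_left = X[idx, self.feature[node]] <= self.threshold[node]
            stack.append((int(self.left[node]), idx[go_left]))
            stack.append((int(self.right[node]), idx[~go_left]))
        return out

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RegressionTree":
        return cls(**payload)


def _best_split(Xs, rs, min_leaf):
    """Best (feature, threshold) by squared-error reduction on presorted data.

    ``Xs``/``rs`` are column-sorted copies of the node's feature matrix and
    residuals.  Returns ``None`` when no split strictly reduces the summed
    squared error.  Ties break to the lowest feature index, then the lowest
    threshold.
    """
    n = Xs.shape[0]
    csum = np.cumsum(rs, axis=0)
    total = csum[-1, 0]
    sizes = np.arange(1, n, dtype=float)[:, None]
    left_sum = csum[:-1]
    right_sum = total - left_sum
    # Maximizing sum-of-squares over the two children minimizes SSE.
    score = left_sum**2 / sizes + right_sum**2 / (n - sizes)
    valid = Xs[1:] > Xs[:-1]
    if min_leaf > 1:
        valid &= (sizes >= min_leaf) & ((n - sizes) >= min_leaf)
    score = np.where(valid, score, -np.inf)
    flat = score.T.ravel()  # feature-major: argmax ties -> lowest feature/threshold
    best = int(np.argmax(flat))
    best_score = flat[best]
    baseline = total * total / n
    if not np.isfinite(best_score) or best_score <= baseline + 1e-12 * max(1.0, abs(baseline)):
        return None
    f, pos = divmod(best, n - 1)
    threshold = 0.5 * (Xs[pos, f] + Xs[pos + 1, f])
    # Adjacent floats can round the midpoint onto the upper value, which
    # would send every sample left; fall back to the lower value.
    if threshold >= Xs[pos + 1, f]:
        threshold = Xs[pos, f]
    return f, threshold


def fit_regression_tree(
    X: np.ndarray,
    residuals: np.ndarray,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_leaf: int = DEFAULT_MIN_LEAF,
    return_train_pred: bool = False,
):
    """Fit one regression tree to residuals by greedy variance reduction.

    Leaf values are mean residuals; a node is not split when no candidate
    split strictly reduces the summed squared error or a child would fall
    below ``min_leaf`` samples.
    """
    X = np.asarray(X, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D array")
    if X.shape[0] != residuals.shape[0]:
        raise ValueError("X and residuals disagree on sample count")
    if not np.all(np.isfinite(residuals)):
        raise ValueError("residuals must be finite")

    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []
    train_pred = np.empty(X.shape[0]) if return_train_pred else None

    def new_node() -> int:
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        value.append(np.nan)
        return len(feature) - 1

    # (node id, row indices, depth) work stack.
    root = new_node()
    stack = [(root, np.arange(X.shape[0]), 0)]
    while stack:
        node, idx, depth = stack.pop()
        r = residuals[idx]
        split = None
        if depth < max_depth and idx.size >= 2 * min_leaf and idx.size >= 2:
            Xn = X[idx]
            order = np.argsort(Xn, axis=0, kind="stable")
            split = _best_split(
                np.take_along_axis(Xn, order, axis=0), r[order], min_leaf
            )
        if split is None:
            value[node] = float(r.mean())
            if train_pred is not None:
                train_pred[idx] = value[node]
            continue
        f, thr = split
        feature[node] = f
        threshold[node] = thr
        go_left = X[idx, f] <= thr
        left[node] = new_node()
        right[node] = new_node()
        stack.append((left[node], idx[go_left], depth + 1))
        stack.append((right[node], idx[~go_left], depth + 1))

    tree = RegressionTree(feature, threshold, left, right, value)
    if return_train_pred:
        return tree, train_pred
    return tree


@dataclass
class BoostedModel:
    """A shrunk additive ensemble of regression trees."""

    trees: list[RegressionTree] = field(default_factory=list)
    shrinkage: float = DEFAULT_SHRINKAGE
    n_features: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Raw ensemble score ``sum_m eps * T_m(x)`` (no clipping)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.trees and X.shape[1] != self.n_features:
            raise ValueError(
                f"model expects {self.n_features} features, got {X.shape[1]}"
            )
        out = np.zeros(X.shape[0])
        for tree in self.trees:
            out += self.shrinkage * tree.predict(X)
        return out

    def to_dict(self) -> dict:
        return {
            "shrinkage": self.shrinkage,
            "n_features": self.n_features,
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BoostedModel":
        return cls(
            trees=[RegressionTree.from_dict(t) for t in payload["trees"]],
            shrinkage=payload["shrinkage"],
            n_features=payload["n_features"],
        )


def fit_boosted(
    X: np.ndarray,
    y: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
    n_trees: int = DEFAULT_N_TREES,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_leaf: int = DEFAULT_MIN_LEAF,
) -> BoostedModel:
    """Fit the boosted ensemble on binary 0/1 targets.

    Stagewise: tree ``m`` fits the residuals ``y - f_{m-1}(X)`` and the
    model advances by ``eps`` times its prediction, so the training loss is
    non-increasing in ``m``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D array")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("targets must be binary 0/1")
    model = BoostedModel(shrinkage=shrinkage, n_features=X.shape[1])
    f = np.zeros(X.shape[0])
    for _ in range(n_trees):
        tree, pred = fit_regression_tree(
            X, y - f, max_depth=max_depth, min_leaf=min_leaf, return_train_pred=True
        )
        f += shrinkage * pred
        model.trees.append(tree)
    return model


@dataclass
class BoostedModelPair:
    """Two ensembles trained on complementary balanced halves.

    ``model_a`` saw a random half of the pathogenic variants plus all
    neutral ones; ``model_b`` saw the complementary half plus all neutral
    ones.  A prediction is the mean of the two raw scores, clipped to
    [0, 1] for reporting.
    """

    model_a: BoostedModel
    model_b: BoostedModel
    split_seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        raw = 0.5 * (self.model_a.predict(X) + self.model_b.predict(X))
        return np.clip(raw, 0.0, 1.0)

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "truncvar-boosted-pair",
            "version": 1,
            "split_seed": self.split_seed,
            "model_a": self.model_a.to_dict(),
            "model_b": self.model_b.to_dict(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "BoostedModelPair":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "truncvar-boosted-pair":
            raise ValueError(f"{path}: not a boosted model pair file")
        return cls(
            model_a=BoostedModel.from_dict(payload["model_a"]),
            model_b=BoostedModel.from_dict(payload["model_b"]),
            split_seed=payload["split_seed"],
        )


def train_pair(
    features_pathogenic: np.ndarray,
    features_neutral: np.ndarray,
    seed: int = 0,
    hyperparams: Hyperparams | None = None,
) -> BoostedModelPair:
    """Train the dual balanced-model pair.

    The pathogenic rows are permuted with ``seed`` and split into halves of
    size ceil(n/2) and floor(n/2); each model trains on its half plus all
    neutral rows.  Deterministic given the seed.
    """
    hp = hyperparams or Hyperparams()
    Xp = np.atleast_2d(np.asarray(features_pathogenic, dtype=float))
    Xn = np.atleast_2d(np.asarray(features_neutral, dtype=float))
    if Xp.shape[0] == 0 or Xn.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(Xp.shape[0])
    half = -(-Xp.shape[0] // 2)  # ceil
    halves = (perm[:half], perm[half:])
    models = []
    for rows in halves:
        X = np.vstack([Xp[rows], Xn])
        y = np.concatenate([np.ones(rows.size), np.zeros(Xn.shape[0])])
        models.append(
            fit_boosted(
                X,
                y,
                shrinkage=hp.shrinkage,
                n_trees=hp.n_trees,
                max_depth=hp.max_depth,
                min_leaf=hp.min_leaf,
            )
        )
    return BoostedModelPair(model_a=models[0], model_b=models[1], split_seed=seed)


def predict_score(model: BoostedModel, x: np.ndarray) -> float:
    """Raw ensemble score of a single sample (no clipping)."""
    return float(model.predict(np.atleast_2d(x))[0])


def score_pair(pair: BoostedModelPair, x: np.ndarray) -> float:
    """Averaged pair score of a single sample, clipped to [0, 1]."""
    return float(pair.predict(np.atleast_2d(x))[0])
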