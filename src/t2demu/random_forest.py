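"""From-scratch multivariate regression CART and bagged random forest.

Trees make binary splits X_i <= c vs X_i > c chosen to minimise the total
within-child sum of squared errors pooled over the (standardized) outcome
components; leaves predict the mean outcome vector of their training rows.
The forest averages N trees, each grown on its own bootstrap resample with
``mtry`` candidate features per node.  The full tree structure (split
variable, threshold, depth, leaf means) is exposed so the depth-based
variable-importance analyses can traverse it, and serialises to nested JSON.

Splitting details: thresholds are midpoints between consecutive distinct
sorted feature values; ties in SSE break to the lowest feature index, then
the smallest threshold.  Pure nodes (all outcome rows identical) and nodes
with no valid split become leaves; zero-gain splits of impure nodes are
allowed, as in standard CART, so e.g. XOR-structured data is still fitted
exactly at depth 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .surrogate_models import Standardization

__all__ = [
    "TreeNode",
    "ForestParams",
    "Forest",
    "best_split",
    "grow_tree",
    "fit_forest",
    "predict_tree",
    "predict_forest",
    "forest_to_json",
    "forest_from_json",
]


@dataclass
class TreeNode:
    """Either an internal node (split_var/threshold/children) or a leaf (mu)."""

    depth: int
    n: int
    split_var: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    mu: np.ndarray | None = None   # leaf mean outcome vector

    @property
    def is_leaf(self) -> bool:
        return self.mu is not None


@dataclass(frozen=True)
class ForestParams:
    """Forest hyperparameters (defaults: 100 trees, mtry 3 ~ p/3, leaves >= 5)."""

    n_trees: int = 100
    mtry: int = 3
    min_leaf: int = 5
    max_depth: int | None = None
    bootstrap: bool = True


@dataclass
class Forest:
    trees: list[TreeNode]
    params: ForestParams
    seed: int
    y_stats: Standardization
    n_features: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _as_xy(X, Y) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return X, Y


def best_split(
    X: np.ndarray,
    Y: np.ndarray,
    features: Sequence[int] | None = None,
    min_leaf: int = 1,
) -> tuple[int, float, float] | None:
    """Exhaustive best binary split over the candidate features.

    Returns ``(feature, threshold, gain)`` minimising the summed within-child
    SSE over all outcome components, or ``None`` when the node is pure or no
    split leaves ``min_leaf`` rows on each side.  ``gain`` is parent SSE
    minus children SSE (can be 0 for an impure node, e.g. XOR data).
    """
    X, Y = _as_xy(X, Y)
    n = Y.shape[0]
    if n < 2 or n < 2 * min_leaf:
        return None
    if np.all(Y == Y[0]):
        return None  # pure node: every split has zero gain
    sse_parent = float(((Y - Y.mean(axis=0)) ** 2).sum())

    features = range(X.shape[1]) if features is None else sorted(features)
    best: tuple[float, int, float] | None = None  # (children_sse, var, thr)
    for f in features:
        xs_raw = X[:, f]
        order = np.argsort(xs_raw, kind="stable")
        xs = xs_raw[order]
        ys = Y[order]
        cum = np.cumsum(ys, axis=0)
        cumsq = np.cumsum((ys**2).sum(axis=1))
        total = cum[-1]
        total_sq = cumsq[-1]
        k = np.arange(1, n)  # left child takes the first k sorted rows
        valid = xs[1:] > xs[:-1]
        if min_leaf > 1:
            valid &= (k >= min_leaf) & (n - k >= min_leaf)
        if not valid.any():
            continue
        k = k[valid]
        sum_left = cum[k - 1]
        sse_left = cumsq[k - 1] - (sum_left**2).sum(axis=1) / k
        sum_right = total - sum_left
        sse_right = (total_sq - cumsq[k - 1]) - (sum_right**2).sum(axis=1) / (n - k)
        children = sse_left + sse_right
        i = int(np.argmin(children))  # first minimum -> smallest threshold
        if best is None or children[i] < best[0]:  # strict: lowest index wins ties
            thr = 0.5 * (xs[k[i] - 1] + xs[k[i]])
            best = (float(children[i]), int(f), float(thr))
    if best is None:
        return None
    children_sse, var, thr = best
    return var, thr, sse_parent - children_sse


def grow_tree(
    X: np.ndarray,
    Y: np.ndarray,
    rng: np.random.Generator | None = None,
    mtry: int | None = None,
    min_leaf: int = 1,
    max_depth: int | None = None,
    _depth: int = 0,
) -> TreeNode:
    """Recursively grow one regression tree.

    ``mtry`` candidate features are drawn without replacement at every node
    (all features when ``mtry`` is None or >= p).  Growth stops at pure
    nodes, ``min_leaf``, ``max_depth`` or when no valid split exists.
    Deterministic given the generator state.
    """
    X, Y = _as_xy(X, Y)
    n, p = X.shape

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node_y = Y[idx]
        if (
            len(idx) < 2
            or len(idx) < 2 * min_leaf
            or (max_depth is not None and depth >= max_depth)
        ):
            return TreeNode(depth=depth, n=len(idx), mu=node_y.mean(axis=0))
        if mtry is not None and mtry < p:
            features = np.sort(rng.choice(p, size=mtry, replace=False))
        else:
            features = None
        found = best_split(X[idx], node_y, features=features, min_leaf=min_leaf)
        if found is None:
            return TreeNode(depth=depth, n=len(idx), mu=node_y.mean(axis=0))
        var, thr, _gain = found
        mask = X[idx, var] <= thr
        node = TreeNode(depth=depth, n=len(idx), split_var=var, threshold=thr)
        node.left = build(idx[mask], depth + 1)
        node.right = build(idx[~mask], depth + 1)
        return node

    if mtry is not None and mtry < p and rng is None:
        raise ValueError("feature subsampling (mtry < p) requires an rng")
    return build(np.arange(n), _depth)


def fit_forest(
    X: np.ndarray,
    Y: np.ndarray,
    params: ForestParams | None = None,
    seed: int = 0,
) -> Forest:
    """Fit a bagged multivariate forest; reproducible per seed.

    Outputs are jointly z-scored by training statistics so the multivariate
    SSE weights each outcome equally; leaf means are stored in standardized
    units and de-standardized at prediction time.
    """
    X, Y = _as_xy(X, Y)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a forest")
    params = ForestParams() if params is None else params
    y_stats = Standardization.fit(Y)
    Yz = y_stats.transform(Y)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    trees = []
    for _ in range(params.n_trees):
        idx = rng.integers(0, n, size=n) if params.bootstrap else np.arange(n)
        trees.append(
            grow_tree(
                X[idx],
                Yz[idx],
                rng=rng,
                mtry=params.mtry,
                min_leaf=params.min_leaf,
                max_depth=params.max_depth,
            )
        )
    return Forest(
        trees=trees, params=params, seed=seed, y_stats=y_stats,
        n_features=X.shape[1],
    )


def predict_tree(tree: TreeNode, X: np.ndarray) -> np.ndarray:
    """Predictions of a single tree (in whatever units it was grown on)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    # discover output dimension from any leaf
    node = tree
    while not node.is_leaf:
        node = node.left
    q = len(node.mu)
    out = np.empty((X.shape[0], q))

    def descend(node: TreeNode, idx: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.mu
            return
        mask = X[idx, node.split_var] <= node.threshold
        descend(node.left, idx[mask])
        descend(node.right, idx[~mask])

    descend(tree, np.arange(X.shape[0]))
    return out


def predict_forest(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Unweighted mean of the per-tree leaf vectors, de-standardized."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    acc = np.zeros((X.shape[0], len(forest.y_stats.mean)))
    for tree in forest.trees:
        acc += predict_tree(tree, X)
    return forest.y_stats.inverse(acc / forest.n_trees)


def _node_to_dict(node: TreeNode) -> dict:
    if node.is_leaf:
        return {"mu": node.mu.tolist(), "n": node.n}
    return {
        "var": node.split_var,
        "thr": node.threshold,
        "left": _node_to_dict(node.left),
        "right": _node_to_dict(node.right),
        "n": node.n,
    }


def _node_from_dict(d: dict, depth: int = 0) -> TreeNode:
    if "mu" in d:
        return TreeNode(depth=depth, n=d["n"], mu=np.asarray(d["mu"], dtype=float))
    node = TreeNode(depth=depth, n=d["n"], split_var=d["var"], threshold=d["thr"])
    node.left = _node_from_dict(d["left"], depth + 1)
    node.right = _node_from_dict(d["right"], depth + 1)
    return node


def forest_to_json(forest: Forest, path) -> None:
    payload = {
        "params": {
            "n_trees": forest.params.n_trees,
            "mtry": forest.params.mtry,
            "min_leaf": forest.params.min_leaf,
            "max_depth": forest.params.max_depth,
            "bootstrap": forest.params.bootstrap,
        },
        "seed": forest.seed,
        "n_features": forest.n_features,
        "stats": {
            "y_mean": forest.y_stats.mean.tolist(),
            "y_sd": forest.y_stats.sd.tolist(),
        },
        "trees": [_node_to_dict(t) for t in forest.trees],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def forest_from_json(path) -> Forest:
    with open(path) as fh:
        d = json.load(fh)
    return Forest(
        trees=[_node_from_dict(t) for t in d["trees"]],
        params=ForestParams(**d["params"]),
        seed=d["seed"],
        y_stats=Standardization(
            np.asarray(d["stats"]["y_mean"]), np.asarray(d["stats"]["y_sd"])
        ),
        n_features=d["n_features"],
    )
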