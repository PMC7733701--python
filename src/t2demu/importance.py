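"""Variable-importance analyses on a fitted multivariate forest.

Three complementary views of which initial-condition factors drive the
6-month outcomes:

1. *Noising-up (permutation) importance* of a single predictor: the increase
   in standardized out-of-sample MSE when that predictor's column is
   randomly permuted, averaged over replicates, per output and pooled.
2. *Pairwise co-influence*: the same differencing with two columns permuted
   jointly (independent permutations).
3. *Minimal depth / maximal subtrees*: for each tree, the depth of the first
   split on a variable (smaller = more influential), and for ordered pairs
   (i, j) the depth of the first split on j inside the maximal i-subtrees.
   Depths are normalised per tree by (tree height + 1), so entries lie in
   [0, 1], with variables that never split mapping to 1; the 9 x 9 matrix is
   averaged over trees with equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .random_forest import Forest, TreeNode, predict_forest
from .surrogate_models import (
    IMPORTANCE_ORDER,
    PREDICTOR_NAMES,
    Standardization,
    standardized_mse,
)
from .synthetic_simulator import OUTCOME_NAMES

__all__ = [
    "ImportanceRecord",
    "DepthMatrix",
    "permutation_importance",
    "pairwise_importance",
    "importance_table",
    "pairwise_table",
    "minimal_depth",
    "tree_height",
    "maximal_subtrees",
    "depth_matrix",
]


@dataclass(frozen=True)
class ImportanceRecord:
    """Noising-up importance of a variable (or ordered variable pair)."""

    variables: tuple[int, ...]
    per_output: np.ndarray   # MSE increase per outcome component
    pooled: float            # MSE increase pooled over components
    n_reps: int


def _per_output_mse(Y, Y_hat, y_stats: Standardization) -> np.ndarray:
    z = (np.asarray(Y, float) - np.asarray(Y_hat, float)) / y_stats.sd
    return (z**2).mean(axis=0)


def _permute_and_score(
    forest: Forest,
    X: np.ndarray,
    Y: np.ndarray,
    variables: tuple[int, ...],
    rng: np.random.Generator,
    n_reps: int,
    y_stats: Standardization,
) -> ImportanceRecord:
    base_hat = predict_forest(forest, X)
    base_per = _per_output_mse(Y, base_hat, y_stats)
    base_pooled = standardized_mse(Y, base_hat, y_stats)
    per = np.zeros(Y.shape[1])
    pooled = 0.0
    n = X.shape[0]
    for _ in range(n_reps):
        Xp = X.copy()
        for v in variables:  # independent permutation per column
            Xp[:, v] = Xp[rng.permutation(n), v]
        hat = predict_forest(forest, Xp)
        per += _per_output_mse(Y, hat, y_stats) - base_per
        pooled += standardized_mse(Y, hat, y_stats) - base_pooled
    return ImportanceRecord(
        variables=variables,
        per_output=per / n_reps,
        pooled=pooled / n_reps,
        n_reps=n_reps,
    )


def permutation_importance(
    forest: Forest,
    X: np.ndarray,
    Y: np.ndarray,
    var: int,
    rng: np.random.Generator,
    n_reps: int = 5,
    y_stats: Standardization | None = None,
) -> ImportanceRecord:
    """Noising-up importance of one predictor by within-column permutation.

    A variable never used by any tree leaves predictions unchanged, so its
    importance is exactly zero.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    y_stats = forest.y_stats if y_stats is None else y_stats
    return _permute_and_score(forest, X, Y, (int(var),), rng, n_reps, y_stats)


def pairwise_importance(
    forest: Forest,
    X: np.ndarray,
    Y: np.ndarray,
    pair: tuple[int, int],
    rng: np.random.Generator,
    n_reps: int = 3,
    y_stats: Standardization | None = None,
) -> ImportanceRecord:
    """Joint noising-up importance of an ordered pair of distinct predictors."""
    i, j = int(pair[0]), int(pair[1])
    if i == j:
        raise ValueError("pairwise importance requires two distinct variables")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    y_stats = forest.y_stats if y_stats is None else y_stats
    return _permute_and_score(forest, X, Y, (i, j), rng, n_reps, y_stats)


def importance_table(
    forest: Forest,
    X: np.ndarray,
    Y: np.ndarray,
    seed: int = 0,
    n_reps: int = 5,
    y_stats: Standardization | None = None,
    names: Sequence[str] = PREDICTOR_NAMES,
) -> pd.DataFrame:
    """Single-variable importance for every predictor, one row per variable."""
    rng = np.random.default_rng(seed)
    rows = []
    for v, name in enumerate(names):
        rec = permutation_importance(forest, X, Y, v, rng, n_reps, y_stats)
        row = {"variable": name, "pooled": rec.pooled, "n_reps": rec.n_reps}
        for out_name, val in zip(OUTCOME_NAMES, rec.per_output):
            row[out_name] = val
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_table(
    forest: Forest,
    X: np.ndarray,
    Y: np.ndarray,
    seed: int = 0,
    n_reps: int = 3,
    y_stats: Standardization | None = None,
    names: Sequence[str] = PREDICTOR_NAMES,
) -> pd.DataFrame:
    """Joint importance of every unordered predictor pair, sorted by pooled
    importance (descending)."""
    rng = np.random.default_rng(seed)
    rows = []
    p = len(names)
    for i in range(p):
        for j in range(i + 1, p):
            rec = pairwise_importance(forest, X, Y, (i, j), rng, n_reps, y_stats)
            row = {
                "var_a": names[i],
                "var_b": names[j],
                "pooled": rec.pooled,
                "n_reps": rec.n_reps,
            }
            for out_name, val in zip(OUTCOME_NAMES, rec.per_output):
                row[out_name] = val
            rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("pooled", ascending=False, kind="stable").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# minimal depth and maximal subtrees
# ---------------------------------------------------------------------------


def tree_height(tree: TreeNode) -> int:
    """Maximum node depth (leaves included), with the root at depth 0."""
    if tree.is_leaf:
        return tree.depth
    return max(tree_height(tree.left), tree_height(tree.right))


def minimal_depth(tree: TreeNode, var: int) -> int:
    """Depth of the shallowest split on ``var`` (root = 0).

    Returns the sentinel ``tree height + 1`` when the variable never splits,
    so the normalised depth of an absent variable is 1.
    """
    sentinel = tree_height(tree) + 1

    def walk(node: TreeNode) -> int:
        if node.is_leaf:
            return sentinel
        if node.split_var == var:
            return node.depth
        return min(walk(node.left), walk(node.right))

    return walk(tree)


def maximal_subtrees(tree: TreeNode, var: int) -> list[TreeNode]:
    """Roots of the maximal ``var``-subtrees: nodes splitting on ``var`` with
    no ancestor splitting on ``var``."""
    roots: list[TreeNode] = []

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        if node.split_var == var:
            roots.append(node)
            return  # deeper var-splits are inside this subtree: not maximal
        walk(node.left)
        walk(node.right)

    walk(tree)
    return roots


def _min_depth_below(root: TreeNode, var: int) -> int | None:
    """Minimal depth of a split on ``var`` strictly below ``root``, measured
    from ``root`` (children are at distance 1); None when absent."""
    best: int | None = None

    def walk(node: TreeNode, dist: int) -> None:
        nonlocal best
        if node.is_leaf:
            return
        if dist > 0 and node.split_var == var:
            if best is None or dist < best:
                best = dist
            return
        walk(node.left, dist + 1)
        walk(node.right, dist + 1)

    walk(root, 0)
    return best


@dataclass(frozen=True)
class DepthMatrix:
    """Normalised minimal-depth matrix averaged over the trees of a forest.

    Diagonal (i, i): minimal depth of variable i from the tree root.
    Off-diagonal (i, j): minimal depth of j inside the maximal i-subtrees,
    measured from each subtree root and minimised over subtrees.  All entries
    normalised per tree by (height + 1) and averaged with equal tree weight;
    smaller means more influential.
    """

    values: np.ndarray
    names: tuple[str, ...]

    def to_frame(self, order: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.names, columns=self.names)
        if order is not None:
            df = df.loc[list(order), list(order)]
        return df


def depth_matrix(
    forest: Forest | Iterable[TreeNode],
    n_features: int | None = None,
    names: Sequence[str] | None = None,
) -> DepthMatrix:
    """Compute the p x p normalised minimal-depth matrix of a forest."""
    if isinstance(forest, Forest):
        trees: list[TreeNode] = forest.trees
        p = forest.n_features if n_features is None else n_features
    else:
        trees = list(forest)
        if n_features is None:
            raise ValueError("n_features is required when passing raw trees")
        p = n_features
    if names is None:
        names = PREDICTOR_NAMES if p == len(PREDICTOR_NAMES) else tuple(
            f"x{i}" for i in range(p)
        )
    M = np.zeros((p, p))
    for tree in trees:
        norm = tree_height(tree) + 1
        for i in range(p):
            M[i, i] += min(minimal_depth(tree, i), norm) / norm
            roots = maximal_subtrees(tree, i)
            for j in range(p):
                if j == i:
                    continue
                dij = norm  # sentinel: j absent below every maximal i-subtree
                for r in roots:
                    d = _min_depth_below(r, j)
                    if d is not None:
                        dij = min(dij, d)
                M[i, j] += dij / norm
    M /= len(trees)
    return DepthMatrix(values=M, names=tuple(names))
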