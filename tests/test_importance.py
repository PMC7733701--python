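"""Permutation/pairwise importance, minimal depth, maximal subtrees."""

import numpy as np
import pytest

from t2demu.importance import (
    depth_matrix,
    maximal_subtrees,
    minimal_depth,
    pairwise_importance,
    permutation_importance,
    tree_height,
)
from t2demu.random_forest import ForestParams, TreeNode, fit_forest


def make_node(var=None, thr=None, left=None, right=None, mu=0.0, depth=0, n=1):
    if var is None:
        return TreeNode(depth=depth, n=n, mu=np.atleast_1d(np.asarray(mu, float)))
    node = TreeNode(depth=depth, n=n, split_var=var, threshold=thr)
    node.left = left
    node.right = right
    return node


def set_depths(node, depth=0):
    node.depth = depth
    if not node.is_leaf:
        set_depths(node.left, depth + 1)
        set_depths(node.right, depth + 1)
    return node


def random_tree(rng, p, max_depth=4, leaf_prob=0.35, depth=0):
    """Random binary tree over p features (structure only, for depth tests)."""
    if depth >= max_depth or rng.random() < leaf_prob:
        return make_node(mu=rng.normal(), depth=depth)
    return make_node(
        var=int(rng.integers(p)),
        thr=float(rng.normal()),
        left=random_tree(rng, p, max_depth, leaf_prob, depth + 1),
        right=random_tree(rng, p, max_depth, leaf_prob, depth + 1),
        depth=depth,
    )


def enumerate_nodes(tree):
    """(node, depth, ancestors') split-var list for every node, by BFS."""
    out = []
    queue = [(tree, [])]
    while queue:
        node, anc = queue.pop(0)
        out.append((node, anc))
        if not node.is_leaf:
            queue.append((node.left, anc + [node.split_var]))
            queue.append((node.right, anc + [node.split_var]))
    return out


def brute_minimal_depth(tree, var):
    depths = [n.depth for n, _ in enumerate_nodes(tree)
              if not n.is_leaf and n.split_var == var]
    if not depths:
        return tree_height(tree) + 1
    return min(depths)


def brute_depth_matrix_one_tree(tree, p):
    """Exhaustive single-tree depth matrix by full node enumeration."""
    nodes = enumerate_nodes(tree)
    h = max(n.depth for n, _ in nodes)
    norm = h + 1
    M = np.zeros((p, p))
    for i in range(p):
        M[i, i] = min(brute_minimal_depth(tree, i), norm) / norm
        roots = [n for n, anc in nodes
                 if not n.is_leaf and n.split_var == i and i not in anc]
        for j in range(p):
            if j == i:
                continue
            best = norm
            for r in roots:
                for n, _ in enumerate_nodes(r):
                    if not n.is_leaf and n.split_var == j and n.depth > r.depth:
                        best = min(best, n.depth - r.depth)
            M[i, j] = best / norm
    return M


class TestMinimalDepth:
    def test_root_split_has_depth_zero(self):
        tree = set_depths(make_node(0, 0.5, make_node(mu=0.0), make_node(mu=1.0)))
        assert minimal_depth(tree, 0) == 0

    def test_absent_variable_gets_sentinel_height_plus_one(self):
        tree = set_depths(make_node(0, 0.5, make_node(mu=0.0), make_node(mu=1.0)))
        assert tree_height(tree) == 1
        assert minimal_depth(tree, 3) == 2

    def test_hand_built_depth_three_tree(self):
        # var 2 first appears at depth 2 in the right-right branch
        tree = set_depths(
            make_node(
                0, 0.0,
                make_node(1, 0.0, make_node(mu=0), make_node(mu=1)),
                make_node(
                    1, 1.0,
                    make_node(2, 0.5,
                              make_node(mu=2),
                              make_node(0, 2.0, make_node(mu=3), make_node(mu=4))),
                    make_node(mu=5),
                ),
            )
        )
        assert minimal_depth(tree, 2) == 2
        assert minimal_depth(tree, 2) == brute_minimal_depth(tree, 2)

    def test_oracle_equivalence_on_random_trees(self):
        rng = np.random.default_rng(77)
        for _ in range(300):
            p = int(rng.integers(2, 5))
            tree = random_tree(rng, p)
            for var in range(p):
                assert minimal_depth(tree, var) == brute_minimal_depth(tree, var)


class TestDepthMatrix:
    def test_maximal_subtrees_exclude_nested_splits(self):
        # root splits on 0; a deeper 0-split is inside the maximal 0-subtree
        tree = set_depths(
            make_node(
                0, 0.0,
                make_node(0, -1.0, make_node(mu=0), make_node(mu=1)),
                make_node(mu=2),
            )
        )
        roots = maximal_subtrees(tree, 0)
        assert len(roots) == 1 and roots[0].depth == 0

    def test_single_tree_root_variable_diagonal_is_zero(self):
        tree = set_depths(make_node(0, 0.5, make_node(mu=0.0), make_node(mu=1.0)))
        M = depth_matrix([tree], n_features=2)
        assert M.values[0, 0] == 0.0
        assert M.values[1, 1] == 1.0  # absent variable normalises to 1

    def test_two_tree_hand_forest_against_oracle(self):
        rng = np.random.default_rng(5)
        trees = [random_tree(rng, 3, max_depth=3), random_tree(rng, 3, max_depth=3)]
        M = depth_matrix(trees, n_features=3).values
        expected = (
            brute_depth_matrix_one_tree(trees[0], 3)
            + brute_depth_matrix_one_tree(trees[1], 3)
        ) / 2
        assert M == pytest.approx(expected, abs=1e-12)

    def test_oracle_equivalence_on_random_trees(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            p = int(rng.integers(2, 5))
            tree = random_tree(rng, p)
            M = depth_matrix([tree], n_features=p).values
            assert M == pytest.approx(brute_depth_matrix_one_tree(tree, p),
                                      abs=1e-12)

    def test_entries_lie_in_unit_interval(self):
        rng = np.random.default_rng(8)
        trees = [random_tree(rng, 4) for _ in range(10)]
        M = depth_matrix(trees, n_features=4).values
        assert np.all(M >= 0.0) and np.all(M <= 1.0)

    def test_default_study_depth_ranking(self, default_study):
        """BMI0 splits shallowest; PA variables split deepest (diagonals)."""
        diag = np.diag(default_study.depth.to_numpy())
        names = list(default_study.depth.index)
        order = [names[i] for i in np.argsort(diag)]
        assert order[0] == "bmi0"
        assert set(order[-3:]) == {"n_pa", "d_pa", "i_pa"}


def irrelevant_variable_forest():
    """y depends only on x0; x1 varies but is never split (noise-free y)."""
    rng = np.random.default_rng(10)
    X = np.column_stack([
        rng.integers(0, 4, size=100).astype(float),
        rng.normal(size=100),
    ])
    Y = np.column_stack([X[:, 0], 2 * X[:, 0]])
    forest = fit_forest(
        X, Y, ForestParams(n_trees=10, mtry=2, min_leaf=1), seed=4
    )
    for tree in forest.trees:  # confirm x1 is indeed never used
        stack = [tree]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                assert node.split_var == 0
                stack += [node.left, node.right]
    return forest, X, Y


class TestPermutationImportance:
    def test_never_split_variable_has_exactly_zero_importance(self):
        forest, X, Y = irrelevant_variable_forest()
        rec = permutation_importance(
            forest, X, Y, var=1, rng=np.random.default_rng(0), n_reps=3
        )
        assert rec.pooled == 0.0
        assert np.all(rec.per_output == 0.0)

    def test_pair_of_never_split_variables_has_zero_importance(self):
        rng = np.random.default_rng(11)
        X = np.column_stack([
            rng.integers(0, 4, size=80).astype(float),
            rng.normal(size=80),
            rng.normal(size=80),
        ])
        Y = X[:, 0]
        forest = fit_forest(X, Y, ForestParams(n_trees=5, mtry=3, min_leaf=1),
                            seed=2)
        rec = pairwise_importance(
            forest, X, Y, (1, 2), rng=np.random.default_rng(1), n_reps=3
        )
        assert rec.pooled == 0.0

    def test_identical_pair_indices_rejected(self):
        forest, X, Y = irrelevant_variable_forest()
        with pytest.raises(ValueError, match="distinct"):
            pairwise_importance(forest, X, Y, (1, 1), np.random.default_rng(0))

    def test_dominant_planted_variable_ranks_first(self):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 5, size=(300, 3)).astype(float)
        Y = 10.0 * X[:, 0] + 0.5 * X[:, 1] + 0.1 * rng.normal(size=300)
        forest = fit_forest(X, Y, ForestParams(n_trees=20, mtry=2, min_leaf=2),
                            seed=3)
        pooled = [
            permutation_importance(
                forest, X, Y, v, np.random.default_rng(v), n_reps=5
            ).pooled
            for v in range(3)
        ]
        assert np.argmax(pooled) == 0

    def test_importance_stable_across_permutation_seeds(self):
        rng = np.random.default_rng(13)
        X = rng.integers(0, 5, size=(400, 2)).astype(float)
        Y = X[:, 0] + 0.2 * rng.normal(size=400)
        forest = fit_forest(X, Y, ForestParams(n_trees=20, mtry=1, min_leaf=2),
                            seed=6)
        n_reps = 20

        def run(seed):
            reps = []
            r = np.random.default_rng(seed)
            for _ in range(n_reps):
                reps.append(
                    permutation_importance(forest, X, Y, 0, r, n_reps=1).pooled
                )
            return np.mean(reps), np.std(reps, ddof=1) / np.sqrt(n_reps)

        m1, se1 = run(100)
        m2, se2 = run(200)
        assert abs(m1 - m2) <= 3 * np.hypot(se1, se2)

    def test_default_study_pooled_ranking(self, default_study):
        tab = default_study.importance_single.set_index("variable")
        assert tab["pooled"].idxmax() == "bmi0"

    def test_default_study_top_pairs_involve_bmi0_and_carb(self, default_study):
        top5 = default_study.importance_pairs.head(5)
        pairs = {frozenset((a, b)) for a, b in zip(top5["var_a"], top5["var_b"])}
        assert frozenset(("bmi0", "carb_mult")) in pairs

    def test_default_study_pair_importance_dominates_singles(self, default_study):
        """Jointly permuting a pair hurts at least as much as the worse single
        (up to Monte-Carlo error) -- reported as an empirical check."""
        singles = default_study.importance_single.set_index("variable")["pooled"]
        pairs = default_study.importance_pairs
        row = pairs[
            (pairs["var_a"] == "bmi0") & (pairs["var_b"] == "carb_mult")
        ].iloc[0]
        assert row["pooled"] >= max(singles["bmi0"], singles["carb_mult"]) - 0.05
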