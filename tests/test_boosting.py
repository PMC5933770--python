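"""From-scratch boosted-tree learner: split search, boosting recursion,
dual balanced-model protocol."""

import numpy as np
import pytest

from truncvar import (
    BoostedModel,
    Hyperparams,
    confusion,
    fit_boosted,
    fit_regression_tree,
    metrics,
    predict_score,
    score_pair,
    train_pair,
)


def brute_force_best_split(X, r, min_leaf=1):
    """Exhaustive split search: every feature, every midpoint threshold.

    Independent of the tree builder; ties break to lowest feature then
    lowest threshold, mirroring the documented convention.
    """
    n, F = X.shape
    best = None
    base = r.sum() ** 2 / n
    for f in range(F):
        values = np.unique(X[:, f])
        for a, b in zip(values[:-1], values[1:]):
            thr = (a + b) / 2
            mask = X[:, f] <= thr
            nl = mask.sum()
            if nl < min_leaf or n - nl < min_leaf:
                continue
            score = r[mask].sum() ** 2 / nl + r[~mask].sum() ** 2 / (n - nl)
            if best is None or score > best[0] + 1e-12:
                best = (score, f, thr)
    if best is None or best[0] <= base + 1e-12:
        return None
    return best[1], best[2]


class TestRegressionTree:
    def test_depth1_example_split(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        r = np.array([0.0, 0.0, 1.0, 1.0])
        tree = fit_regression_tree(X, r, max_depth=1)
        assert tree.feature[0] == 0 and tree.threshold[0] == pytest.approx(1.5)
        np.testing.assert_allclose(tree.predict(X), [0, 0, 1, 1])

    def test_constant_residuals_single_leaf(self):
        tree = fit_regression_tree(np.random.default_rng(0).normal(size=(10, 3)),
                                   np.full(10, 0.25), max_depth=8)
        assert tree.n_nodes == 1 and tree.value[0] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(8))
    def test_root_split_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 6, size=(20, 3)).astype(float)
        r = rng.normal(size=20)
        tree = fit_regression_tree(X, r, max_depth=1)
        expected = brute_force_best_split(X, r)
        if expected is None:
            assert tree.n_nodes == 1
        else:
            assert (tree.feature[0], tree.threshold[0]) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(4))
    def test_small_samples_fit_exactly_at_depth8(self, seed):
        # with n <= depth+1 samples even a chain of splits resolves every
        # sample, so the greedy tree reaches SSE = 0
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(9, 2))
        r = rng.normal(size=9)
        tree = fit_regression_tree(X, r, max_depth=8)
        assert ((tree.predict(X) - r) ** 2).sum() == pytest.approx(0.0, abs=1e-20)

    def test_depth_limit_respected(self):
        rng = np.random.default_rng(3)
        tree = fit_regression_tree(rng.normal(size=(200, 4)),
                                   rng.normal(size=200), max_depth=8)
        assert tree.depth <= 8

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        r = rng.normal(size=30)
        tree = fit_regression_tree(X, r, max_depth=8, min_leaf=5)
        leaf_sizes = []
        idx_stack = [(0, np.arange(30))]
        while idx_stack:
            node, idx = idx_stack.pop()
            if tree.feature[node] < 0:
                leaf_sizes.append(idx.size)
                continue
            m = X[idx, tree.feature[node]] <= tree.threshold[node]
            idx_stack.append((int(tree.left[node]), idx[m]))
            idx_stack.append((int(tree.right[node]), idx[~m]))
        assert min(leaf_sizes) >= 5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_regression_tree(np.empty((0, 2)), np.empty(0))


class TestBoosting:
    def test_all_ones_geometric_series(self):
        X = np.random.default_rng(0).normal(size=(12, 2))
        model = fit_boosted(X, np.ones(12), shrinkage=0.005, n_trees=2000)
        expected = 1 - (1 - 0.005) ** 2000
        np.testing.assert_allclose(model.predict(X), expected, atol=1e-12)

    def test_zero_trees_predicts_zero(self):
        X = np.ones((3, 2))
        model = fit_boosted(X, np.array([0.0, 1.0, 1.0]), n_trees=0)
        np.testing.assert_allclose(model.predict(X), 0.0)

    def test_single_tree_shrinkage(self):
        from truncvar.boosting import RegressionTree

        tree = RegressionTree([-1], [np.nan], [-1], [-1], [2.0])
        model = BoostedModel(trees=[tree], shrinkage=0.005, n_features=1)
        assert predict_score(model, np.array([0.0])) == pytest.approx(0.01)

    def test_nonbinary_targets_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_boosted(np.ones((3, 1)), np.array([0.0, 0.5, 1.0]))

    def test_training_loss_nonincreasing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        y = (rng.random(60) < 0.4).astype(float)
        model = fit_boosted(X, y, shrinkage=0.05, n_trees=40)
        f = np.zeros(60)
        losses = []
        for tree in model.trees:
            f += model.shrinkage * tree.predict(X)
            losses.append(((y - f) ** 2).sum())
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        y = (rng.random(50) < 0.5).astype(float)
        m1 = fit_boosted(X, y, shrinkage=0.1, n_trees=15)
        perm = rng.permutation(50)
        m2 = fit_boosted(X[perm], y[perm], shrinkage=0.1, n_trees=15)
        grid = rng.normal(size=(25, 4))
        np.testing.assert_array_equal(m1.predict(grid), m2.predict(grid))

    def test_dimension_mismatch_rejected(self):
        model = fit_boosted(np.ones((4, 3)), np.array([0.0, 1, 0, 1]), n_trees=2)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.ones((2, 5)))


class TestModelPair:
    def _data(self, n_path=10, n_neu=8, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n_path, 3)), rng.normal(size=(n_neu, 3))

    @pytest.mark.parametrize("n_path,sizes", [(10, (5, 5)), (11, (6, 5))])
    def test_halves_are_complementary_with_ceil_convention(self, n_path, sizes):
        # reconstruct the documented split (seeded permutation, ceil/floor
        # halves) and check each ensemble matches a model trained on its
        # half plus all neutrals
        Xp, Xn = self._data(n_path=n_path)
        hp = Hyperparams(n_trees=3, shrinkage=0.1)
        pair = train_pair(Xp, Xn, seed=0, hyperparams=hp)
        perm = np.random.default_rng(0).permutation(n_path)
        half_a, half_b = perm[: sizes[0]], perm[sizes[0]:]
        assert len(half_a) == sizes[0] and len(half_b) == sizes[1]
        assert sorted(np.r_[half_a, half_b]) == list(range(n_path))
        grid = np.random.default_rng(1).normal(size=(15, 3))
        for rows, model in ((half_a, pair.model_a), (half_b, pair.model_b)):
            X = np.vstack([Xp[rows], Xn])
            y = np.r_[np.ones(len(rows)), np.zeros(len(Xn))]
            manual = fit_boosted(X, y, shrinkage=0.1, n_trees=3)
            np.testing.assert_array_equal(model.predict(grid), manual.predict(grid))

    def test_same_seed_reproduces_pair(self):
        Xp, Xn = self._data()
        hp = Hyperparams(n_trees=5, shrinkage=0.1)
        p1 = train_pair(Xp, Xn, seed=7, hyperparams=hp)
        p2 = train_pair(Xp, Xn, seed=7, hyperparams=hp)
        grid = np.random.default_rng(1).normal(size=(20, 3))
        np.testing.assert_array_equal(p1.predict(grid), p2.predict(grid))

    def test_empty_class_rejected(self):
        Xp, _ = self._data()
        with pytest.raises(ValueError, match="non-empty"):
            train_pair(Xp, np.empty((0, 3)))

    def test_score_is_clipped_mean(self):
        from truncvar.boosting import BoostedModelPair, RegressionTree

        def constant_model(v):
            tree = RegressionTree([-1], [np.nan], [-1], [-1], [v])
            return BoostedModel(trees=[tree], shrinkage=1.0, n_features=2)

        x = np.zeros(2)
        pair = BoostedModelPair(constant_model(0.2), constant_model(0.4), 0)
        assert score_pair(pair, x) == pytest.approx(0.3)
        pair_hi = BoostedModelPair(constant_model(1.1), constant_model(1.1), 0)
        assert score_pair(pair_hi, x) == 1.0

    def test_save_load_round_trip(self, tmp_path):
        Xp, Xn = self._data()
        pair = train_pair(Xp, Xn, seed=0, hyperparams=Hyperparams(n_trees=3,
                                                                  shrinkage=0.1))
        pair.save(tmp_path / "model.json")
        from truncvar import BoostedModelPair

        loaded = BoostedModelPair.load(tmp_path / "model.json")
        grid = np.random.default_rng(2).normal(size=(10, 3))
        np.testing.assert_array_equal(pair.predict(grid), loaded.predict(grid))

    def test_separable_toy_training_mcc_is_one(self):
        # linearly separable planted signal: with the full-protocol shrinkage
        # at 200 trees the pathogenic training scores pass 0.5 and the
        # neutral stay near 0
        rng = np.random.default_rng(9)
        Xp = rng.uniform(1.0, 2.0, size=(100, 3))
        Xn = rng.uniform(-2.0, -1.0, size=(100, 3))
        pair = train_pair(Xp, Xn, seed=0, hyperparams=Hyperparams(n_trees=200))
        scores = pair.predict(np.vstack([Xp, Xn]))
        labels = ["pathogenic"] * 100 + ["neutral"] * 100
        assert metrics(confusion(scores, labels, 0.5)).mcc == 1.0
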