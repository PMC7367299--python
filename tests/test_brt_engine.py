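"""Boosted regression tree engine: split search, boosting, interpretation."""

import numpy as np
import pytest

from phylobrt.brt_engine import (
    BRTConfig,
    fit_brt,
    fit_tree,
    interaction_strength,
    partial_dependence,
    percent_deviance_explained,
    variable_importance,
)
from phylobrt.trait_table import CONTINUOUS, NOMINAL

from conftest import make_frame, naive_fit_tree_total_improvement


def total_improvement(tree):
    return sum(node.improvement for node in tree.split_nodes())


class TestFitTree:
    def test_step_function_single_split(self):
        n = 20
        x = np.concatenate([np.arange(10), np.arange(20, 30)]).astype(float)
        y = (x > 15).astype(float)
        frame = make_frame(x[:, None])
        tree = fit_tree(frame, y, BRTConfig(tree_complexity=1))
        (split,) = tree.split_nodes()
        assert 9 < split.threshold < 20
        assert sorted([split.left.value, split.right.value]) == [0.0, 1.0]
        assert split.improvement == pytest.approx(n / 4)

    def test_constant_residuals_give_single_leaf(self):
        frame = make_frame(np.arange(8)[:, None].astype(float))
        tree = fit_tree(frame, np.full(8, 3.25), BRTConfig())
        assert tree.n_splits == 0
        assert tree.root.value == pytest.approx(3.25)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_exhaustive_search(self, seed):
        """Vectorised split search equals plain-arithmetic enumeration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        p = int(rng.integers(1, 4))
        kinds = [
            NOMINAL if rng.random() < 0.4 else CONTINUOUS for _ in range(p)
        ]
        X = np.empty((n, p))
        levels = {}
        for j, kind in enumerate(kinds):
            if kind == NOMINAL:
                n_lev = int(rng.integers(2, 5))
                X[:, j] = rng.integers(n_lev, size=n)
                levels[j] = list(range(n_lev))
            else:
                X[:, j] = rng.normal(size=n)
        r = rng.normal(size=n)
        frame = make_frame(X, kinds=kinds, levels=levels)
        config = BRTConfig(tree_complexity=2)
        tree = fit_tree(frame, r, config)
        n_levels = [len(levels.get(j, ())) for j in range(p)]
        expected = naive_fit_tree_total_improvement(X, kinds, n_levels, r, 2)
        assert total_improvement(tree) == pytest.approx(expected, rel=1e-9)

    def test_nominal_subset_split(self, rng):
        codes = rng.integers(4, size=40).astype(float)
        y = np.isin(codes, [1, 3]).astype(float)
        frame = make_frame(
            codes[:, None], kinds=[NOMINAL], levels={0: list(range(4))}
        )
        tree = fit_tree(frame, y, BRTConfig(tree_complexity=1))
        (split,) = tree.split_nodes()
        sides = {frozenset(split.left_levels), frozenset({0, 1, 2, 3}) - frozenset(split.left_levels)}
        assert frozenset({1.0, 3.0}) in sides

    def test_missing_values_routed_to_heavier_child(self, rng):
        x = np.concatenate([np.zeros(10), np.ones(4), [np.nan] * 3])
        y = np.concatenate([np.zeros(10), np.ones(4), np.ones(3)])
        frame = make_frame(x[:, None])
        tree = fit_tree(frame, y, BRTConfig(tree_complexity=1))
        (split,) = tree.split_nodes()
        # left child (x=0) has 10 present rows vs 4: missing go left
        assert split.missing_left
        assert split.left.n == 13


class TestFitBrt:
    def linear_frame(self, n, seed, sigma=0.5, p_noise=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 1 + p_noise))
        y = 2.0 * X[:, 0] + rng.normal(0, sigma, n)
        return make_frame(X), y

    def test_unshrunk_boosting_interpolates(self):
        frame, y = self.linear_frame(50, 0, sigma=0.5)
        config = BRTConfig(
            learning_rate=1.0,
            bag_fraction=1.0,
            tree_complexity=49,
            max_trees=20,
            step_size=20,
        )
        model = fit_brt(frame, y, config, cv=False)
        rms = np.sqrt(np.mean((model.predict(frame.X) - y) ** 2))
        assert rms < 1e-6

    def test_training_deviance_non_increasing_without_bagging(self):
        frame, y = self.linear_frame(80, 1)
        config = BRTConfig(
            learning_rate=0.1, bag_fraction=1.0, max_trees=60, step_size=30
        )
        model = fit_brt(frame, y, config, cv=False)
        devs = [
            np.mean((model.predict(frame.X, n_trees=k) - y) ** 2)
            for k in range(0, 61, 5)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(devs[:-1], devs[1:]))

    @pytest.mark.parametrize("seed", range(5))
    def test_cv_model_beats_null_on_linear_signal(self, seed):
        """Holdout deviance under 40% of null with a 2x + noise signal."""
        frame, y = self.linear_frame(200, seed)
        config = BRTConfig(
            learning_rate=0.1,
            max_trees=300,
            step_size=50,
            n_folds=5,
            rng_seed=seed,
        )
        model = fit_brt(frame, y, config)
        assert model.cv_deviance < 0.4 * model.null_deviance

    def test_cv_deviance_percent_near_analytic_noise_floor(self):
        """CV percent deviance within 10 points of 1 - sigma^2/var(y)."""
        for seed in range(5):
            frame, y = self.linear_frame(200, seed)
            config = BRTConfig(
                learning_rate=0.1, max_trees=300, step_size=50, n_folds=5,
                rng_seed=seed,
            )
            model = fit_brt(frame, y, config)
            pct = percent_deviance_explained(model, mode="cv")
            floor = 100 * (1 - 0.25 / np.var(y))
            assert abs(pct - floor) < 10

    def test_degenerate_response_rejected(self):
        frame, _ = self.linear_frame(20, 0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_brt(frame, np.ones(20), BRTConfig(max_trees=10, step_size=10))

    def test_reproducible_given_seed(self):
        frame, y = self.linear_frame(60, 3)
        config = BRTConfig(
            learning_rate=0.1, max_trees=100, step_size=25, n_folds=4,
            rng_seed=7,
        )
        m1 = fit_brt(frame, y, config)
        m2 = fit_brt(frame, y, config)
        np.testing.assert_array_equal(m1.predict(frame.X), m2.predict(frame.X))
        assert variable_importance(m1).equals(variable_importance(m2))
        np.testing.assert_array_equal(m1.cv_trace, m2.cv_trace)

    def test_shrinkage_consistency(self):
        """Halving the learning rate with double the trees barely moves fits."""
        frame, y = self.linear_frame(150, 5)
        preds = {}
        for lr, n_trees in [(0.1, 200), (0.05, 400)]:
            config = BRTConfig(
                learning_rate=lr, bag_fraction=1.0, max_trees=n_trees,
                step_size=n_trees,
            )
            model = fit_brt(frame, y, config, cv=False)
            preds[lr] = model.predict(frame.X)
        rms_diff = np.sqrt(np.mean((preds[0.1] - preds[0.05]) ** 2))
        rms_scale = np.sqrt(np.mean(preds[0.1] ** 2))
        assert rms_diff < 0.05 * rms_scale

    def test_matches_sklearn_gradient_boosting(self):
        """Cross-implementation check against an established library."""
        ensemble = pytest.importorskip("sklearn.ensemble")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 3))
        y = X[:, 0] - 2 * X[:, 1] ** 2 + rng.normal(0, 0.3, 120)
        frame = make_frame(X)
        config = BRTConfig(
            learning_rate=0.1, tree_complexity=1, bag_fraction=1.0,
            max_trees=150, step_size=150,
        )
        ours = fit_brt(frame, y, config, cv=False).predict(X)
        ref = ensemble.GradientBoostingRegressor(
            learning_rate=0.1, n_estimators=150, max_depth=1, random_state=0,
        ).fit(X, y).predict(X)
        assert np.corrcoef(ours, ref)[0, 1] > 0.99


class TestVariableImportance:
    def fitted(self, seed=0, p_noise=3, n=100):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 1 + p_noise))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.3, n)
        frame = make_frame(X)
        config = BRTConfig(
            learning_rate=0.1, max_trees=100, step_size=50, n_folds=4,
            rng_seed=seed,
        )
        return frame, y, fit_brt(frame, y, config)

    def test_sums_to_100(self):
        _, _, model = self.fitted()
        assert variable_importance(model).sum() == pytest.approx(100, abs=1e-9)

    def test_unused_predictor_scores_zero(self):
        x = np.linspace(0, 1, 40)
        frame = make_frame(np.column_stack([x, np.full(40, 7.0)]))
        y = (x > 0.5).astype(float)
        config = BRTConfig(
            learning_rate=0.5, max_trees=20, step_size=10, n_folds=4
        )
        model = fit_brt(frame, y, config)
        vi = variable_importance(model)
        assert vi["x1"] == 0.0
        assert vi["x0"] == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_single_informative_predictor_dominates(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(300, 11))
        y = 3.0 * X[:, 4] + rng.normal(0, 0.3, 300)
        frame = make_frame(X)
        config = BRTConfig(
            learning_rate=0.1, max_trees=150, step_size=50, n_folds=5,
            rng_seed=seed,
        )
        vi = variable_importance(fit_brt(frame, y, config))
        # strong signal: the informative column takes > 80% in most seeds
        if seed < 4:
            assert vi["x4"] > 80

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 3))
        y = X[:, 0] + 0.5 * X[:, 2] + rng.normal(0, 0.2, 80)
        config = BRTConfig(
            learning_rate=0.1, bag_fraction=1.0, max_trees=80, step_size=40,
            n_folds=4, rng_seed=1,
        )
        vi1 = variable_importance(fit_brt(make_frame(X), y, config))
        perm = [2, 0, 1]
        frame2 = make_frame(X[:, perm])
        vi2 = variable_importance(fit_brt(frame2, y, config))
        for new_j, old_j in enumerate(perm):
            assert vi2[f"x{new_j}"] == pytest.approx(
                vi1[f"x{old_j}"], abs=1e-9
            )


class TestDevianceExplained:
    def test_perfect_training_fit_is_100(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 1))
        y = np.sign(X[:, 0])
        frame = make_frame(X)
        config = BRTConfig(
            learning_rate=1.0, bag_fraction=1.0, tree_complexity=49,
            max_trees=20, step_size=20,
        )
        model = fit_brt(frame, y, config, cv=False)
        assert percent_deviance_explained(model, mode="training") == pytest.approx(
            100, abs=1e-6
        )

    def test_intercept_only_model_is_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 1))
        y = rng.normal(size=30)
        frame = make_frame(X)
        config = BRTConfig(max_trees=10, step_size=10)
        model = fit_brt(frame, y, config, cv=False)
        model.selected_n_trees = 0
        assert percent_deviance_explained(model, mode="training") == pytest.approx(0)


class TestPartialDependence:
    def additive_model(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-2, 2, size=(n, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + rng.normal(0, 0.1, n)
        frame = make_frame(X)
        config = BRTConfig(
            learning_rate=0.05, bag_fraction=1.0, max_trees=1200,
            step_size=1200, rng_seed=seed,
        )
        return fit_brt(frame, y, config, cv=False)

    def test_unused_predictor_gives_flat_curve(self):
        x = np.linspace(0, 1, 60)
        frame = make_frame(np.column_stack([x, np.zeros(60)]))
        y = (x > 0.5).astype(float)
        config = BRTConfig(
            learning_rate=0.5, max_trees=20, step_size=20, bag_fraction=1.0
        )
        model = fit_brt(frame, y, config, cv=False)
        curve = partial_dependence(model, "x1", grid=[0.0])
        flat = partial_dependence(model, "x0")
        assert curve.shape[0] == 1
        assert np.ptp(partial_dependence(model, "x1", grid=[-1, 0, 1])["prediction"]) == 0
        assert np.ptp(flat["prediction"]) > 0

    def test_additive_components_recovered_after_centering(self):
        model = self.additive_model()
        for col, truth in [("x0", np.sin), ("x1", lambda g: 0.5 * g)]:
            curve = partial_dependence(model, col)
            grid = curve[col].to_numpy()
            inner = (grid > -1.8) & (grid < 1.8)  # edges are data-sparse
            pred = curve["prediction"].to_numpy()[inner]
            target = truth(grid[inner])
            dev = (pred - pred.mean()) - (target - target.mean())
            assert np.max(np.abs(dev)) < 0.1

    def test_nominal_curve_has_one_point_per_level(self, rng):
        codes = rng.integers(10, size=200).astype(float)
        y = (codes % 3).astype(float) + rng.normal(0, 0.1, 200)
        frame = make_frame(
            codes[:, None], kinds=[NOMINAL], levels={0: [f"h{i}" for i in range(10)]}
        )
        config = BRTConfig(
            learning_rate=0.3, max_trees=60, step_size=30, n_folds=4
        )
        model = fit_brt(frame, y, config)
        curve = partial_dependence(model, "x0")
        assert curve.shape[0] == 10
        assert list(curve["x0"]) == [f"h{i}" for i in range(10)]

    def test_nominal_grid_outside_levels_rejected(self, rng):
        codes = rng.integers(3, size=50).astype(float)
        frame = make_frame(
            codes[:, None], kinds=[NOMINAL], levels={0: ["a", "b", "c"]}
        )
        y = codes + rng.normal(0, 0.1, 50)
        config = BRTConfig(learning_rate=0.3, max_trees=20, step_size=20)
        model = fit_brt(frame, y, config, cv=False)
        with pytest.raises(ValueError, match="level set"):
            partial_dependence(model, "x0", grid=[5])


class TestInteractionStrength:
    def fit(self, y_fn, seed=0, n=500):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, 3))
        y = y_fn(X) + rng.normal(0, 0.1, n)
        frame = make_frame(X)
        config = BRTConfig(
            learning_rate=0.1, bag_fraction=1.0, tree_complexity=3,
            max_trees=200, step_size=200, rng_seed=seed,
        )
        return fit_brt(frame, y, config, cv=False), y

    def test_additive_truth_gives_near_zero_strength(self):
        model, y = self.fit(lambda X: np.sin(2 * X[:, 0]) + X[:, 1])
        s = interaction_strength(model, "x0", "x1")
        assert s < 0.05 * np.var(y)

    def test_multiplicative_truth_ranks_true_pair_first(self):
        model, _ = self.fit(lambda X: 2 * X[:, 0] * X[:, 1])
        pairs = {
            (a, b): interaction_strength(model, a, b)
            for a, b in [("x0", "x1"), ("x0", "x2"), ("x1", "x2")]
        }
        assert max(pairs, key=pairs.get) == ("x0", "x1")

    def test_absent_predictor_gives_zero(self):
        x = np.linspace(0, 1, 50)
        frame = make_frame(np.column_stack([x, np.zeros(50)]))
        y = (x > 0.5).astype(float)
        config = BRTConfig(learning_rate=0.5, max_trees=10, step_size=10)
        model = fit_brt(frame, y, config, cv=False)
        assert interaction_strength(model, "x0", "x1") == 0.0
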