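"""Boosted-tree engine: tree growth vs an exhaustive oracle, boosting
invariants, relative influence, partial dependence."""

import numpy as np
import pandas as pd
import pytest

from lakehealth.boosting import (BoostedModel, GBMConfig, fit_gbm, fit_tree,
                                 partial_dependence, relative_influence)
from lakehealth.errors import ConfigurationError, ValidationError


# --- exhaustive greedy oracle (plain loops, no shared code paths) ----------

def _sse(vals):
    vals = np.asarray(vals, dtype=float)
    return float(np.sum((vals - vals.mean()) ** 2)) if len(vals) else 0.0


def oracle_best_split(X, r, rows, min_node):
    """Scan every (variable, midpoint) candidate; ties resolve to the lowest
    variable index, then the lowest threshold."""
    best = None
    parent = _sse(r[rows])
    for j in range(X.shape[1]):
        xs = sorted(set(X[i, j] for i in rows))
        for a, b in zip(xs, xs[1:]):
            thr = (a + b) / 2.0
            left = [i for i in rows if X[i, j] <= thr]
            right = [i for i in rows if X[i, j] > thr]
            if len(left) < min_node or len(right) < min_node:
                continue
            imp = parent - _sse(r[left]) - _sse(r[right])
            if imp > 1e-12 and (best is None or imp > best[2] + 1e-9):
                best = (j, thr, imp, left, right)
    return best


def oracle_tree_splits(X, r, depth, min_node):
    """Best-first growth by repeated exhaustive scan; returns the split list
    [(feature, threshold, improvement)] in growth order."""
    frontier = {0: list(range(len(r)))}
    splits = []
    next_id = 1
    for _ in range(depth):
        best_node, best = None, None
        for node, rows in frontier.items():
            cand = oracle_best_split(X, r, rows, min_node)
            if cand is not None and (best is None or cand[2] > best[2] + 1e-9):
                best_node, best = node, cand
        if best is None:
            break
        j, thr, imp, left, right = best
        splits.append((j, thr, imp))
        del frontier[best_node]
        frontier[next_id] = left
        frontier[next_id + 1] = right
        next_id += 2
    return splits


class TestFitTree:
    def test_constant_residuals_single_leaf(self):
        X = np.arange(10.0).reshape(-1, 1)
        r = np.full(10, 3.5)
        tree = fit_tree(X, r, depth=3, min_node=1)
        assert tree.n_splits == 0
        assert tree.value[0] == 3.5
        assert tree.improvement.sum() == 0.0

    def test_two_point_forced_stump(self):
        X = np.array([[0.0], [1.0]])
        r = np.array([0.0, 1.0])
        tree = fit_tree(X, r, depth=1, min_node=1)
        assert tree.n_splits == 1
        assert tree.threshold[0] == 0.5
        np.testing.assert_array_equal(tree.predict(X), [0.0, 1.0])

    def test_recovers_three_step_breakpoints(self):
        x = np.arange(20.0)
        y = np.select([x < 5, x < 12, x < 17], [0.0, 1.0, 3.0], 6.0)
        tree = fit_tree(x.reshape(-1, 1), y, depth=3, min_node=1)
        found = sorted(tree.threshold[tree.feature >= 0])
        assert found == [4.5, 11.5, 16.5]
        np.testing.assert_array_equal(tree.predict(x.reshape(-1, 1)), y)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        """On <=30-row instances the grown tree's split set and improvements
        equal the exhaustive greedy oracle's, and predictions agree."""
        rng = np.random.default_rng(seed)
        n, p = rng.integers(12, 31), rng.integers(1, 4)
        X = rng.normal(size=(n, p)).round(2)  # rounding induces ties
        y = rng.normal(size=n)
        tree = fit_tree(X, y, depth=3, min_node=2)
        expected = oracle_tree_splits(X, y, depth=3, min_node=2)
        got = [(int(f), float(t), float(i)) for f, t, i in zip(
            tree.feature[tree.feature >= 0],
            tree.threshold[tree.feature >= 0],
            tree.improvement[tree.feature >= 0])]
        assert len(got) == len(expected)
        for (jf, jt, ji), (of, ot, oi) in zip(sorted(got), sorted(expected)):
            assert jf == of
            assert jt == pytest.approx(ot)
            assert ji == pytest.approx(oi, rel=1e-9)

    def test_min_node_respected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        tree = fit_tree(X, y, depth=5, min_node=10)
        counts = _leaf_counts(tree, X)
        assert all(c >= 10 for c in counts)


def _leaf_counts(tree, X):
    leaf_of = []
    for row in X:
        node = 0
        while tree.feature[node] >= 0:
            node = (tree.left[node] if row[tree.feature[node]] <= tree.threshold[node]
                    else tree.right[node])
        leaf_of.append(node)
    return list(pd.Series(leaf_of).value_counts())


@pytest.fixture(scope="module")
def small_fit():
    """A modest seeded fit with a known additive signal and a null column."""
    rng = np.random.default_rng(11)
    n = 150
    X = pd.DataFrame({
        "signal": rng.uniform(0, 10, n),
        "minor": rng.uniform(0, 1, n),
        "null": rng.normal(size=n),
    })
    y = np.where(X["signal"] > 5, 2.0, 0.0) + 0.3 * X["minor"] \
        + rng.normal(0, 0.2, n)
    cfg = GBMConfig(n_trees=300, interaction_depth=3, learning_rate=0.05,
                    min_node_size=5, seed=2)
    return X, y, fit_gbm(X, y, cfg)


class TestFitGbm:
    def test_constant_response_predicts_mean_everywhere(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = np.full(30, 4.2)
        model = fit_gbm(X, y, GBMConfig(n_trees=20, cv_folds=3, seed=0,
                                        min_node_size=2))
        np.testing.assert_allclose(model.predict(X, iterations=20), 4.2)
        assert model.train_curve[-1] == pytest.approx(0.0, abs=1e-20)

    def test_training_loss_monotone_without_subsampling(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(120, 3))
        y = np.sin(6 * X[:, 0]) + X[:, 1]
        cfg = GBMConfig(n_trees=150, bag_fraction=1.0, learning_rate=0.1,
                        min_node_size=5, seed=1)
        model = fit_gbm(X, y, cfg)
        assert np.all(np.diff(model.train_curve) <= 1e-12)

    def test_prediction_decomposition_per_iteration(self, small_fit):
        X, _, model = small_fit
        Xm = X.to_numpy()
        for m in (1, 5, 77, 300):
            delta = model.predict(X, iterations=m) - model.predict(
                X, iterations=m - 1)
            np.testing.assert_allclose(
                delta,
                model.config.learning_rate * model.trees[m - 1].predict(Xm),
                rtol=1e-10, atol=1e-12)

    def test_zero_iterations_returns_init(self, small_fit):
        X, y, model = small_fit
        np.testing.assert_allclose(model.predict(X, iterations=0), y.mean())

    def test_best_iteration_within_bounds(self, small_fit):
        _, _, model = small_fit
        assert 1 <= model.best_iteration <= model.config.n_trees
        assert len(model.cv_curve) == model.config.n_trees

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 2))
        y = X[:, 0] + rng.normal(0, 0.1, 60)
        cfg = GBMConfig(n_trees=30, seed=7, min_node_size=3)
        a = fit_gbm(X, y, cfg)
        b = fit_gbm(X, y, cfg)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        assert a.best_iteration == b.best_iteration

    def test_too_few_rows_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_gbm(np.zeros((3, 1)), np.zeros(3), GBMConfig(cv_folds=5))

    def test_missing_values_rejected(self):
        X = np.array([[1.0], [np.nan], [2.0], [3.0], [4.0]])
        with pytest.raises(ValidationError):
            fit_gbm(X, np.zeros(5), GBMConfig(n_trees=5))

    def test_serialization_roundtrip(self, small_fit, tmp_path):
        X, _, model = small_fit
        path = tmp_path / "model.json"
        model.to_json(path)
        back = BoostedModel.from_json(path)
        np.testing.assert_array_equal(model.predict(X), back.predict(X))
        assert back.best_iteration == model.best_iteration


class TestInfluence:
    def test_sums_to_one_hundred(self, small_fit):
        _, _, model = small_fit
        assert relative_influence(model).sum() == pytest.approx(100.0)
        assert (relative_influence(model) >= 0).all()

    def test_single_true_driver_takes_nearly_all_influence(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 100),
                          "b": rng.uniform(0, 1, 100)})
        y = np.where(X["a"] > 0.5, 1.0, 0.0)  # noiseless, depends on a only
        model = fit_gbm(X, y, GBMConfig(n_trees=50, learning_rate=0.2,
                                        bag_fraction=1.0, min_node_size=5,
                                        seed=0))
        assert relative_influence(model)["a"] > 99.0

    def test_null_predictor_influence_below_five_percent(self, small_fit):
        _, _, model = small_fit
        assert relative_influence(model)["null"] < 5.0

    def test_no_split_model_all_zero(self):
        X = np.arange(20.0).reshape(-1, 1)
        y = np.full(20, 1.0)
        model = fit_gbm(X, y, GBMConfig(n_trees=5, cv_folds=2,
                                        min_node_size=2, seed=0))
        assert relative_influence(model, up_to=5).sum() == 0.0


class TestPartialDependence:
    def test_flat_for_variable_the_model_never_splits_on(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.uniform(0, 10, 80),
                          "ignored": np.zeros(80)})  # constant: unsplittable
        y = np.where(X["x"] > 4, 3.0, 1.0)
        model = fit_gbm(X, y, GBMConfig(n_trees=40, learning_rate=0.2,
                                        min_node_size=5, seed=0))
        out = partial_dependence(model, X, ["ignored"],
                                 grid=np.linspace(-5, 5, 11))
        assert out["partial_dependence"].std() == pytest.approx(0.0, abs=1e-9)

    def test_stump_model_pdp_equals_prediction_function(self):
        """For an ensemble of single-variable stumps, partial dependence on
        that variable reproduces the model's own 1-D prediction curve."""
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"x": rng.uniform(0, 10, 80)})
        y = np.where(X["x"] > 4, 3.0, 1.0) + rng.normal(0, 0.1, 80)
        model = fit_gbm(X, y, GBMConfig(n_trees=60, interaction_depth=1,
                                        learning_rate=0.2, bag_fraction=1.0,
                                        min_node_size=5, seed=0))
        grid = np.linspace(0.5, 9.5, 19)
        out = partial_dependence(model, X, ["x"], grid=grid)
        direct = model.predict(pd.DataFrame({"x": grid}))
        np.testing.assert_allclose(out["partial_dependence"], direct, rtol=1e-10)

    def test_threshold_component_recovered_in_pdp(self, abiotic_396):
        """Fitting an additive log-scale truth with a temperature ramp at
        16 degC, the 1-D partial dependence rises across the breakpoint by
        at least half the true component's rise over the same window."""
        from lakehealth.synthetic import ramp

        rng = np.random.default_rng(21)
        X = abiotic_396[["WTEMP", "pH", "TSS", "NOISE"]]
        true_comp = ramp(16.0, 26.0, 2.6)
        y = true_comp(X["WTEMP"].to_numpy()) + 0.4 * (X["pH"] - 8.42) \
            + rng.normal(0, 0.3, len(X))
        model = fit_gbm(X, y.to_numpy(), GBMConfig(
            n_trees=400, learning_rate=0.05, min_node_size=10, seed=3))
        grid = np.array([13.0, 16.0, 19.0, 22.0, 26.0])
        out = partial_dependence(model, X, ["WTEMP"], grid=grid)
        fitted_rise = (out["partial_dependence"].iloc[-1]
                       - out["partial_dependence"].iloc[0])
        true_rise = true_comp(np.array([26.0]))[0] - true_comp(np.array([13.0]))[0]
        assert fitted_rise >= 0.5 * true_rise

    def test_two_variable_grid_shape(self, small_fit):
        X, _, model = small_fit
        out = partial_dependence(model, X, ["signal", "minor"], grid_size=5)
        assert len(out) == 25
        assert set(out.columns) == {"signal", "minor", "partial_dependence"}

    def test_unknown_variable_rejected(self, small_fit):
        X, _, model = small_fit
        with pytest.raises(ConfigurationError):
            partial_dependence(model, X, ["absent"])
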