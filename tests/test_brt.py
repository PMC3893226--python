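"""Boosted-tree engine: CV tree selection, influence, partial dependence,
ensembles, and serialization."""

import numpy as np
import pandas as pd
import pytest

from reefscape import brt
from reefscape.brt import BRTConfig, BRTModel, _FrozenTree


def fast_config(**kw):
    base = dict(learning_rate=0.1, tree_complexity=2, bag_fraction=0.7,
                n_folds=3, step_size=10, max_trees=120, family="bernoulli",
                seed=0, patience=2)
    base.update(kw)
    return BRTConfig(**base)


@pytest.fixture
def separable(rng):
    x = rng.uniform(-3, 3, 300)
    X = pd.DataFrame({"x": x, "noise": rng.standard_normal(300)})
    y = (x > 0).astype(float)
    return X, y


class TestFitBrt:
    def test_constant_response_degenerate_base_rate(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(50)})
        with pytest.warns(UserWarning, match="constant response"):
            m = brt.fit_brt(X, np.ones(50), fast_config())
        assert m.degenerate
        assert m.optimal_n_trees == 0
        p = brt.predict_brt(m, X)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_perfectly_separable_predictor(self, separable):
        X, y = separable
        m = brt.fit_brt(X.iloc[:200], y[:200], fast_config())
        p = brt.predict_brt(m, X.iloc[200:])
        from reefscape.validation import roc_auc
        assert roc_auc(p, y[200:]).auc == 1.0
        infl = brt.relative_influence(m)
        assert infl["x"] > 99.0

    def test_cv_trace_minimum_is_selected_size(self, separable):
        X, y = separable
        m = brt.fit_brt(X, y, fast_config())
        k = int(np.argmin(m.cv_deviance))
        assert m.cv_steps[k] == m.optimal_n_trees
        assert m.optimal_n_trees <= m.config.max_trees

    def test_training_deviance_non_increasing(self, separable):
        X, y = separable
        m = brt.fit_brt(X, y, fast_config())
        assert np.all(np.diff(m.train_deviance) <= 1e-9)

    def test_deterministic_given_seed(self, separable):
        X, y = separable
        a = brt.fit_brt(X, y, fast_config(seed=5))
        b = brt.fit_brt(X, y, fast_config(seed=5))
        assert a.optimal_n_trees == b.optimal_n_trees
        np.testing.assert_array_equal(brt.predict_brt(a, X), brt.predict_brt(b, X))

    def test_poisson_family_on_counts(self, rng):
        x = rng.uniform(0, 1, 400)
        y = rng.poisson(np.exp(0.3 + 2.0 * x))
        X = pd.DataFrame({"x": x})
        m = brt.fit_brt(X, y, fast_config(family="poisson"))
        p = brt.predict_brt(m, X)
        assert np.all(p >= 0)
        # fitted mean rises with x
        assert p[x > 0.8].mean() > p[x < 0.2].mean()

    def test_invalid_inputs_rejected(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(30)})
        with pytest.raises(ValueError, match="0/1"):
            brt.fit_brt(X, np.arange(30.0), fast_config())
        with pytest.raises(ValueError, match="non-negative"):
            brt.fit_brt(X, -np.ones(30), fast_config(family="poisson"))
        with pytest.raises(ValueError, match="all-nodata"):
            brt.fit_brt(pd.DataFrame({"a": [np.nan] * 30}),
                        np.r_[np.zeros(15), np.ones(15)], fast_config())


class TestPredict:
    def _stump_model(self, intercept=0.3):
        cfg = fast_config(learning_rate=1.0)
        tree = _FrozenTree(left=[1, -1, -1], right=[2, -1, -1],
                           feature=[0, -2, -2], threshold=[5.0, -2.0, -2.0])
        m = BRTModel(config=cfg, feature_names=["x"], f0=intercept,
                     trees=[tree], leaf_values=[np.array([0.0, -1.0, 1.0])],
                     optimal_n_trees=1,
                     feature_means=np.array([5.0]), feature_mins=np.array([0.0]),
                     feature_maxs=np.array([10.0]))
        return m

    def test_single_stump_closed_form(self):
        # split at x < 5 with leaves -1/+1, learning rate 1, bernoulli:
        # prediction = logistic(intercept +/- 1)
        m = self._stump_model()
        p = brt.predict_brt(m, pd.DataFrame({"x": [2.0, 8.0]}))
        expit = lambda v: 1 / (1 + np.exp(-v))
        assert p[0] == pytest.approx(expit(0.3 - 1.0), abs=1e-12)
        assert p[1] == pytest.approx(expit(0.3 + 1.0), abs=1e-12)

    def test_bernoulli_output_in_unit_interval(self, separable):
        X, y = separable
        m = brt.fit_brt(X, y, fast_config())
        p = brt.predict_brt(m, X)
        assert np.all((p >= 0) & (p <= 1))

    def test_missing_feature_column_named(self, separable):
        X, y = separable
        m = brt.fit_brt(X, y, fast_config())
        with pytest.raises(ValueError, match="noise"):
            brt.predict_brt(m, X[["x"]])


class TestRelativeInfluence:
    def test_sums_to_100(self, separable):
        X, y = separable
        m = brt.fit_brt(X, y, fast_config())
        assert brt.relative_influence(m).sum() == pytest.approx(100.0, abs=1e-6)

    def test_stronger_predictor_dominates_and_matches_split_recomputation(self, rng):
        n = 500
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = 2.0 * x1 + 0.5 * x2 + 0.2 * rng.standard_normal(n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        m = brt.fit_brt(X, y, fast_config(family="gaussian"))
        infl = brt.relative_influence(m)
        assert infl["x1"] > infl["x2"]
        # brute-force recomputation from the stored split structures
        totals = np.zeros(2)
        for tree in m.trees[:m.optimal_n_trees]:
            t = tree.tree_
            for node in range(t.node_count):
                if t.children_left[node] == -1:
                    continue
                l, r = t.children_left[node], t.children_right[node]
                w, wl, wr = (t.weighted_n_node_samples[i] for i in (node, l, r))
                gain = w * t.impurity[node] - wl * t.impurity[l] - wr * t.impurity[r]
                totals[t.feature[node]] += gain / t.weighted_n_node_samples[0]
        want = totals / totals.sum() * 100
        assert infl["x1"] == pytest.approx(want[0], rel=1e-9)

    def test_degenerate_model_all_zero_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(40)})
        with pytest.warns(UserWarning):
            m = brt.fit_brt(X, np.zeros(40), fast_config())
        with pytest.warns(UserWarning, match="degenerate"):
            infl = brt.relative_influence(m)
        assert np.all(infl.to_numpy() == 0)


class TestPartialDependence:
    def test_ignored_predictor_gives_flat_curve(self, separable):
        X, y = separable
        m = brt.fit_brt(X, y, fast_config())
        curve = brt.partial_dependence(m, "noise", n_points=30)
        assert np.ptp(curve.response) <= 1e-6 or np.ptp(curve.response) < 0.02 * np.ptp(
            brt.partial_dependence(m, "x").response)

    def test_monotone_signal_gives_monotone_curve(self, rng):
        x = rng.uniform(0, 10, 400)
        X = pd.DataFrame({"x": x})
        y = (x > 5).astype(float)
        m = brt.fit_brt(X, y, fast_config())
        curve = brt.partial_dependence(m, "x", n_points=50)
        assert np.all(np.diff(curve.response) >= -1e-9)
        assert curve.grid[0] == pytest.approx(x.min())
        assert curve.grid[-1] == pytest.approx(x.max())

    def test_unknown_predictor_rejected(self, separable):
        X, y = separable
        m = brt.fit_brt(X, y, fast_config())
        with pytest.raises(ValueError, match="unknown predictor"):
            brt.partial_dependence(m, "bogus")


class TestEnsemble:
    def test_partition_property_per_replicate(self, separable):
        X, y = separable
        ens = brt.fit_ensemble(X, y, fast_config(), n_replicates=4)
        n = len(X)
        for tr, ho in zip(ens.train_indices, ens.holdout_indices):
            merged = np.sort(np.concatenate([tr, ho]))
            np.testing.assert_array_equal(merged, np.arange(n))
        assert len(ens.models) == 4

    def test_single_replicate_average_equals_member(self, separable):
        X, y = separable
        ens = brt.fit_ensemble(X, y, fast_config(), n_replicates=1)
        np.testing.assert_allclose(brt.predict_ensemble(ens, X),
                                   brt.predict_brt(ens.models[0], X), atol=1e-14)

    def test_ensemble_mean_is_arithmetic_mean(self, separable):
        X, y = separable
        ens = brt.fit_ensemble(X, y, fast_config(), n_replicates=3)
        stacked = np.stack([brt.predict_brt(m, X) for m in ens.models])
        np.testing.assert_allclose(brt.predict_ensemble(ens, X),
                                   stacked.mean(axis=0), atol=1e-12)

    def test_raster_prediction_matches_per_member_mean(self, rng):
        from reefscape import terrain
        from reefscape.grids import BathymetryGrid

        depth = 40 + np.tile(np.linspace(0, 20, 30), (20, 1)) \
            + 0.5 * rng.standard_normal((20, 30))
        grid = BathymetryGrid(depth=depth, cell_size=2.0)
        stack = terrain.build_predictor_stack(grid, surfaces=("depth", "depth_sd"),
                                              radii=(4.0, 8.0))
        X = pd.DataFrame({n: l.ravel() for n, l in stack.layers.items()})
        y = (X["depth@4"] > 50).astype(float).to_numpy()
        ens = brt.fit_ensemble(X, y, fast_config(), n_replicates=3)
        raster = brt.predict_ensemble_raster(ens, stack)
        members = np.stack([brt.predict_brt(m, X).reshape(grid.shape)
                            for m in ens.models])
        np.testing.assert_allclose(raster, members.mean(axis=0), atol=1e-12)


class TestSerialization:
    def test_round_trip_preserves_predictions_and_influence(self, separable):
        import json

        X, y = separable
        m = brt.fit_brt(X, y, fast_config())
        d = json.loads(json.dumps(brt.model_to_dict(m)))
        m2 = brt.model_from_dict(d)
        np.testing.assert_allclose(brt.predict_brt(m2, X), brt.predict_brt(m, X),
                                   atol=1e-12)
        pd.testing.assert_series_equal(brt.relative_influence(m2),
                                       brt.relative_influence(m), atol=1e-9)
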