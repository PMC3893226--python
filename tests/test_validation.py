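"""Validation metrics against hand computations and brute-force oracles."""

import numpy as np
import pytest

from reefscape import validation

import oracles


class TestRocAuc:
    def test_perfect_separation(self):
        r = validation.roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_hand_counted_example(self):
        # positives {0.9, 0.8, 0.7}, negatives {0.75, 0.6}: 5 of 6 pairs concordant
        scores = [0.9, 0.8, 0.7, 0.75, 0.6]
        labels = [1, 1, 1, 0, 0]
        r = validation.roc_auc(scores, labels)
        assert r.auc == pytest.approx(5 / 6)

    def test_all_ties_give_half(self):
        r = validation.roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert r.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            validation.roc_auc([0.1, 0.9], [1, 1])

    def test_matches_concordance_oracle_on_random_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 50))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            got = validation.roc_auc(scores, labels).auc
            want = oracles.auc_concordance_oracle(scores, labels)
            assert got == pytest.approx(want, abs=1e-12)

    def test_curve_monotone_from_origin_to_one(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        r = validation.roc_auc(scores, labels)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)


class TestMulticlassAuc:
    def test_two_classes_reduce_to_binary(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        m = validation.multiclass_auc(scores, labels)
        b = validation.roc_auc(scores, labels)
        assert m.m == pytest.approx(b.auc, abs=1e-12)

    def test_four_classes_give_six_pairwise_entries(self, rng):
        scores = rng.random(40)
        labels = np.repeat([0, 1, 2, 3], 10)
        m = validation.multiclass_auc(scores, labels)
        assert len(m.pairwise) == 6

    def test_three_class_toy_matches_pairwise_concordance(self):
        scores = np.array([0.1, 0.2, 0.3, 0.35, 0.5, 0.55, 0.7, 0.9, 0.8])
        labels = np.repeat(["a", "b", "c"], 3)
        m = validation.multiclass_auc(scores, labels)
        for (ci, cj), auc in m.pairwise.items():
            mask = (labels == ci) | (labels == cj)
            want = oracles.auc_concordance_oracle(scores[mask],
                                                  (labels[mask] == cj).astype(int))
            assert auc == pytest.approx(want, abs=1e-12)
        assert m.m == pytest.approx(np.mean(list(m.pairwise.values())), abs=1e-12)

    def test_sparse_class_excluded_with_warning(self):
        scores = [0.1, 0.2, 0.3, 0.4, 0.9]
        labels = [0, 0, 1, 1, 2]  # class 2 has a single member
        with pytest.warns(UserWarning, match="excluded"):
            m = validation.multiclass_auc(scores, labels)
        assert (0, 1) in m.pairwise
        assert np.isnan(m.pairwise[(0, 2)])
        assert m.excluded_pairs == [(0, 2), (1, 2)]


class TestJenks:
    def test_two_well_separated_groups(self):
        c = validation.jenks_breaks([1, 2, 3, 10, 11, 12], k=2)
        assert 3 <= c.thresholds[0] < 10

    def test_single_class(self):
        c = validation.jenks_breaks([1.0, 2.0, 5.0], k=1)
        assert len(c.thresholds) == 0
        assert len(set(c.labels)) == 1

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            validation.jenks_breaks([1.0, 1.0, 2.0], k=3)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_dp_equals_exhaustive_optimum(self, k, rng):
        for _ in range(10):
            vals = np.round(rng.random(int(rng.integers(max(k + 1, 6), 13))) * 10, 1)
            if len(np.unique(vals)) < k:
                continue
            c = validation.jenks_breaks(vals, k=k)
            got = oracles.jenks_sse(vals, c.thresholds)
            want = oracles.jenks_exhaustive_oracle(vals, k)
            assert got == pytest.approx(want, abs=1e-9)

    def test_density_class_names_and_frequencies(self):
        vals = np.concatenate([np.zeros(50), np.full(30, 1.0), np.full(15, 3.0),
                               np.full(5, 8.0)])
        c = validation.jenks_breaks(vals, k=4)
        assert c.class_names == list(validation.DENSITY_CLASS_NAMES)
        assert sum(c.frequencies.values()) == pytest.approx(1.0)
        assert c.frequencies["absent_to_low"] == 0.5


class TestErrorMetrics:
    def test_perfect_prediction(self):
        em = validation.error_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert em.mae == 0.0 and em.rmse == 0.0
        assert all(c.endswith("le_mae") for c in em.residual_classes)

    def test_hand_computed_errors(self):
        em = validation.error_metrics([1.0, -1.0, 3.0], [0.0, 0.0, 0.0])
        assert em.mae == pytest.approx(5 / 3)
        assert em.rmse == pytest.approx(np.sqrt(11 / 3))

    def test_rmse_at_least_mae_universally(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 60))
            em = validation.error_metrics(rng.standard_normal(n),
                                          rng.standard_normal(n))
            assert em.rmse >= em.mae >= 0.0
            assert len(em.residual_classes) == n

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            validation.error_metrics([1.0, 2.0], [1.0])


class TestDetrend:
    def test_exact_quadratic_trend_removed(self, rng):
        xy = rng.uniform(0, 100, size=(60, 2))
        z = 2.0 + 0.1 * xy[:, 0] - 0.05 * xy[:, 1] + 0.002 * xy[:, 0] * xy[:, 1] \
            + 0.001 * xy[:, 0] ** 2
        res = validation.detrend_residuals(xy, z)
        assert np.max(np.abs(res)) < 1e-6 * np.ptp(z)

    def test_constant_field_gives_zero_residuals(self, rng):
        xy = rng.uniform(0, 100, size=(30, 2))
        res = validation.detrend_residuals(xy, np.full(30, 7.0))
        assert res == pytest.approx(0.0, abs=1e-9)

    def test_white_noise_variance_roughly_preserved(self, rng):
        xy = rng.uniform(0, 100, size=(300, 2))
        z = rng.standard_normal(300)
        res = validation.detrend_residuals(xy, z)
        assert res.var() == pytest.approx(z.var(), rel=0.10)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            validation.detrend_residuals(rng.random((5, 2)), np.arange(5.0))


class TestSemivariogram:
    def test_constant_residuals_give_zero(self, rng):
        xy = rng.uniform(0, 100, size=(20, 2))
        emp = validation.empirical_semivariogram(xy, np.full(20, 3.0), n_lags=5)
        assert np.nansum(emp[:, 1]) == 0.0

    def test_two_point_hand_value(self):
        emp = validation.empirical_semivariogram(np.array([[0.0, 0.0], [10.0, 0.0]]),
                                                 np.array([0.0, 2.0]), n_lags=1,
                                                 max_lag=20.0)
        assert emp[0, 1] == pytest.approx(2.0)  # (1/2) * 2^2 / 1 pair
        assert emp[0, 2] == 1

    def test_iid_noise_is_flat_at_the_variance(self, rng):
        xy = rng.uniform(0, 1000, size=(400, 2))
        z = rng.standard_normal(400)
        emp = validation.empirical_semivariogram(xy, z, n_lags=8)
        ok = emp[:, 2] > 30
        assert np.allclose(emp[ok, 1], 1.0, atol=0.35)

    def test_empty_bins_carry_zero_count(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [100.0, 0.0]])
        emp = validation.empirical_semivariogram(xy, np.array([0.0, 1.0, 2.0]),
                                                 n_lags=10, max_lag=100.0)
        assert (emp[:, 2] == 0).any()
        assert np.isnan(emp[emp[:, 2] == 0, 1]).all()


class TestSphericalFit:
    def test_noiseless_parameters_recovered(self):
        h = np.linspace(20, 600, 15)
        g = validation.spherical_model(h, 0.1, 1.0, 300.0)
        emp = np.column_stack([h, g, np.full(15, 200.0)])
        vg = validation.fit_spherical_variogram(emp)
        assert vg.nugget == pytest.approx(0.1, abs=1e-3)
        assert vg.partial_sill == pytest.approx(1.0, abs=1e-3)
        assert vg.range_m == pytest.approx(300.0, abs=0.3)
        assert not vg.flagged

    def test_pure_nugget_flagged(self, rng):
        h = np.linspace(20, 600, 12)
        emp = np.column_stack([h, np.full(12, 0.8), np.full(12, 100.0)])
        vg = validation.fit_spherical_variogram(emp)
        assert vg.flagged
        assert vg.partial_sill == pytest.approx(0.0, abs=1e-6)

    def test_too_few_bins_rejected(self):
        emp = np.array([[10.0, 0.5, 5.0], [20.0, 0.6, 5.0]])
        with pytest.raises(ValueError):
            validation.fit_spherical_variogram(emp)

    def test_model_evaluates_spherical_form(self):
        vg = validation.VariogramModel(nugget=0.1, partial_sill=1.0, range_m=300.0,
                                       empirical=np.empty((0, 3)))
        assert vg(0.0) == pytest.approx(0.1)
        assert vg(300.0) == pytest.approx(1.1)
        assert vg(1e4) == pytest.approx(1.1)
        assert vg(150.0) == pytest.approx(0.1 + 1.0 * (0.75 - 0.5 * 0.125))


class TestThinning:
    def test_empty_input(self):
        assert len(validation.thin_by_range(np.empty((0, 2)), 100.0)) == 0

    def test_collinear_left_to_right_greedy(self):
        pts = np.column_stack([np.arange(0, 700, 100.0), np.zeros(7)])
        kept = validation.thin_by_range(pts, 280.0, order=np.arange(7))
        assert pts[kept][:, 0].tolist() == [0.0, 300.0, 600.0]

    def test_postconditions_on_random_clouds(self, rng):
        for _ in range(10):
            pts = rng.uniform(0, 1000, size=(int(rng.integers(20, 120)), 2))
            r = float(rng.uniform(50, 400))
            kept = validation.thin_by_range(pts, r, seed=int(rng.integers(1000)))
            kxy = pts[kept]
            if len(kxy) > 1:
                d = np.sqrt(((kxy[:, None] - kxy[None]) ** 2).sum(-1))
                np.fill_diagonal(d, np.inf)
                assert d.min() >= r
            removed = np.setdiff1d(np.arange(len(pts)), kept)
            for i in removed:  # maximality: every removed point blocked by a kept one
                dd = np.sqrt(((kxy - pts[i]) ** 2).sum(-1))
                assert dd.min() < r

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            validation.thin_by_range(np.zeros((3, 2)), 0.0)


class TestLocalMorans:
    def test_constant_field_all_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        r = validation.local_morans(pts, np.full(4, 2.0), n_permutations=19)
        assert np.all(r.local_i == 0)
        assert set(r.labels) == {"not-significant"}

    def test_side_split_rectangle_hand_computation(self):
        # like values 1 m apart, unlike values 3 m away: positive local I everywhere
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [3.0, 1.0]])
        vals = np.array([5.0, 5.0, -5.0, -5.0])
        r = validation.local_morans(pts, vals, n_permutations=19)
        # hand: z = vals, m2 = 25; weights from d in {1, 3, sqrt(10)}
        w1, w3, wd = 1.0, 1 / 3, 1 / np.sqrt(10)
        s = w1 + w3 + wd
        lag0 = (w1 * 5 + w3 * -5 + wd * -5) / s
        assert r.local_i[0] == pytest.approx(5 * lag0 / 25, abs=1e-12)
        assert np.all(r.local_i > 0)

    def test_mean_local_equals_global_moran_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(25, 2))
        vals = rng.standard_normal(25)
        r = validation.local_morans(pts, vals, n_permutations=19)
        want = oracles.global_morans_oracle(pts, vals)
        assert np.mean(r.local_i) == pytest.approx(want, abs=1e-12)
        assert r.global_i == pytest.approx(want, abs=1e-12)

    def test_cluster_labels_on_strong_pattern(self, rng):
        # two well-separated value plateaus produce significant HH and LL points
        xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
        left = np.column_stack([xs.ravel(), ys.ravel()])
        right = left + [50.0, 0.0]
        pts = np.vstack([left, right])
        vals = np.r_[np.full(25, 10.0), np.full(25, -10.0)]
        vals += 0.1 * rng.standard_normal(50)
        r = validation.local_morans(pts, vals, n_permutations=199, seed=3)
        assert "HH" in r.labels and "LL" in r.labels
        assert not {"HL", "LH"} & set(r.labels)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            validation.local_morans(np.zeros((2, 2)), np.array([1.0, 2.0]))
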