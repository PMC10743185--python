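"""Ordered predictors selection: informative vectors and the three variants."""

import numpy as np
import pytest

from nirselect import (OPSConfig, SyntheticSpec, ValidationError, auto_ops,
                       band_coverage, feed_ops, generate_dataset, i_ops,
                       informative_vector, ops_run)
from nirselect.ops_select import VECTOR_KINDS, _prefix_sizes

FAST = OPSConfig(folds=5, increment=20, max_lv=6)


class TestInformativeVector:
    @pytest.mark.parametrize("kind", VECTOR_KINDS)
    def test_signal_column_ranked_first(self, kind):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 15))
            k = int(rng.integers(15))
            y = X[:, k] + 0.05 * rng.normal(size=40)
            v = informative_vector(X, y, kind, h=2)
            hits += int(v.ranking()[0]) == k
        assert hits >= 18

    def test_vip_sum_of_squares_identity(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        v = informative_vector(X, y, "VIP", h=4)
        np.testing.assert_allclose(np.sum(v.values**2), 12, rtol=1e-8)

    def test_cor_and_cov_on_y_column(self, rng):
        y = rng.normal(size=25)
        X = np.column_stack([y, rng.normal(size=25)])
        cor = informative_vector(X, y, "COR", h=1)
        cov = informative_vector(X, y, "COV", h=1)
        np.testing.assert_allclose(cor.values[0], 1.0, atol=1e-10)
        np.testing.assert_allclose(cov.values[0], np.var(y, ddof=1), atol=1e-10)

    def test_urxy_is_squared_correlation(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        urxy = informative_vector(X, y, "URXY", h=1).values
        for j in range(6):
            r = np.corrcoef(X[:, j], y)[0, 1]
            np.testing.assert_allclose(urxy[j], r**2, atol=1e-10)

    def test_zero_variance_column_scored_zero(self, rng):
        X = rng.normal(size=(15, 4))
        X[:, 2] = 7.0
        v = informative_vector(X, rng.normal(size=15), "COR", h=1)
        assert v.values[2] == 0.0

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValidationError, match="unknown"):
            informative_vector(np.ones((4, 2)), np.arange(4.0), "XYZ", h=1)


class TestOpsRun:
    def test_prefix_schedule_arithmetic(self):
        assert _prefix_sizes(20, 5, 5) == [5, 10, 15, 20]
        assert _prefix_sizes(22, 5, 5) == [5, 10, 15, 20, 22]
        assert _prefix_sizes(7, 7, 3) == [7]

    def test_planted_signal_beats_full_spectrum(self, rng):
        # only 10 of 60 variables carry signal
        X = rng.normal(size=(50, 60))
        beta = np.zeros(60)
        beta[20:30] = rng.normal(size=10)
        y = X @ beta + 0.2 * rng.normal(size=50)
        v = informative_vector(X, y, "COR", h=2)
        res = ops_run(X, y, v, window=5, increment=5, folds=5, h_model=5)
        full = res.subsets[-1]
        assert full.size == 60
        assert res.rmsecv <= full.rmsecv

    def test_degenerate_single_candidate(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        v = informative_vector(X, y, "COR", h=1)
        res = ops_run(X, y, v, window=8, increment=3, folds=4, h_model=2)
        assert len(res.subsets) == 1
        np.testing.assert_array_equal(res.chosen_indices, np.arange(8))

    def test_chosen_is_prefix_of_ranking(self, rng):
        X = rng.normal(size=(30, 20))
        y = X[:, 3] + 0.3 * rng.normal(size=30)
        v = informative_vector(X, y, "REG", h=2)
        res = ops_run(X, y, v, window=4, increment=4, folds=5, h_model=3)
        k = res.n_selected
        assert set(res.chosen_indices.tolist()) == set(res.ranking[:k].tolist())

    def test_chosen_minimizes_rmsecv_with_size_tie_break(self, rng):
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        v = informative_vector(X, y, "COV", h=2)
        res = ops_run(X, y, v, window=3, increment=3, folds=5, h_model=2)
        best = min(res.subsets, key=lambda s: (s.rmsecv, s.size))
        assert res.rmsecv == best.rmsecv
        assert res.n_selected == best.size


class TestAutoOps:
    def test_planted_band_recovered(self, small_spec, small_dataset):
        data, _ = small_dataset
        X = data.X - data.X.mean(0)
        res = auto_ops(X, data.y, FAST)
        assert band_coverage(res.chosen_indices, small_spec) >= 0.8

    def test_best_not_worse_than_each_vector_run(self, rng):
        X = rng.normal(size=(30, 25))
        y = X[:, 5] - X[:, 17] + 0.2 * rng.normal(size=30)
        cfg = OPSConfig(folds=5, window=5, increment=5, h_model=3, h_vector=3)
        res = auto_ops(X, y, cfg)
        assert all(res.rmsecv <= r for r in res.extras["per_vector_rmsecv"].values())

    def test_deterministic(self, rng):
        X = rng.normal(size=(28, 20))
        y = rng.normal(size=28)
        cfg = OPSConfig(folds=4, window=5, increment=5, h_model=2, h_vector=2)
        a = auto_ops(X, y, cfg)
        b = auto_ops(X, y, cfg)
        np.testing.assert_array_equal(a.chosen_indices, b.chosen_indices)
        assert a.vector_kind == b.vector_kind

    def test_indices_valid_sorted_unique(self, rng):
        X = rng.normal(size=(26, 18))
        y = X[:, 2] + 0.5 * rng.normal(size=26)
        cfg = OPSConfig(folds=4, window=4, increment=6, h_model=2, h_vector=2)
        res = auto_ops(X, y, cfg)
        idx = res.chosen_indices
        assert np.all(np.diff(idx) > 0)
        assert idx.min() >= 0 and idx.max() < 18


class TestFeedOps:
    def test_fixed_point_terminates(self, rng):
        X = rng.normal(size=(30, 15))
        y = X[:, 4] + 0.1 * rng.normal(size=30)
        cfg = OPSConfig(folds=5, window=5, increment=5, h_model=2, h_vector=2)
        res = feed_ops(X, y, cfg, max_rounds=6)
        rounds = res.extras["rounds"]
        assert 1 <= len(rounds) <= 6

    def test_subset_size_non_increasing(self, small_dataset):
        data, _ = small_dataset
        X = data.X - data.X.mean(0)
        res = feed_ops(X, data.y, FAST, max_rounds=4)
        sizes = [r.n_selected for r in res.extras["rounds"]]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_final_not_worse_than_round_one(self, small_dataset):
        data, _ = small_dataset
        X = data.X - data.X.mean(0)
        res = feed_ops(X, data.y, FAST, max_rounds=4)
        assert res.rmsecv <= res.extras["rounds"][0].rmsecv + 1e-12


class TestIOps:
    def test_final_subset_within_interval_union(self, small_dataset):
        data, _ = small_dataset
        X = data.X - data.X.mean(0)
        res = i_ops(X, data.y, 50, FAST)
        pool = np.unique(np.concatenate(res.extras["interval_picks"]))
        assert set(res.chosen_indices.tolist()) <= set(pool.tolist())

    def test_two_band_recovery(self):
        spec = SyntheticSpec(n_samples=80, n_points=200)
        hits = 0
        n_runs = 8
        for seed in range(n_runs):
            data, _ = generate_dataset(spec, seed=seed)
            X = data.X - data.X.mean(0)
            res = i_ops(X, data.y, 50, FAST)
            hits += band_coverage(res.chosen_indices, spec) >= 0.5
        assert hits >= 0.8 * n_runs

    def test_interval_equals_p_behaves_like_double_autoops(self, rng):
        X = rng.normal(size=(26, 12))
        y = X[:, 3] + 0.2 * rng.normal(size=26)
        cfg = OPSConfig(folds=4, window=4, increment=4, h_model=2, h_vector=2)
        res = i_ops(X, y, 12, cfg)
        first = auto_ops(X, y, cfg)
        second = auto_ops(X[:, first.chosen_indices], y, cfg)
        np.testing.assert_array_equal(
            res.chosen_indices, first.chosen_indices[second.chosen_indices])
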