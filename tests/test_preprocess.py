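"""Preprocessing operators against their one-line formula oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirselect import (PreprocessConfig, SpectraSet, ValidationError,
                       apply_pipeline, autoscale, mean_center, msc,
                       savitzky_golay, snv)


class TestMeanCenter:
    def test_constant_column_to_zero(self):
        X, stats = mean_center(np.array([[5.0], [5.0], [5.0]]))
        np.testing.assert_allclose(X, 0.0)
        np.testing.assert_allclose(stats, [5.0])

    def test_idempotent_on_centered(self, rng):
        X = rng.normal(size=(6, 3))
        Xc, _ = mean_center(X)
        Xcc, _ = mean_center(Xc)
        np.testing.assert_allclose(Xcc, Xc, atol=1e-12)

    def test_matches_oracle(self, rng):
        X = rng.normal(size=(8, 4))
        Xc, stats = mean_center(X)
        np.testing.assert_allclose(Xc, X - X.mean(0), atol=1e-12)
        assert np.abs(Xc.mean(0)).max() < 1e-10

    def test_stored_stats_replayed(self, rng):
        X = rng.normal(size=(5, 3))
        _, stats = mean_center(X)
        Xnew = rng.normal(size=(2, 3))
        Xc, _ = mean_center(Xnew, stats=stats)
        np.testing.assert_allclose(Xc, Xnew - X.mean(0))

    def test_stats_length_mismatch(self):
        with pytest.raises(ValidationError):
            mean_center(np.ones((2, 3)), stats=np.ones(2))


class TestAutoscale:
    def test_three_point_column(self):
        X, _ = autoscale(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(X.ravel(), [-1, 0, 1])

    def test_matches_zscore_oracle(self, rng):
        X = rng.normal(size=(10, 6))
        Xs, _ = autoscale(X)
        oracle = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(Xs, oracle, atol=1e-12)
        assert np.abs(Xs.mean(0)).max() < 1e-10
        np.testing.assert_allclose(Xs.std(0, ddof=1), 1.0, atol=1e-10)

    def test_stored_stats_reproduce_fit(self, rng):
        X = rng.normal(size=(7, 4))
        Xs, stats = autoscale(X)
        Xs2, _ = autoscale(X, stats=stats)
        np.testing.assert_allclose(Xs2, Xs)

    def test_zero_variance_column_named(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        with pytest.raises(ValidationError, match=r"\[1\]"):
            autoscale(X)


class TestSNV:
    def test_row_formula(self):
        out = snv(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1, 0, 1])

    def test_idempotence(self, rng):
        X = rng.normal(size=(4, 10))
        np.testing.assert_allclose(snv(snv(X)), snv(X), atol=1e-12)

    def test_matches_row_oracle(self, rng):
        X = rng.normal(size=(5, 20))
        out = snv(X)
        oracle = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        np.testing.assert_allclose(out, oracle, atol=1e-12)
        assert np.abs(out.mean(1)).max() < 1e-10
        np.testing.assert_allclose(out.std(1, ddof=1), 1.0, atol=1e-10)

    def test_constant_row_named(self):
        with pytest.raises(ValidationError, match=r"\[1\]"):
            snv(np.array([[1.0, 2.0], [3.0, 3.0]]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rows_standardized_property(self, seed):
        X = np.random.default_rng(seed).normal(size=(3, 12))
        out = snv(X)
        np.testing.assert_allclose(out.mean(1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(1, ddof=1), 1.0, atol=1e-10)


class TestMSC:
    def test_affine_distortions_removed(self, rng):
        r = np.sin(np.linspace(0, 3, 40)) + 2
        gains = np.array([0.5, 1.0, 2.0, 1.7])
        offsets = np.array([-0.3, 0.0, 0.4, 1.0])
        X = gains[:, None] * r + offsets[:, None]
        out, ref = msc(X, reference=r)
        np.testing.assert_allclose(out, np.tile(r, (4, 1)), atol=1e-8)

    def test_reference_unchanged(self):
        r = np.linspace(1, 2, 10)
        out, _ = msc(r[None, :], reference=r)
        np.testing.assert_allclose(out.ravel(), r, atol=1e-12)

    def test_coefficients_match_normal_equations(self, rng):
        X = rng.normal(size=(6, 30)) + 3
        ref = X.mean(0)
        out, _ = msc(X)
        A = np.column_stack([np.ones(30), ref])
        for i in range(6):
            a, b = np.linalg.lstsq(A, X[i], rcond=None)[0]
            np.testing.assert_allclose(out[i], (X[i] - a) / b, atol=1e-10)

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            msc(np.ones((2, 5)) + np.eye(2, 5), reference=np.ones(5))


class TestSavitzkyGolay:
    def test_polynomial_reproduced(self):
        x = np.arange(30.0)
        row = 2.0 + 0.5 * x + 0.1 * x**2
        out = savitzky_golay(row[None, :], window=7, polyorder=2, deriv=0)
        np.testing.assert_allclose(out.ravel(), row, atol=1e-9)

    def test_linear_ramp_derivative(self):
        row = 3.0 * np.arange(25.0)
        out = savitzky_golay(row[None, :], window=9, polyorder=2, deriv=1)
        np.testing.assert_allclose(out.ravel()[4:-4], 3.0, atol=1e-9)

    def test_derivative_matches_local_fit_oracle(self):
        x = np.linspace(0, 4 * np.pi, 120)
        row = np.sin(x)
        dx = x[1] - x[0]
        out = savitzky_golay(row[None, :], window=7, polyorder=2, deriv=1,
                             axis_spacing=dx)
        # brute-force: per-point quadratic least squares on the window
        for i in range(3, 117):
            t = (x[i - 3:i + 4] - x[i])
            coef = np.polynomial.polynomial.polyfit(t, row[i - 3:i + 4], 2)
            np.testing.assert_allclose(out[0, i], coef[1], atol=1e-10)

    def test_output_width_preserved(self, rng):
        X = rng.normal(size=(3, 50))
        assert savitzky_golay(X, 11, 2, 0).shape == X.shape

    @pytest.mark.parametrize("window,polyorder,deriv", [
        (4, 2, 0),    # even window
        (5, 5, 0),    # polyorder >= window
        (5, 2, 3),    # unsupported derivative order
    ])
    def test_invalid_parameters(self, window, polyorder, deriv):
        with pytest.raises(ValidationError):
            savitzky_golay(np.ones((2, 30)), window, polyorder, deriv)


class TestPipeline:
    def _set(self, rng, n=12, p=30):
        return SpectraSet(ids=[f"s{i}" for i in range(n)],
                          wavelengths=np.linspace(1000, 2000, p),
                          X=rng.normal(size=(n, p)) + 5)

    def test_empty_steps_identity(self, rng):
        s = self._set(rng)
        out, _ = apply_pipeline(s, PreprocessConfig(steps=[]))
        np.testing.assert_array_equal(out.X, s.X)

    def test_train_stats_replayed_on_test(self, rng):
        cfg = PreprocessConfig(steps=[
            ("savitzky_golay", {"window": 7, "polyorder": 2, "deriv": 1}),
            ("mean_center", {}),
        ])
        train, test = self._set(rng), self._set(rng)
        _, fitted = apply_pipeline(train, cfg)
        out, _ = apply_pipeline(test, cfg, fitted=fitted)
        # test transform must use the *train* means, so columns need not be 0
        sg_train = apply_pipeline(train, PreprocessConfig(
            steps=[("savitzky_golay", {"window": 7, "polyorder": 2, "deriv": 1})]))[0]
        sg_test = apply_pipeline(test, PreprocessConfig(
            steps=[("savitzky_golay", {"window": 7, "polyorder": 2, "deriv": 1})]))[0]
        np.testing.assert_allclose(out.X, sg_test.X - sg_train.X.mean(0), atol=1e-10)

    def test_composition_matches_manual(self, rng):
        s = self._set(rng)
        cfg = PreprocessConfig(steps=[("snv", {}), ("mean_center", {})])
        out, _ = apply_pipeline(s, cfg)
        manual, _ = mean_center(snv(s.X))
        np.testing.assert_allclose(out.X, manual, atol=1e-12)

    def test_error_reports_step_index(self):
        bad = SpectraSet(ids=["a", "b"], wavelengths=[1.0, 2.0],
                         X=[[3.0, 3.0], [4.0, 4.0]])  # constant rows break SNV
        with pytest.raises(ValidationError, match="step 0"):
            apply_pipeline(bad, PreprocessConfig(steps=[("snv", {})]))

    def test_unknown_step_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            PreprocessConfig(steps=[("detrend", {})])

    def test_nonuniform_axis_rejected_for_derivative(self, rng):
        s = SpectraSet(ids=["a", "b"], wavelengths=np.array([1, 2, 4, 8, 16, 32,
                                                             64, 128, 256, 512,
                                                             1024, 2048]) * 1.0,
                       X=rng.normal(size=(2, 12)))
        cfg = PreprocessConfig(steps=[
            ("savitzky_golay", {"window": 5, "polyorder": 2, "deriv": 1})])
        with pytest.raises(ValidationError, match="non-uniform"):
            apply_pipeline(s, cfg)
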