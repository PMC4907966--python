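"""NIPALS PLSR core: centering, fitting, prediction, CV, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from serspls.plsr import (
    fit_nipals,
    mean_center,
    predict,
    r_squared,
    rmse,
    select_components_cv,
)
from serspls.preprocess import extract_windows, windows_from_bands, average_replicates
from serspls.synth import NoiseConfig, make_mixture_design, simulate_dataset


def random_instance(rng, n, m):
    X = rng.normal(size=(n, m))
    y = rng.normal(size=n)
    return X, y


class TestMeanCenter:
    def test_identical_rows_center_to_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        Xc, yc, xm, ym = mean_center(X, [1, 3, 1, 3])
        assert np.all(Xc == 0)
        np.testing.assert_array_equal(xm, [1, 2, 3])

    def test_centered_response(self):
        _, yc, _, ym = mean_center(np.ones((2, 3)), [1.0, 3.0])
        np.testing.assert_array_equal(yc, [-1.0, 1.0])
        assert ym == 2.0

    def test_recomposition_is_exact(self, rng):
        X, y = random_instance(rng, 6, 4)
        Xc, yc, xm, ym = mean_center(X, y)
        np.testing.assert_allclose(Xc + xm, X, rtol=1e-15, atol=1e-15)
        np.testing.assert_allclose(yc + ym, y, rtol=1e-15, atol=1e-15)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            mean_center(np.ones((1, 3)), [1.0])


class TestFitNipals:
    def test_perfectly_explanatory_column_recovers_response(self, rng):
        y = rng.normal(size=8)
        X = np.column_stack([3.0 * y, rng.normal(size=8)])
        model, _ = fit_nipals(X, y, 2)
        np.testing.assert_allclose(predict(model, X), y, rtol=1e-10, atol=1e-12)

    def test_full_rank_matches_least_squares_oracle(self, rng):
        # A = full rank -> PLSR coefficient equals the minimum-norm LS solution
        X, y = random_instance(rng, 6, 4)
        model, _ = fit_nipals(X, y, 4)
        Xc, yc, _, _ = mean_center(X, y)
        b_ls = np.linalg.pinv(Xc) @ yc
        np.testing.assert_allclose(model.b, b_ls, rtol=1e-8, atol=1e-10)

    def test_first_weight_maximizes_covariance(self, rng):
        X, y = random_instance(rng, 10, 8)
        model, _ = fit_nipals(X, y, 1)
        Xc, yc, _, _ = mean_center(X, y)
        # analytic optimum direction
        np.testing.assert_allclose(
            model.W[:, 0], Xc.T @ yc / np.linalg.norm(Xc.T @ yc), rtol=1e-12
        )
        # Monte-Carlo oracle: no random unit direction achieves more covariance
        best = abs(float((Xc @ model.W[:, 0]) @ yc))
        u = rng.normal(size=(10_000, 8))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        assert np.abs(u @ Xc.T @ yc).max() <= best * (1 + 1e-12)

    def test_one_component_coefficient_direction_and_scale(self, rng):
        # b_1 ∝ X_c^T y_c, with the constant from regressing y_c on t_1
        X, y = random_instance(rng, 12, 6)
        model, diag = fit_nipals(X, y, 1)
        Xc, yc, _, _ = mean_center(X, y)
        w = Xc.T @ yc / np.linalg.norm(Xc.T @ yc)
        t = Xc @ w
        np.testing.assert_allclose(model.b, w * (yc @ t) / (t @ t), rtol=1e-10)

    def test_component_count_beyond_rank_limit_rejected(self, rng):
        X, y = random_instance(rng, 4, 10)
        with pytest.raises(ValueError):
            fit_nipals(X, y, 4)  # limit is rows - 1 = 3

    def test_rank_deficient_data_stops_early_with_flag(self, rng):
        y = rng.normal(size=8)
        X = np.outer(y, [1.0, 2.0, -1.0])  # rank 1 after centering
        model, diag = fit_nipals(X, y, 3)
        assert model.n_components < 3
        assert diag.early_stopped

    def test_matches_sklearn_pls_regression(self, rng):
        # independent cross-check of the whole fit against scikit-learn
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_instance(rng, 20, 12)
        model, _ = fit_nipals(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(
            np.asarray(predict(model, X)), ref.predict(X).ravel(), rtol=1e-8
        )

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(
        n=st.integers(5, 50),
        m=st.integers(3, 200),
        a=st.integers(1, 4),
        seed=st.integers(0, 10_000),
    )
    def test_score_orthogonality_and_weight_orthonormality(self, n, m, a, seed):
        rng = np.random.default_rng(seed)
        X, y = random_instance(rng, n, m)
        a = min(a, n - 1, m)
        model, diag = fit_nipals(X, y, a)
        T = diag.scores
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = G / np.outer(norms, norms) - np.eye(model.n_components)
        assert np.abs(off).max() < 1e-8
        WtW = model.W.T @ model.W
        assert np.abs(WtW - np.eye(model.n_components)).max() < 1e-10

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_full_component_equivalence_with_least_squares(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(4, 12)), int(rng.integers(2, 8))
        X, y = random_instance(rng, n, m)
        a = min(n - 1, m)
        model, _ = fit_nipals(X, y, a)
        Xc, yc, _, ym = mean_center(X, y)
        b_ls, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        ls_pred = Xc @ b_ls + ym
        np.testing.assert_allclose(np.asarray(predict(model, X)), ls_pred, rtol=1e-8, atol=1e-8)

    def test_scale_and_shift_equivariance(self, rng):
        X, y = random_instance(rng, 10, 6)
        model, _ = fit_nipals(X, y, 2)
        scaled, _ = fit_nipals(X, 3.5 * y, 2)
        np.testing.assert_allclose(scaled.b, 3.5 * model.b, rtol=1e-10)
        shifted, _ = fit_nipals(X, y + 11.0, 2)
        np.testing.assert_allclose(
            np.asarray(predict(shifted, X)), np.asarray(predict(model, X)) + 11.0, rtol=1e-10
        )


class TestPredict:
    def test_mean_spectrum_predicts_mean_concentration(self, rng):
        X, y = random_instance(rng, 8, 5)
        model, _ = fit_nipals(X, y, 2)
        assert predict(model, model.x_mean) == pytest.approx(model.y_mean)

    def test_zero_coefficient_gives_constant_prediction(self, rng):
        X, y = random_instance(rng, 8, 5)
        model, _ = fit_nipals(X, y, 2)
        model.b = np.zeros_like(model.b)
        assert predict(model, rng.normal(size=5)) == pytest.approx(model.y_mean)

    def test_channel_mismatch_rejected_with_counts(self, rng):
        X, y = random_instance(rng, 8, 5)
        model, _ = fit_nipals(X, y, 2)
        with pytest.raises(ValueError, match="5"):
            predict(model, np.ones(7))


class TestSelectComponentsCV:
    def test_noiseless_rank_two_mixture_selects_two(self, libraries, axis, zero_noise):
        ss = average_replicates(
            simulate_dataset(make_mixture_design(1), libraries, zero_noise, axis, 0)
        )
        fm = extract_windows(ss, windows_from_bands(libraries["PS"]), "PS")
        a_star, curve = select_components_cv(fm.X, fm.y, a_max=6)
        assert a_star == 2
        assert curve[1] < 1e-6

    def test_single_candidate_is_selected(self, rng):
        X, y = random_instance(rng, 8, 5)
        a_star, curve = select_components_cv(X, y, a_max=1)
        assert a_star == 1 and len(curve) == 1

    def test_pure_noise_selects_parsimonious_model(self, rng):
        X, y = random_instance(rng, 15, 10)
        a_star, curve = select_components_cv(X, y, a_max=8)
        # no real structure: the curve shows no deep minimum at large A
        assert a_star == int(np.argmin(curve)) + 1

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            select_components_cv(np.ones((2, 3)), [1.0, 2.0])


class TestMetrics:
    def test_perfect_and_affine_predictions_score_one(self):
        actual = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(actual, actual) == pytest.approx(1.0)
        assert r_squared(2 * actual + 7, actual) == pytest.approx(1.0)

    def test_r_squared_matches_hand_computation(self):
        # Pearson: cov² / (var·var) = 6.5² / (5 · 8.75) computed by hand
        assert r_squared([1, 2, 3, 4], [1, 2, 3, 5]) == pytest.approx(0.96571428, abs=1e-6)

    def test_r_squared_symmetric(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=9)
        assert r_squared(a, b) == pytest.approx(r_squared(b, a), rel=1e-12)

    def test_constant_argument_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1, 2, 3], [5, 5, 5])

    def test_rmse_hand_values(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([1, 2, 3], [1, 2, 4]) == pytest.approx(np.sqrt(1 / 3), abs=1e-10)
        assert rmse(np.zeros(5) + 2.5, np.zeros(5)) == pytest.approx(2.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            r_squared([1, 2], [1, 2, 3])
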