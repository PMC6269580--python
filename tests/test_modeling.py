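"""PCA, PCR/PLS calibration, cross-validation and latent-variable choice."""

import numpy as np
import pytest
from scipy.stats import f as f_dist
from sklearn.cross_decomposition import PLSRegression

from miaqsar import CalibrationModel, choose_n_lv, fit_pcr, fit_pls, loo_rmsecv, pca, predict
from miaqsar.modeling import CvCurve


def lstsq_oracle(x_train, y_train, x_new):
    """Minimum-norm least squares with explicit centering."""
    xm, ym = x_train.mean(axis=0), y_train.mean()
    b, *_ = np.linalg.lstsq(x_train - xm, y_train - ym, rcond=None)
    return (x_new - xm) @ b + ym


class TestPca:
    def test_rank_one_matrix_explains_everything(self, rng):
        x = np.outer(rng.random(6), rng.random(4))
        with pytest.warns(UserWarning, match="rank"):
            _, _, evr = pca(x, 3)
        assert evr[0] == pytest.approx(1.0)

    def test_full_reconstruction(self, rng):
        x = rng.random((8, 5))
        scores, loadings, _ = pca(x, 5)
        np.testing.assert_allclose(scores @ loadings.T, x - x.mean(axis=0), atol=1e-9)

    def test_explained_variance_matches_eigendecomposition(self, rng):
        x = rng.random((10, 6))
        _, _, evr = pca(x, 5)
        xc = x - x.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(xc.T @ xc))[::-1]
        np.testing.assert_allclose(evr, (eig / eig.sum())[:5], atol=1e-10)

    def test_loadings_orthonormal(self, rng):
        _, loadings, _ = pca(rng.random((9, 7)), 4)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(4), atol=1e-10)


class TestPcr:
    def test_exact_linear_response_interpolated_at_full_rank(self, rng):
        x = rng.random((10, 4))
        y = x @ np.array([1.0, -2.0, 0.5, 3.0]) + 2.0
        model = fit_pcr(x, y, 4)
        np.testing.assert_allclose(predict(model, x), y, atol=1e-8)

    def test_full_rank_matches_least_squares_oracle(self, rng):
        x, x_new = rng.random((12, 5)), rng.random((4, 5))
        y = rng.random(12)
        model = fit_pcr(x, y, 5)
        np.testing.assert_allclose(predict(model, x_new), lstsq_oracle(x, y, x_new), atol=1e-8)

    def test_response_orthogonal_to_first_component_gives_null_model(self, rng):
        x = rng.random((10, 5))
        scores, _, _ = pca(x, 2)
        y = scores[:, 1]  # orthogonal to the first score column by construction
        model = fit_pcr(x, y, 1)
        assert np.linalg.norm(model.regression_vector) < 1e-8

    def test_rank_deficiency_rejected(self, rng):
        x = np.tile(rng.random((6, 1)), (1, 4))
        with pytest.raises(ValueError, match="rank"):
            fit_pcr(x, rng.random(6), 2)


class TestPls:
    def test_full_rank_matches_least_squares_oracle(self, rng):
        x, x_new = rng.random((12, 5)), rng.random((4, 5))
        y = rng.random(12)
        model = fit_pls(x, y, 5)
        np.testing.assert_allclose(
            predict(model, x_new), lstsq_oracle(x, y, x_new), rtol=1e-6, atol=1e-6
        )

    def test_single_column_collapses_to_simple_regression(self, rng):
        x = rng.random((9, 1))
        y = rng.random(9)
        model = fit_pls(x, y, 1)
        xc, yc = x[:, 0] - x.mean(), y - y.mean()
        slope = (xc @ yc) / (xc @ xc)
        assert model.regression_vector[0] == pytest.approx(slope, rel=1e-10)

    def test_uncorrelated_response_gives_null_first_component(self, rng):
        x = rng.random((8, 4))
        xc = x - x.mean(axis=0)
        # build y orthogonal to every column
        q, _ = np.linalg.qr(xc)
        y = rng.random(8)
        y -= q @ (q.T @ y)
        y -= y.mean()  # stays orthogonal: columns are centered
        if np.ptp(y) == 0:
            pytest.skip("degenerate draw")
        model = fit_pls(x, y + 1.0, 1)
        assert np.linalg.norm(model.regression_vector) < 1e-8

    def test_scores_mutually_orthogonal(self, rng):
        x, y = rng.random((14, 8)), rng.random(14)
        model = fit_pls(x, y, 5)
        g = model.scores.T @ model.scores
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(g)).max()

    def test_matches_sklearn_nipals(self, rng):
        x, y = rng.random((15, 7)), rng.random(15)
        for n_lv in (1, 3, 5):
            model = fit_pls(x, y, n_lv)
            sk = PLSRegression(n_components=n_lv, scale=False).fit(x, y)
            np.testing.assert_allclose(
                predict(model, x), sk.predict(x).ravel(), rtol=1e-8, atol=1e-8
            )

    def test_constant_response_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fit_pls(rng.random((6, 3)), np.ones(6), 1)


class TestLooRmsecv:
    def test_exact_linear_response_reaches_zero(self, rng):
        x = rng.random((10, 3))
        y = x @ np.array([1.0, 2.0, -1.0])
        curve = loo_rmsecv(x, y, method="pls", lv_range=[3])
        assert curve.rmsecv[0] < 1e-8

    @pytest.mark.parametrize("method", ["pls", "pcr"])
    def test_matches_naive_double_loop(self, method, rng):
        x, y = rng.random((8, 5)), rng.random(8)
        curve = loo_rmsecv(x, y, method=method, lv_range=[1, 2, 3])
        fit = fit_pls if method == "pls" else fit_pcr
        for lv, got in zip(curve.n_lvs, curve.rmsecv):
            press = 0.0
            for i in range(8):
                mask = np.arange(8) != i
                m = fit(x[mask], y[mask], lv)
                press += (predict(m, x[i : i + 1])[0] - y[i]) ** 2
            assert got == pytest.approx(np.sqrt(press / 8), rel=1e-10)

    def test_row_permutation_leaves_curve_unchanged(self, rng):
        x, y = rng.random((9, 4)), rng.random(9)
        perm = rng.permutation(9)
        a = loo_rmsecv(x, y, method="pls", lv_range=[1, 2])
        b = loo_rmsecv(x[perm], y[perm], method="pls", lv_range=[1, 2])
        np.testing.assert_allclose(a.rmsecv, b.rmsecv, rtol=1e-10)

    def test_unsupported_lv_candidates_skipped_with_warning(self, rng):
        x, y = rng.random((5, 6)), rng.random(5)
        with pytest.warns(UserWarning, match="skipping"):
            curve = loo_rmsecv(x, y, method="pls", lv_range=[1, 5])
        assert curve.n_lvs == [1]


class TestChooseNLv:
    def test_manual_f_quantile_computation(self):
        curve = CvCurve(n_lvs=[1, 2, 3, 4], rmsecv=[1.0, 0.50, 0.49, 0.48], n=20)
        chosen = choose_n_lv(curve, alpha=0.25)
        f_crit = f_dist.ppf(0.75, 20, 20)
        assert (1.0 / 0.48) ** 2 >= f_crit  # LV 1 is significantly worse
        assert (0.50 / 0.48) ** 2 < f_crit  # LV 2 is not
        assert chosen == 2

    def test_flat_curve_prefers_smallest(self):
        curve = CvCurve(n_lvs=[1, 2, 3], rmsecv=[0.3, 0.3, 0.3], n=10)
        assert choose_n_lv(curve) == 1

    def test_steep_descent_keeps_argmin(self):
        curve = CvCurve(n_lvs=[1, 2, 3], rmsecv=[9.0, 3.0, 0.1], n=10)
        assert choose_n_lv(curve) == 3


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, rng):
        x, y = rng.random((10, 4)), rng.random(10)
        model = fit_pls(x, y, 2)
        fitted = (x - model.x_means) @ model.regression_vector + model.y_mean
        np.testing.assert_allclose(predict(model, x), fitted)

    def test_mean_row_predicts_mean_response(self, rng):
        x, y = rng.random((10, 4)), rng.random(10)
        model = fit_pcr(x, y, 2)
        assert predict(model, x.mean(axis=0))[0] == pytest.approx(y.mean())

    def test_column_count_mismatch_raises(self, rng):
        model = fit_pls(rng.random((8, 3)), rng.random(8), 1)
        with pytest.raises(ValueError, match="column"):
            predict(model, rng.random((2, 5)))

    def test_json_roundtrip_preserves_predictions(self, tmp_path, rng):
        x, y = rng.random((9, 4)), rng.random(9)
        model = fit_pls(x, y, 3, column_map=np.argwhere(np.ones((2, 2))))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = CalibrationModel.from_json(path)
        np.testing.assert_allclose(predict(loaded, x), predict(model, x), rtol=1e-12)
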