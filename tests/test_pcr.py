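"""PCR: covariate handling, PCA conventions, k-selection, transfer, metrics."""

import numpy as np
import pandas as pd
import pytest

from gcaconn.pcr import (
    PCR,
    CovariateSpec,
    apply_covariates,
    covariate_design,
    cv_metrics,
    fit_covariates,
    fit_pca,
    fit_pcr,
    predict,
    select_k,
)


@pytest.fixture()
def cov_frame(rng):
    n = 200
    return pd.DataFrame(
        {
            "age": rng.normal(10, 0.6, n),
            "sex": rng.choice(["F", "M"], n),
            "race": rng.choice(["A", "B", "C"], n),
            "mean_fd": rng.gamma(4, 0.05, n),
        }
    )


class TestCovariates:
    def test_design_includes_squared_terms_as_columns(self, cov_frame):
        spec = CovariateSpec.from_frame(cov_frame)
        x = covariate_design(cov_frame, spec)
        assert "age_sq" in spec.columns and "mean_fd_sq" in spec.columns
        age_c = cov_frame["age"] - cov_frame["age"].mean()
        np.testing.assert_allclose(
            x[:, spec.columns.index("age_sq")], age_c**2
        )

    def test_orthogonal_y_residuals_are_centered_y(self, rng):
        n = 500
        x = rng.standard_normal((n, 2))
        x1 = np.column_stack([np.ones(n), x])
        y = rng.standard_normal(n)
        y -= x1 @ np.linalg.lstsq(x1, y, rcond=None)[0]  # orthogonal incl. intercept
        y += 2.0  # restore a mean so the centering is visible
        resid, betas = fit_covariates(y, x)
        np.testing.assert_allclose(resid, y - y.mean(), atol=1e-10)

    def test_exact_linear_y_gives_zero_residuals(self, rng):
        x = rng.standard_normal((100, 3))
        y = 2.0 + x @ np.array([1.0, -2.0, 0.5])
        resid, _ = fit_covariates(y, x)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.standard_normal((50, 2))
        x = np.column_stack([x, x[:, 0] * 2.0])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_covariates(rng.standard_normal(50), x)

    def test_apply_equals_fit_on_same_data(self, rng):
        x = rng.standard_normal((80, 3))
        y = rng.standard_normal(80)
        resid, betas = fit_covariates(y, x)
        np.testing.assert_allclose(apply_covariates(y, x, betas), resid, atol=1e-12)

    def test_transfer_differs_from_refit_on_shifted_test(self, rng):
        x_tr = rng.standard_normal((100, 2))
        y_tr = x_tr @ np.array([1.0, 0.5]) + rng.standard_normal(100)
        _, betas = fit_covariates(y_tr, x_tr)
        x_te = rng.standard_normal((100, 2)) + 3.0  # shifted covariate means
        y_te = x_te @ np.array([1.0, 0.5]) + rng.standard_normal(100)
        transferred = apply_covariates(y_te, x_te, betas)
        refit, _ = fit_covariates(y_te, x_te)
        assert not np.allclose(transferred, refit)

    def test_zero_betas_return_y(self, rng):
        y = rng.standard_normal(30)
        out = apply_covariates(y, rng.standard_normal((30, 2)), np.zeros(3))
        np.testing.assert_array_equal(out, y)


class TestPCA:
    def test_collinear_points_explained_by_first_component(self, rng):
        t = rng.standard_normal(50)
        feats = np.column_stack([t, 2 * t])
        _, comps, scores = fit_pca(feats)
        var = scores.var(axis=0)
        assert var[0] / var.sum() == pytest.approx(1.0)

    def test_full_reconstruction_is_exact(self, rng):
        feats = rng.standard_normal((20, 6))
        means, comps, scores = fit_pca(feats)
        np.testing.assert_allclose(means + scores @ comps.T, feats, atol=1e-10)

    def test_matches_eigendecomposition_oracle(self, rng):
        feats = rng.standard_normal((20, 6))
        means, comps, scores = fit_pca(feats)
        cov = np.cov(feats, rowvar=False, ddof=1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vecs = vecs[:, order]
        for k in range(6):
            v = vecs[:, k] * np.sign(vecs[np.abs(vecs[:, k]).argmax(), k])
            assert np.abs(comps[:, k] - v).max() < 1e-10
        np.testing.assert_allclose(
            scores, (feats - means) @ comps, atol=1e-10
        )

    def test_sign_convention_deterministic(self, rng):
        feats = rng.standard_normal((30, 5))
        _, c1, _ = fit_pca(feats)
        _, c2, _ = fit_pca(feats.copy())
        np.testing.assert_array_equal(c1, c2)
        assert all(c1[np.abs(c1[:, j]).argmax(), j] > 0 for j in range(5))


class TestSelectK:
    def test_recovers_single_component_signal(self, rng):
        n, p = 300, 40
        w = rng.standard_normal(n) * 3.0
        direction = rng.standard_normal(p)
        feats = np.outer(w, direction) + rng.standard_normal((n, p))
        y = w + 0.5 * rng.standard_normal(n)
        k, path = select_k(feats, y, [1, 2, 5, 10, 20], seed=0)
        assert k <= 2

    def test_singleton_grid(self, rng):
        feats = rng.standard_normal((50, 10))
        k, _ = select_k(feats, rng.standard_normal(50), [7], seed=0)
        assert k == 7

    def test_empty_grid_raises(self, rng):
        with pytest.raises(ValueError, match="empty"):
            select_k(rng.standard_normal((50, 10)), rng.standard_normal(50), [])

    def test_noise_y_still_returns_grid_member(self, rng):
        feats = rng.standard_normal((60, 15))
        grid = [1, 3, 5]
        k, _ = select_k(feats, rng.standard_normal(60), grid, seed=1)
        assert k in grid

    def test_family_blocking_keeps_families_together(self, rng):
        from gcaconn.pcr import _family_folds

        fams = np.repeat(np.arange(20), 3)
        folds = _family_folds(fams, 5, rng)
        for fold in folds:
            for f in np.unique(fams[fold]):
                assert np.isin(np.flatnonzero(fams == f), fold).all()


class TestFitPredict:
    def test_noiseless_linear_data_interpolated(self, rng):
        n, p = 30, 10
        feats = rng.standard_normal((n, p))
        beta = rng.standard_normal(p)
        y = feats @ beta
        model = fit_pcr(feats, y, np.empty((n, 0)), k=min(n - 1, p))
        pred = predict(model, feats)
        assert np.corrcoef(pred, y)[0, 1] > 0.999999

    def test_planted_component_carries_largest_beta(self, rng):
        n, p = 400, 60
        w = rng.standard_normal(n) * 4.0
        direction = np.zeros(p)
        direction[:10] = 1.0
        feats = np.outer(w, direction) + rng.standard_normal((n, p))
        y = w + rng.standard_normal(n)
        model = fit_pcr(feats, y, np.empty((n, 0)), k=5)
        assert np.abs(model.phenotype_betas[1:]).argmax() == 0

    def test_refit_is_deterministic(self, rng):
        feats = rng.standard_normal((50, 12))
        y = rng.standard_normal(50)
        x = rng.standard_normal((50, 2))
        m1 = fit_pcr(feats, y, x, k=4)
        m2 = fit_pcr(feats, y, x, k=4)
        np.testing.assert_array_equal(m1.components, m2.components)
        np.testing.assert_array_equal(m1.phenotype_betas, m2.phenotype_betas)

    def test_zero_features_predict_intercept(self, rng):
        feats = rng.standard_normal((50, 8))
        y = rng.standard_normal(50) + 3.0
        model = fit_pcr(feats, y, np.empty((50, 0)), k=3)
        pred = predict(model, model.feature_means[None, :])
        assert pred[0] == pytest.approx(model.phenotype_betas[0])

    def test_train_test_separation(self, rng):
        # corrupting the test set must not change the fitted model
        feats = rng.standard_normal((60, 10))
        y = rng.standard_normal(60)
        model = fit_pcr(feats, y, np.empty((60, 0)), k=4)
        test = rng.standard_normal((20, 10))
        p1 = predict(model, test)
        model2 = fit_pcr(feats, y, np.empty((60, 0)), k=4)
        np.testing.assert_array_equal(model.phenotype_betas, model2.phenotype_betas)
        np.testing.assert_array_equal(p1, predict(model2, test))


class TestCVMetrics:
    def test_perfect_predictions(self, rng):
        y = rng.standard_normal(100)
        x = np.empty((100, 0))
        resid, betas = fit_covariates(y, x)
        m = cv_metrics(resid, y, x, betas)
        assert m.r_cv == pytest.approx(1.0)
        assert m.partial_eta2_cv == pytest.approx(1.0)

    def test_zero_predictions_give_zero_eta2(self, rng):
        y = rng.standard_normal(100)
        x = np.empty((100, 0))
        _, betas = fit_covariates(y, x)
        with pytest.warns(RuntimeWarning):
            m = cv_metrics(np.zeros(100), y, x, betas)
        assert m.partial_eta2_cv == 0.0
        assert np.isnan(m.r_cv)

    def test_r_squared_tracks_partial_eta2(self, rng):
        # planted linear signal: eta2 ~ r^2 for a well-scaled predictor
        n = 2000
        w = rng.standard_normal(n)
        y = 0.42 * w + np.sqrt(1 - 0.42**2) * rng.standard_normal(n)
        x = np.empty((n, 0))
        _, betas = fit_covariates(y, x)
        m = cv_metrics(0.42 * w, y, x, betas)
        assert abs(m.r_cv**2 - m.partial_eta2_cv) < 0.02
        assert m.r_cv == pytest.approx(0.42, abs=0.05)

    def test_null_safety_mean_r_near_zero(self, rng):
        rs = []
        for _ in range(20):
            feats = rng.standard_normal((120, 30))
            y = rng.standard_normal(120)
            model = fit_pcr(feats[:80], y[:80], np.empty((80, 0)), k=5)
            pred = predict(model, feats[80:])
            m = cv_metrics(pred, y[80:], np.empty((40, 0)), model.covariate_betas)
            rs.append(m.r_cv)
        assert -0.05 < np.mean(rs) < 0.05


class TestModelClassFrontEnd:
    def test_fit_selects_k_and_predicts(self, rng):
        n, p = 250, 30
        w = rng.standard_normal(n) * 3
        feats = np.outer(w, rng.standard_normal(p)) + rng.standard_normal((n, p))
        y = w + rng.standard_normal(n)
        res = PCR(y[:200], feats[:200], np.empty((200, 0)), k_grid=[1, 5, 10]).fit()
        assert res.k in (1, 5, 10)
        metrics = res.evaluate(feats[200:], y[200:], np.empty((50, 0)))
        assert metrics.r_cv > 0.7
        assert "Principal component regression" in res.summary()
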