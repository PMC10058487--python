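import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blockpath import (
    explained_variance_fraction,
    fit_pls,
    predict,
    predict_components,
    vip,
)
from conftest import regression_problem


class TestFitPLS:
    def test_single_column_proportional_response_exact(self):
        X = np.arange(10, dtype=float)[:, None]
        Y = 2.0 * X
        model = fit_pls(X, Y, 1)
        np.testing.assert_allclose(predict(model, X), Y, atol=1e-10)
        assert model.coefficients[0, 0] == pytest.approx(2.0)

    def test_full_rank_matches_ols_oracle(self, rng, ols_oracle):
        X, Y = regression_problem(rng, n=10, p=3)
        model = fit_pls(X, Y, 3)
        np.testing.assert_allclose(predict(model, X), ols_oracle(X, Y), atol=1e-8)

    def test_orthogonal_response_stops_early(self, rng):
        X = rng.normal(size=(20, 3))
        Xc = X - X.mean(axis=0)
        # build Y orthogonal to every centered column of X
        q, _ = np.linalg.qr(Xc)
        noise = rng.normal(size=20)
        Y = noise - q @ (q.T @ noise)
        model = fit_pls(X, Y, 2)
        assert model.early_stopped
        assert model.n_components == 0
        np.testing.assert_allclose(model.coefficients, 0.0, atol=1e-12)

    def test_scores_mutually_orthogonal(self, rng):
        X, Y = regression_problem(rng, n=30, p=6, q=2, noise=0.5)
        model = fit_pls(X, Y, 5)
        T = model.x_scores
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8 * np.diag(gram).max()

    def test_coefficient_and_score_predictions_agree(self, rng):
        X, Y = regression_problem(rng, n=25, p=4, q=3, noise=0.3)
        model = fit_pls(X, Y, 3)
        via_coef = predict(model, X)
        via_scores = model.x_scores @ model.y_loadings.T + model.y_means
        np.testing.assert_allclose(via_coef, via_scores, atol=1e-8)

    def test_row_permutation_invariance(self, rng):
        X, Y = regression_problem(rng, n=30, p=4, q=2, noise=0.2)
        perm = rng.permutation(30)
        m1 = fit_pls(X, Y, 3)
        m2 = fit_pls(X[perm], Y[perm], 3)
        np.testing.assert_allclose(m1.coefficients, m2.coefficients, atol=1e-10)

    def test_training_evar_nondecreasing_in_components(self, rng):
        X, Y = regression_problem(rng, n=40, p=6, noise=1.0)
        evars = []
        for a in range(1, 7):
            m = fit_pls(X, Y, a)
            evars.append(
                explained_variance_fraction(Y, predict(m, X), Y.mean(axis=0))
            )
        assert np.all(np.diff(evars) >= -1e-12)

    def test_component_cap_enforced(self, rng):
        X, Y = regression_problem(rng, n=5, p=3)
        with pytest.raises(ValueError, match="exceeds"):
            fit_pls(X, Y, 5)

    def test_matches_sklearn_pls(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, Y = regression_problem(rng, n=40, p=8, q=3, noise=0.5)
        for a in (1, 2, 4):
            mine = predict(fit_pls(X, Y, a), X)
            ref = (
                sklearn.PLSRegression(n_components=a, scale=False, tol=1e-12,
                                      max_iter=5000)
                .fit(X, Y)
                .predict(X)
            )
            np.testing.assert_allclose(mine, ref, atol=1e-5)


class TestPredict:
    def test_mean_row_predicts_mean_response(self, rng):
        X, Y = regression_problem(rng, n=20, p=4, noise=0.5)
        model = fit_pls(X, Y, 2)
        pred = predict(model, model.x_means)
        np.testing.assert_allclose(pred.ravel(), model.y_means, atol=1e-10)

    def test_column_mismatch_raises(self, rng):
        X, Y = regression_problem(rng, n=20, p=4)
        model = fit_pls(X, Y, 2)
        with pytest.raises(ValueError, match="columns"):
            predict(model, np.zeros((3, 5)))

    def test_nested_component_predictions_match_separate_fits(self, rng):
        X, Y = regression_problem(rng, n=30, p=5, q=2, noise=0.4)
        model = fit_pls(X, Y, 4)
        path = predict_components(model, X)
        for a in range(1, 5):
            np.testing.assert_allclose(
                path[a - 1], predict(fit_pls(X, Y, a), X), atol=1e-8
            )


class TestExplainedVariance:
    def test_perfect_prediction_is_one(self, rng):
        Y = rng.normal(size=(10, 2))
        assert explained_variance_fraction(Y, Y, Y.mean(axis=0)) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self, rng):
        Y = rng.normal(size=(10, 2))
        pred = np.tile(Y.mean(axis=0), (10, 1))
        assert explained_variance_fraction(Y, pred, Y.mean(axis=0)) == pytest.approx(0.0)

    def test_training_fit_equals_squared_correlation(self, rng):
        x = rng.normal(size=200)
        y = 0.6 * x + 0.8 * rng.normal(size=200)
        model = fit_pls(x[:, None], y, 1)
        ev = explained_variance_fraction(
            y, predict(model, x[:, None]).ravel(), y.mean()
        )
        r = np.corrcoef(x, y)[0, 1]
        assert ev == pytest.approx(r**2, abs=1e-10)

    def test_constant_truth_raises(self):
        with pytest.raises(ValueError, match="zero total variance"):
            explained_variance_fraction(np.ones(5), np.ones(5), np.array([1.0]))


def vip_reference(model):
    """Independent re-implementation of the VIP formula from W, T, Q."""
    W, T, Q = model.weights, model.x_scores, model.y_loadings
    p, a = W.shape
    ssy = np.array(
        [float(Q[:, k] @ Q[:, k]) * float(T[:, k] @ T[:, k]) for k in range(a)]
    )
    out = np.zeros(p)
    for j in range(p):
        num = sum(
            ssy[k] * (W[j, k] / np.linalg.norm(W[:, k])) ** 2 for k in range(a)
        )
        out[j] = np.sqrt(p * num / ssy.sum())
    return out


class TestVIP:
    def test_single_predictor_vip_is_one(self, rng):
        X = rng.normal(size=(15, 1))
        y = X.ravel() + 0.1 * rng.normal(size=15)
        assert vip(fit_pls(X, y, 1)) == pytest.approx([1.0])

    def test_mean_squared_vip_is_one(self, rng):
        X, Y = regression_problem(rng, n=30, p=7, q=2, noise=0.5)
        for a in (1, 3, 5):
            v = vip(fit_pls(X, Y, a))
            assert np.mean(v**2) == pytest.approx(1.0, abs=1e-8)

    def test_informative_variable_outranks_noise(self, rng):
        x1 = rng.normal(size=100)
        x2 = rng.normal(size=100)
        y = x1 + 0.05 * rng.normal(size=100)
        model = fit_pls(np.column_stack([x1, x2]), y, 1)
        v = vip(model)
        assert v[0] > 1 > v[1]
        np.testing.assert_allclose(v, vip_reference(model), atol=1e-10)

    def test_matches_reference_formula(self, rng):
        X, Y = regression_problem(rng, n=40, p=9, q=3, noise=0.8)
        model = fit_pls(X, Y, 4)
        np.testing.assert_allclose(vip(model), vip_reference(model), atol=1e-10)

    def test_scale_invariance_after_uv_scaling(self, rng):
        # multiplying a raw column by a constant is undone by unit-variance
        # scaling, so the downstream VIP is unchanged
        X, Y = regression_problem(rng, n=30, p=4, noise=0.5)
        Xs = X / X.std(axis=0, ddof=1)
        X2 = X.copy()
        X2[:, 1] *= 7.5
        X2s = X2 / X2.std(axis=0, ddof=1)
        v1 = vip(fit_pls(Xs, Y, 2))
        v2 = vip(fit_pls(X2s, Y, 2))
        np.testing.assert_allclose(v1, v2, atol=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(8, 30),
    p=st.integers(2, 6),
    a=st.integers(1, 3),
)
def test_pls_invariants_hold_for_random_problems(seed, n, p, a):
    """Score orthogonality and the VIP normalization hold on arbitrary
    well-posed regression problems."""
    rng = np.random.default_rng(seed)
    a = min(a, p, n - 1)
    X = rng.normal(size=(n, p))
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    model = fit_pls(X, y, a)
    if model.n_components == 0:
        return
    T = model.x_scores
    gram = T.T @ T
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() <= 1e-8 * max(np.diag(gram).max(), 1e-30)
    assert np.mean(vip(model) ** 2) == pytest.approx(1.0, abs=1e-8)
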