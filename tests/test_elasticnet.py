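"""Coordinate-descent solver: closed-form limits, KKT certificates, path
behaviour and cross-validation."""

import numpy as np
import pytest

from dogclock import elasticnet as en


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(0)


def test_unpenalized_limit_matches_ols(rng):
    X = rng.normal(size=(20, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=20)
    fit = en.fit_elastic_net(X, y, lam=0.0, alpha=0.5)
    Z = np.column_stack([np.ones(20), X])
    beta = np.linalg.lstsq(Z, y, rcond=None)[0]
    np.testing.assert_allclose(fit.coef, beta[1:], atol=1e-8)
    assert fit.intercept == pytest.approx(beta[0], abs=1e-8)


def test_ridge_limit_matches_closed_form(rng):
    n, p = 30, 8
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    lam = 0.7
    fit = en.fit_elastic_net(X, y, lam=lam, alpha=0.0)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta = np.linalg.solve(Xc.T @ Xc / n + lam * np.eye(p), Xc.T @ yc / n)
    np.testing.assert_allclose(fit.coef, beta, atol=1e-8)


def test_lambda_max_gives_exact_zero(rng):
    X = rng.normal(size=(25, 40))
    y = rng.normal(size=25)
    lmax = en.lambda_max(X, y, alpha=0.5)
    fit = en.fit_elastic_net(X, y, lam=lmax, alpha=0.5)
    assert np.all(fit.coef == 0.0)
    assert fit.intercept == pytest.approx(y.mean())
    # KKT at beta = 0: |x_j' y / N| <= lambda * alpha for every column
    Xc = X - X.mean(axis=0)
    g = np.abs(Xc.T @ (y - y.mean())) / len(y)
    assert g.max() <= lmax * 0.5 + 1e-12
    # and just below lambda_max something activates
    below = en.fit_elastic_net(X, y, lam=lmax * 0.999, alpha=0.5)
    assert np.any(below.coef != 0.0)


def test_lambda_max_matches_column_scan_oracle(rng):
    X = rng.normal(size=(15, 10))
    y = rng.normal(size=15)
    Xc = X - X.mean(axis=0)
    oracle = max(abs(Xc[:, j] @ (y - y.mean())) / 15 for j in range(10)) / 0.5
    assert en.lambda_max(X, y, 0.5) == pytest.approx(oracle, rel=1e-12)


def test_lambda_path_shape_and_monotone(rng):
    X = rng.normal(size=(30, 10))
    y = rng.normal(size=30)
    path = en.lambda_path(X, y, alpha=0.5, n_lambda=50)
    assert len(path) == 50
    assert (np.diff(path) < 0).all()
    assert path[0] == pytest.approx(en.lambda_max(X, y, 0.5))
    # first lambda yields the null model
    fit = en.fit_elastic_net(X, y, path[0], 0.5)
    assert np.all(fit.coef == 0.0)


def test_kkt_certificate_on_random_fits(rng):
    for _ in range(10):
        n, p = int(rng.integers(10, 60)), int(rng.integers(5, 120))
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        lam = float(rng.uniform(0.01, 1.0))
        fit = en.fit_elastic_net(X, y, lam, alpha=0.5)
        assert en.kkt_certificate(X, y, fit) < 1e-6 * y.std()


def test_objective_nonincreasing_across_sweeps(rng):
    """Each coordinate-descent sweep weakly decreases the objective."""
    n, p = 40, 60
    X = rng.normal(size=(n, p))
    y = X[:, :5] @ rng.normal(size=5) + rng.normal(size=n)
    lam, alpha = 0.1, 0.5
    XT, yc, x_mean, y_mean, v = en._prepare(X, y)
    beta = np.zeros(p)
    r = yc.copy()
    cand = np.ones(p, dtype=bool)
    objs = []
    for _ in range(30):
        en._cd_sweeps(XT, r, beta, v, lam * alpha, lam * (1 - alpha), cand, 0.0, 1)
        intercept = y_mean - x_mean @ beta
        objs.append(en.elastic_net_objective(X, y, intercept, beta, lam, alpha))
    diffs = np.diff(objs)
    assert (diffs <= 1e-12).all()


def test_path_continuity_with_warm_starts(rng):
    n, p = 40, 80
    X = rng.normal(size=(n, p))
    y = X[:, :5] @ rng.normal(size=5) + rng.normal(size=n)
    path = en.lambda_path(X, y, 0.5, n_lambda=100)
    coefs, _ = en.fit_path(X, y, path, 0.5)
    jumps = np.abs(np.diff(coefs, axis=0)).max(axis=1)
    # adjacent solutions on a fine log grid stay close
    assert jumps.max() < 0.25 * y.std()


def test_warm_start_reaches_same_solution(rng):
    X = rng.normal(size=(30, 50))
    y = rng.normal(size=30)
    cold = en.fit_elastic_net(X, y, 0.2, 0.5)
    warm = en.fit_elastic_net(X, y, 0.2, 0.5, warm_start=rng.normal(size=50) * 0.1)
    np.testing.assert_allclose(cold.coef, warm.coef, atol=1e-6)


def test_selected_is_exact_support(rng):
    X = rng.normal(size=(30, 50))
    y = X[:, :3] @ np.array([2.0, -1.0, 1.5]) + rng.normal(size=30)
    fit = en.fit_elastic_net(X, y, 0.3, 0.5)
    np.testing.assert_array_equal(fit.selected, np.flatnonzero(fit.coef))


def test_predict_cases(rng):
    X = rng.normal(size=(20, 5))
    y = rng.normal(size=20)
    fit = en.fit_elastic_net(X, y, 0.1, 0.5)
    x = rng.normal(size=5)
    assert en.predict(fit, x) == pytest.approx(fit.intercept + x @ fit.coef)
    assert en.predict(fit, np.zeros(5)) == pytest.approx(fit.intercept)
    with pytest.raises(ValueError, match="dimension"):
        en.predict(fit, np.zeros(4))
    null = en.fit_elastic_net(X, y, en.lambda_max(X, y, 0.5), 0.5)
    assert en.predict(null, x) == pytest.approx(y.mean())


def test_cv_requires_k_at_most_n(rng):
    X = rng.normal(size=(5, 3))
    y = rng.normal(size=5)
    with pytest.raises(ValueError, match="k <= N"):
        en.cv_select_lambda(X, y, k=6)


def test_cv_loocv_boundary(rng):
    X = rng.normal(size=(12, 6))
    y = X[:, 0] * 2 + rng.normal(size=12) * 0.1
    res = en.cv_select_lambda(X, y, k=12, seed=1)
    assert np.isfinite(res.cv_mse).all()
    assert res.lam in res.lambdas


def test_cv_strong_signal_small_lambda(rng):
    n, p = 200, 5
    X = rng.normal(size=(n, p))
    y = X @ np.array([3.0, -2.0, 1.0, 0.0, 0.0]) + rng.normal(size=n)
    res = en.cv_select_lambda(X, y, k=10, seed=2)
    assert res.best_index > len(res.lambdas) // 2  # deep into the path
    assert res.cv_mse[res.best_index] < 1.5        # near the noise variance


def test_cv_pure_noise_prefers_heavy_penalty():
    hits = 0
    n_rep = 20
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 100))
        y = rng.normal(size=40)
        res = en.cv_select_lambda(X, y, k=5, seed=seed)
        if res.best_index < len(res.lambdas) // 4:
            hits += 1
    assert hits > n_rep / 2  # majority land near the null-model end


def test_cv_ties_break_to_larger_lambda():
    # constant response: every lambda gives the null model and identical MSE
    rng = np.random.default_rng(3)
    X = rng.normal(size=(12, 4))
    y = np.full(12, 7.0)
    res = en.cv_select_lambda(X, y, k=3, seed=0)
    assert res.best_index == 0


def test_agreement_with_reference_implementation(rng):
    """Spot-check against the scikit-learn elastic net on random instances
    (the full 100-instance sweep runs in the acceptance suite)."""
    from sklearn.linear_model import ElasticNet

    for _ in range(10):
        n = int(rng.integers(15, 100))
        p = int(rng.integers(5, 200))
        X = rng.normal(size=(n, p))
        k = min(5, p)
        y = X[:, :k] @ rng.normal(size=k) + rng.normal(size=n)
        lam = float(rng.uniform(0.01, 1.0))
        alpha = float(rng.uniform(0.1, 1.0))
        mine = en.fit_elastic_net(X, y, lam, alpha)
        ref = ElasticNet(alpha=lam, l1_ratio=alpha, tol=1e-10, max_iter=200_000).fit(X, y)
        denom = max(np.linalg.norm(ref.coef_), 1e-12)
        assert np.linalg.norm(mine.coef - ref.coef_) / denom < 1e-4
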