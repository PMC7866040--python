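"""Weighted-L1 logistic solver: exactness, KKT, limits, CV selection."""

import numpy as np
import pytest
from scipy.optimize import minimize

from breathlasso import (
    cv_select_lambda,
    fit_weighted_l1,
    kkt_violation,
    lambda_max,
    objective,
    predict_probability,
)
from breathlasso.solver import stratified_folds

from conftest import make_logistic_data


def convex_oracle_objective(X, y, lam, w):
    """Generic convex optimizer on the same penalized likelihood, using the
    smooth split beta = b+ - b- with b+, b- >= 0 (independent of the
    coordinate-descent path it checks)."""
    n, p = X.shape
    finite = np.isfinite(w)
    wpen = np.where(finite, w, 0.0)

    def f(z):
        b0, bp, bm = z[0], z[1 : 1 + p], z[1 + p :]
        eta = b0 + X @ (bp - bm)
        return np.sum(np.logaddexp(0, eta) - y * eta) + lam * np.sum(
            wpen * (bp + bm)
        )

    def g(z):
        b0, bp, bm = z[0], z[1 : 1 + p], z[1 + p :]
        eta = b0 + X @ (bp - bm)
        prob = 1 / (1 + np.exp(-eta))
        gb = X.T @ (prob - y)
        return np.concatenate([[np.sum(prob - y)], gb + lam * wpen, -gb + lam * wpen])

    bounds = [(None, None)]
    for _ in range(2):
        bounds += [(0.0, 0.0) if not finite[j] else (0.0, None) for j in range(p)]
    res = minimize(
        f, np.zeros(1 + 2 * p), jac=g, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.fun


@pytest.mark.parametrize("trial", range(10))
def test_objective_matches_convex_oracle(trial):
    rng = np.random.default_rng(trial)
    X, y = make_logistic_data(
        int(rng.integers(20, 41)), int(rng.integers(2, 7)), seed=trial + 100
    )
    p = X.shape[1]
    w = rng.uniform(0.5, 2.0, p)
    lam = rng.uniform(0.05, 0.5) * lambda_max(X, y, w)
    fit = fit_weighted_l1(X, y, lam, w)
    ours = objective(X, y, fit.intercept, fit.coef, lam, w)
    oracle = convex_oracle_objective(X, y, lam, w)
    assert ours == pytest.approx(oracle, abs=1e-6)
    assert kkt_violation(X, y, fit) < 1e-6


def test_null_model_limit_at_lambda_max():
    X, y = make_logistic_data(60, 5, beta=[1, 0, 0, 0, 0], seed=1)
    lm = lambda_max(X, y)
    fit = fit_weighted_l1(X, y, lm)
    assert np.all(fit.coef == 0.0)
    ybar = y.mean()
    assert fit.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-8)
    # strictly below lambda_max the top-score variable enters
    assert np.any(fit_weighted_l1(X, y, 0.95 * lm).coef != 0)


def test_unpenalized_fit_equals_maximum_likelihood():
    import statsmodels.api as sm

    X, y = make_logistic_data(80, 4, beta=[0.8, -0.5, 0, 0.3], seed=2)
    fit = fit_weighted_l1(X, y, 0.0)
    ml = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert fit.intercept == pytest.approx(ml.params[0], abs=1e-6)
    assert fit.coef == pytest.approx(ml.params[1:], abs=1e-6)


def test_infinite_weight_excludes_variable_exactly():
    X, y = make_logistic_data(50, 2, beta=[1.0, 1.0], seed=3)
    lam = 0.1 * lambda_max(X, y, np.array([1.0, 1.0]))
    fit = fit_weighted_l1(X, y, lam, np.array([1.0, np.inf]))
    assert fit.coef[1] == 0.0
    solo = fit_weighted_l1(X[:, :1], y, lam, np.array([1.0]))
    assert fit.coef[0] == pytest.approx(solo.coef[0], abs=1e-6)


def test_lambda_max_scaling_and_duplication_properties():
    X, y = make_logistic_data(40, 3, beta=[1, 0, 0], seed=4)
    w = np.array([1.0, 2.0, 0.5])
    lm = lambda_max(X, y, w)
    assert lambda_max(X, y, 2 * w) == pytest.approx(lm / 2)
    Xdup = np.hstack([X, X[:, :1]])
    assert lambda_max(Xdup, y, np.r_[w, 1.0]) >= lm - 1e-12
    with pytest.raises(ValueError):
        lambda_max(X, y, np.full(3, np.inf))


def test_lambda_max_agrees_with_dense_grid_search():
    """lambda_max is the smallest all-zero penalty: fits on a dense grid
    are all-zero above it and not all-zero just below it."""
    X, y = make_logistic_data(50, 4, beta=[1.2, -0.8, 0, 0], seed=5)
    lm = lambda_max(X, y)
    for lam in np.linspace(1.0, 1.5, 6) * lm:
        assert np.all(fit_weighted_l1(X, y, lam).coef == 0.0)
    grid = np.linspace(0.80, 0.999, 40) * lm
    assert all(np.any(fit_weighted_l1(X, y, lam).coef != 0) for lam in grid)


def test_shrinkage_is_monotone_along_the_path():
    X, y = make_logistic_data(60, 6, beta=[1.5, -1.0, 0.5, 0, 0, 0], seed=6)
    lm = lambda_max(X, y)
    grid = lm * np.logspace(0, -3, 30)
    nnz = [int((fit_weighted_l1(X, y, lam).coef != 0).sum()) for lam in grid]
    assert all(a <= b for a, b in zip(nnz, nnz[1:]))


def test_input_validation():
    X, y = make_logistic_data(20, 2, seed=7)
    with pytest.raises(ValueError, match="binary"):
        fit_weighted_l1(X, y + 0.5, 1.0)
    with pytest.raises(ValueError, match="lambda"):
        fit_weighted_l1(X, y, -1.0)
    with pytest.raises(ValueError, match="length"):
        fit_weighted_l1(X, y, 1.0, np.ones(3))
    with pytest.raises(ValueError, match=">= 0"):
        fit_weighted_l1(X, y, 1.0, np.array([-1.0, 1.0]))


def test_cv_selects_strong_predictor_and_runs_loo():
    X, y = make_logistic_data(100, 5, beta=[2, 0, 0, 0, 0], seed=8)
    path = cv_select_lambda(X, y, k=10, grid_size=30, seed=8)
    assert path.selected_lambda in path.lambda_grid
    assert np.all(np.isfinite(path.cv_deviance))
    fit = fit_weighted_l1(X, y, path.selected_lambda)
    assert fit.coef[0] != 0.0
    # leave-one-out degenerate fold size runs without error
    Xs, ys = make_logistic_data(20, 3, beta=[1.5, 0, 0], seed=9)
    loo = cv_select_lambda(Xs, ys, k=20, grid_size=15, seed=9)
    assert np.unique(loo.fold_assignment).size == 20


def test_stratified_folds_balance_classes():
    y = np.r_[np.zeros(30), np.ones(12)]
    rng = np.random.default_rng(0)
    assign = stratified_folds(y, 6, rng)
    for f in range(6):
        assert (y[assign == f] == 1).sum() == 2
        assert (y[assign == f] == 0).sum() == 5


def test_predict_probability_basics():
    X, y = make_logistic_data(30, 3, beta=[1, 0, 0], seed=10)
    fit = fit_weighted_l1(X, y, 1e9)  # null model has p = mean(y) everywhere
    fit.intercept = 0.0
    probs = predict_probability(fit, X)
    assert np.allclose(probs, 0.5)
    fit2 = fit_weighted_l1(X, y, 0.1 * lambda_max(X, y))
    j = int(np.flatnonzero(fit2.coef)[0])
    x = X[0].copy()
    p_lo = predict_probability(fit2, x)[0]
    x[j] += 1.0
    p_hi = predict_probability(fit2, x)[0]
    assert (p_hi > p_lo) == (fit2.coef[j] > 0)
    with pytest.raises(ValueError, match="mismatch"):
        predict_probability(fit2, X[:, :2])
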