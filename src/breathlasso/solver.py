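"""Weighted-L1 (LASSO / adaptive LASSO) logistic regression from first
principles.

The estimator minimizes the penalized negative binomial log-likelihood

    L(b0, beta) = -sum_i [ y_i * eta_i - log(1 + exp(eta_i)) ]
                  + lambda * sum_j w_j * |beta_j|,      eta = b0 + X beta

with an unpenalized intercept and per-variable penalty weights ``w_j >= 0``
(``w_j = inf`` excludes variable j outright; unit weights give the plain
LASSO, inverse-preliminary-coefficient weights the adaptive LASSO).  Note
the penalty is applied against the SUM log-likelihood, the convention of
the penalized-likelihood software family this matches, so reported lambdas
are on that scale.

Optimization is proximal-Newton: an iteratively reweighted least-squares
(IRLS) quadratic majorization of the log-likelihood, solved by cyclic
coordinate descent with soft-thresholding, which produces exact zeros.
The hot loop is compiled with numba.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .qc import StandardizationParams

#: Standardized-scale coefficient cap guarding against complete separation.
BETA_CAP = 30.0
DEFAULT_TOL = 1e-7
DEFAULT_MAX_CYCLES = 10_000
_WQ_FLOOR = 1e-5


@njit(cache=False)
def _cd_kernel(X, y, lam, pw, beta, b0, tol, max_cycles, cap):
    """IRLS + cyclic coordinate descent. Mutates ``beta``; returns
    (intercept, total_cycles, converged)."""
    n, p = X.shape
    eta = b0 + X @ beta
    total = 0
    converged = False
    for _outer in range(200):
        b0_prev = b0
        beta_prev = beta.copy()

        prob = 1.0 / (1.0 + np.exp(-eta))
        wq = np.empty(n)
        z = np.empty(n)
        for i in range(n):
            pi = prob[i]
            if pi < 1e-8:
                pi = 1e-8
            elif pi > 1.0 - 1e-8:
                pi = 1.0 - 1e-8
            w = pi * (1.0 - pi)
            if w < _WQ_FLOOR:
                w = _WQ_FLOOR
            wq[i] = w
            z[i] = eta[i] + (y[i] - pi) / w
        sw = wq.sum()

        denom = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += wq[i] * X[i, j] * X[i, j]
            denom[j] = s

        r = z - eta
        inner_done = False
        while not inner_done and total < max_cycles:
            total += 1
            maxd = 0.0
            # intercept (unpenalized)
            d0 = 0.0
            for i in range(n):
                d0 += wq[i] * r[i]
            d0 /= sw
            if d0 != 0.0:
                b0 += d0
                for i in range(n):
                    r[i] -= d0
                if abs(d0) > maxd:
                    maxd = abs(d0)
            for j in range(p):
                if not np.isfinite(pw[j]):
                    if beta[j] != 0.0:
                        bj = beta[j]
                        for i in range(n):
                            r[i] += X[i, j] * bj
                        beta[j] = 0.0
                    continue
                if denom[j] <= 1e-12:
                    continue
                rho = denom[j] * beta[j]
                for i in range(n):
                    rho += wq[i] * X[i, j] * r[i]
                thr = lam * pw[j]
                # dead zone widened by a relative 1e-12 so that scores at
                # the lambda_max boundary produce exact zeros
                thr_eff = thr + 1e-12 * (1.0 + thr)
                if rho > thr_eff:
                    bnew = (rho - thr) / denom[j]
                elif rho < -thr_eff:
                    bnew = (rho + thr) / denom[j]
                else:
                    bnew = 0.0
                if bnew > cap:
                    bnew = cap
                elif bnew < -cap:
                    bnew = -cap
                d = bnew - beta[j]
                if d != 0.0:
                    for i in range(n):
                        r[i] -= X[i, j] * d
                    beta[j] = bnew
                    if abs(d) > maxd:
                        maxd = abs(d)
            if maxd < tol:
                inner_done = True

        for i in range(n):
            eta[i] = z[i] - r[i]

        outer_delta = abs(b0 - b0_prev)
        for j in range(p):
            d = abs(beta[j] - beta_prev[j])
            if d > outer_delta:
                outer_delta = d
        if inner_done and outer_delta < tol:
            converged = True
            break
        if total >= max_cycles:
            break
    return b0, total, converged


@dataclass
class PenalizedFit:
    """A single weighted-L1 logistic fit on the standardized scale."""

    intercept: float
    coef: np.ndarray
    lambda_: float
    penalty_weights: np.ndarray
    converged: bool
    n_iterations: int
    variables: tuple[str, ...] | None = None

    def nonzero_indices(self) -> np.ndarray:
        return np.flatnonzero(self.coef)

    def nonzero_variables(self) -> list[str]:
        if self.variables is None:
            return [str(j) for j in self.nonzero_indices()]
        return [self.variables[j] for j in self.nonzero_indices()]

    def coefficients_original_scale(
        self, params: StandardizationParams
    ) -> tuple[float, np.ndarray]:
        """Back-transform to original units: beta_orig = beta_std / scale,
        intercept_orig = intercept - sum(beta_std * center / scale)."""
        scale = params.scale.to_numpy(float)
        center = params.center.to_numpy(float)
        coef_orig = self.coef / scale
        b0_orig = self.intercept - float(np.sum(self.coef * center / scale))
        return b0_orig, coef_orig

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coef": [float(b) for b in self.coef],
            "lambda": float(self.lambda_),
            "penalty_weights": [
                None if not math.isfinite(w) else float(w)
                for w in self.penalty_weights
            ],
            "converged": bool(self.converged),
            "n_iterations": int(self.n_iterations),
            "variables": list(self.variables) if self.variables else None,
        }


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-d with one row per element of y")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary (0/1)")
    return X, y


def fit_weighted_l1(
    X: np.ndarray,
    y: np.ndarray,
    lambda_: float,
    weights: np.ndarray | None = None,
    *,
    variables: tuple[str, ...] | None = None,
    tol: float = DEFAULT_TOL,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    beta0: np.ndarray | None = None,
    intercept0: float | None = None,
    cap: float = BETA_CAP,
) -> PenalizedFit:
    """Fit the weighted-L1 penalized logistic regression.

    ``X`` is expected standardized (the penalty is only meaningful on a
    common scale); ``weights`` default to 1 for every variable and may
    contain ``inf`` to hard-exclude variables.  Deterministic given inputs.
    """
    X, y = _validate_xy(X, y)
    p = X.shape[1]
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    pw = np.ones(p) if weights is None else np.asarray(weights, dtype=np.float64)
    if pw.shape != (p,):
        raise ValueError("weights length must equal the number of variables")
    if (pw < 0).any():
        raise ValueError("penalty weights must be >= 0")
    beta = (
        np.zeros(p) if beta0 is None else np.array(beta0, dtype=np.float64, copy=True)
    )
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    b0 = math.log(ybar / (1.0 - ybar)) if intercept0 is None else float(intercept0)
    b0, n_iter, converged = _cd_kernel(
        X, y, float(lambda_), pw, beta, b0, float(tol), int(max_cycles), float(cap)
    )
    if not converged:
        warnings.warn(
            f"coordinate descent did not converge in {max_cycles} cycles",
            stacklevel=2,
        )
    if np.any(np.abs(beta) >= cap):
        warnings.warn(
            "coefficient(s) hit the separation cap; data may be separable",
            stacklevel=2,
        )
    return PenalizedFit(
        intercept=float(b0),
        coef=beta,
        lambda_=float(lambda_),
        penalty_weights=pw,
        converged=bool(converged),
        n_iterations=int(n_iter),
        variables=variables,
    )


def objective(
    X: np.ndarray,
    y: np.ndarray,
    intercept: float,
    coef: np.ndarray,
    lambda_: float,
    weights: np.ndarray | None = None,
) -> float:
    """Penalized negative log-likelihood (sum scale) of a candidate solution."""
    X, y = _validate_xy(X, y)
    pw = np.ones(X.shape[1]) if weights is None else np.asarray(weights, float)
    eta = intercept + X @ coef
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    finite = np.isfinite(pw)
    pen = float(lambda_ * np.sum(pw[finite] * np.abs(coef[finite])))
    if np.any(~finite & (coef != 0)):
        return math.inf
    return nll + pen


def lambda_max(
    X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Smallest penalty at which every penalized coefficient is zero.

    At the null model the intercept equals logit(mean(y)); the score of
    variable j is ``x_j . (y - mean(y))``, so the all-zero solution is
    stationary iff ``lambda >= max_j |x_j . (y - ybar)| / w_j`` over
    finite-weight variables.  Exact when columns of X are centered.
    """
    X, y = _validate_xy(X, y)
    p = X.shape[1]
    pw = np.ones(p) if weights is None else np.asarray(weights, float)
    finite = np.isfinite(pw)
    if not finite.any():
        raise ValueError("lambda_max undefined: all penalty weights infinite")
    grad = X.T @ (y - y.mean())
    with np.errstate(divide="ignore"):
        vals = np.abs(grad[finite]) / pw[finite]
    return float(np.max(vals))


def kkt_violation(X: np.ndarray, y: np.ndarray, fit: PenalizedFit) -> float:
    """Maximum violation of the stationarity (KKT) conditions of a fit.

    For zero coefficients the score must satisfy |g_j| <= lambda * w_j; for
    nonzero ones g_j + lambda * w_j * sign(beta_j) = 0.  Returns the largest
    violation across variables and the intercept (0 for an exact optimum).
    """
    X, y = _validate_xy(X, y)
    eta = fit.intercept + X @ fit.coef
    prob = 1.0 / (1.0 + np.exp(-eta))
    grad = -(X.T @ (y - prob))
    viol = abs(float(np.sum(prob - y)))  # intercept stationarity
    for j in range(X.shape[1]):
        w = fit.penalty_weights[j]
        if not np.isfinite(w):
            continue
        if fit.coef[j] == 0.0:
            v = max(0.0, abs(grad[j]) - fit.lambda_ * w)
        else:
            v = abs(grad[j] + fit.lambda_ * w * np.sign(fit.coef[j]))
        viol = max(viol, v)
    return viol


@dataclass
class CVPath:
    """Cross-validation path over a descending lambda grid."""

    lambda_grid: np.ndarray
    cv_deviance: np.ndarray  # mean held-out binomial deviance per lambda
    fold_assignment: np.ndarray
    selected_lambda: float

    def to_dict(self) -> dict:
        return {
            "lambda_grid": [float(v) for v in self.lambda_grid],
            "cv_deviance": [float(v) for v in self.cv_deviance],
            "selected_lambda": float(self.selected_lambda),
        }


def stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Outcome-stratified fold assignment (values in 0..k-1)."""
    y = np.asarray(y)
    assign = np.empty(y.size, dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        offset = int(rng.integers(k))
        assign[idx] = (np.arange(idx.size) + offset) % k
    return assign


def _deviance(eta: np.ndarray, y: np.ndarray) -> float:
    prob = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    k: int = 50,
    grid_size: int = 50,
    seed: int = 0,
    *,
    tol: float = DEFAULT_TOL,
    max_cycles: int = DEFAULT_MAX_CYCLES,
) -> CVPath:
    """Select lambda by k-fold cross-validated binomial deviance.

    The grid is 50 log-spaced values (by default) spanning three decades
    below ``lambda_max``; folds are stratified by outcome and seeded; the
    path is fit warm-started from large to small lambda.  Ties in the mean
    CV deviance resolve to the smallest lambda among the minimizers (the
    denser model).  ``k`` is capped at ``n``; ``k = n`` is leave-one-out.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    k_eff = min(k, n)
    if k_eff < 2:
        raise ValueError("need at least 2 folds")
    pw = np.ones(p) if weights is None else np.asarray(weights, float)
    lmax = max(lambda_max(X, y, pw), 1e-8)
    grid = lmax * np.logspace(0.0, -3.0, grid_size)

    rng = np.random.default_rng(seed)
    assign = stratified_folds(y, k_eff, rng)
    for _attempt in range(2):
        ok = all(
            np.unique(y[assign != f]).size == 2 for f in range(k_eff)
        )
        if ok:
            break
        assign = stratified_folds(y, k_eff, rng)
    else:
        raise ValueError("a fold's training set contains a single class")

    total_dev = np.zeros(grid_size)
    for f in range(k_eff):
        test = assign == f
        train = ~test
        Xtr = np.ascontiguousarray(X[train])
        ytr = y[train]
        Xte = X[test]
        yte = y[test]
        beta = np.zeros(p)
        ybar = float(np.clip(ytr.mean(), 1e-12, 1 - 1e-12))
        b0 = math.log(ybar / (1 - ybar))
        for li, lam in enumerate(grid):
            b0, _, _ = _cd_kernel(
                Xtr, ytr, float(lam), pw, beta, b0, tol, max_cycles, BETA_CAP
            )
            total_dev[li] += _deviance(b0 + Xte @ beta, yte)
    cv_dev = total_dev / n
    minimizers = np.flatnonzero(cv_dev == cv_dev.min())
    sel = int(minimizers.max())  # grid descends: max index = smallest lambda
    return CVPath(
        lambda_grid=grid,
        cv_deviance=cv_dev,
        fold_assignment=assign,
        selected_lambda=float(grid[sel]),
    )


def predict_probability(
    fit: PenalizedFit,
    X,
    params: StandardizationParams | None = None,
) -> np.ndarray:
    """Predicted case probability for rows of ``X``.

    If ``params`` is given, ``X`` is on the original (ppb / years / 0-1)
    scale and is standardized first; otherwise it must already be on the
    standardized scale of the fit.
    """
    if params is not None:
        if fit.variables is None:
            raise ValueError("fit has no variable names to align with params")
        import pandas as pd

        Xdf = pd.DataFrame(X, columns=list(fit.variables)) if not isinstance(
            X, pd.DataFrame
        ) else X
        missing = [v for v in fit.variables if v not in Xdf.columns]
        if missing:
            raise ValueError(f"missing variables: {missing}")
        Z = params.subset(list(fit.variables)).transform(Xdf).to_numpy(float)
    else:
        Z = np.asarray(X, dtype=float)
        if Z.ndim == 1:
            Z = Z[None, :]
        if Z.shape[1] != fit.coef.size:
            raise ValueError("variable mismatch between fit and input")
    eta = fit.intercept + Z @ fit.coef
    return 1.0 / (1.0 + np.exp(-eta))
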