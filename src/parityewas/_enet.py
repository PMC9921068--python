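"""Elastic-net-penalized logistic regression by proximal gradient
descent (FISTA), with per-feature penalty factors.

The objective matches the glmnet parameterisation:

    (1/n) sum_i log(1 + exp(-y_i eta_i))
        + lambda * sum_j pf_j * ( alpha |w_j| + (1 - alpha)/2 w_j^2 )

with eta = b + X w. The intercept and any feature with penalty factor 0
are unpenalized, which is how adjustment covariates (cell fractions,
smoking biomarker) are carried through feature selection without being
shrunk.
"""
from __future__ import annotations

import numpy as np


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log1pexp(z):
    out = np.empty_like(z)
    big = z > 30
    out[big] = z[big]
    out[~big] = np.log1p(np.exp(z[~big]))
    return out


def enet_logistic(X: np.ndarray, y: np.ndarray, lam: float, alpha: float,
                  penalty_factor: np.ndarray | None = None,
                  w0: np.ndarray | None = None, b0: float = 0.0,
                  tol: float = 1e-8, max_iter: int = 5000,
                  xnorm: float | None = None):
    """Fit one penalized logistic regression.

    X is assumed standardized by the caller; y is 0/1. Returns
    (intercept, coefficients).
    """
    n, p = X.shape
    y = np.asarray(y, float)
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    w = np.zeros(p) if w0 is None else w0.copy()
    b = float(b0)

    # Lipschitz constant of the smooth part
    if xnorm is not None:
        top = xnorm
    else:
        top = np.linalg.norm(X, 2) if min(n, p) <= 400 else _power_norm(X)
    L = (top ** 2 / (4.0 * n) + lam * (1 - alpha) * pf.max()
         + 0.25)  # +0.25 covers the intercept coordinate
    step = 1.0 / L
    thresh = step * lam * alpha * pf

    zw, zb = w.copy(), b
    t_mom = 1.0
    for _ in range(max_iter):
        eta = X @ zw + zb
        g = _sigmoid(eta) - y
        grad_w = X.T @ g / n + lam * (1 - alpha) * pf * zw
        grad_b = g.mean()
        w_new = zw - step * grad_w
        w_new = np.sign(w_new) * np.maximum(np.abs(w_new) - thresh, 0.0)
        b_new = zb - step * grad_b
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2)) / 2.0
        mom = (t_mom - 1.0) / t_new
        zw = w_new + mom * (w_new - w)
        zb = b_new + mom * (b_new - b)
        delta = max(np.max(np.abs(w_new - w)), abs(b_new - b))
        w, b, t_mom = w_new, b_new, t_new
        if delta < tol:
            break
    return b, w


def _power_norm(X, iters: int = 50):
    v = np.random.default_rng(0).normal(size=X.shape[1])
    v /= np.linalg.norm(v)
    for _ in range(iters):
        u = X @ v
        v = X.T @ u
        nv = np.linalg.norm(v)
        if nv == 0:
            return 0.0
        v /= nv
    return np.sqrt(nv)


def lambda_path(X: np.ndarray, y: np.ndarray, alpha: float,
                penalty_factor: np.ndarray | None = None,
                n_lambda: int = 20, eps: float = 1e-3) -> np.ndarray:
    """glmnet-style decreasing log-spaced lambda grid.

    lambda_max is the smallest lambda at which every penalized
    coefficient is zero at the null (intercept-only) solution.
    """
    n, p = X.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    ybar = y.mean()
    score = np.abs(X.T @ (y - ybar)) / n
    pen = pf > 0
    denom = max(alpha, 0.001)
    lam_max = float((score[pen] / (pf[pen] * denom)).max()) if pen.any() else 1.0
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """Mean binomial deviance, 2/n * sum of negative log-likelihoods."""
    y = np.asarray(y, float)
    return float(2.0 * np.mean(_log1pexp(eta) - y * eta))


def fit_path(X: np.ndarray, y: np.ndarray, alpha: float,
             lambdas: np.ndarray, penalty_factor: np.ndarray | None = None,
             tol: float = 1e-7, max_iter: int = 2000,
             xnorm: float | None = None) -> list:
    """Warm-started fits along a decreasing lambda grid.

    Returns a list of (lambda, intercept, coefficients)."""
    if xnorm is None:
        n, p = X.shape
        xnorm = (np.linalg.norm(X, 2) if min(n, p) <= 400 else _power_norm(X))
    w = np.zeros(X.shape[1])
    b = float(np.log(max(y.mean(), 1e-12) / max(1 - y.mean(), 1e-12)))
    out = []
    for lam in lambdas:
        b, w = enet_logistic(X, y, lam, alpha, penalty_factor,
                             w0=w, b0=b, tol=tol, max_iter=max_iter,
                             xnorm=xnorm)
        out.append((float(lam), b, w.copy()))
    return out
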