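"""Multi-factor CpG panel selection: cross-validation-tuned elastic-net
logistic regression of parity on methylation features, with
variable-importance ranking on a 0–100 scale.

Tuning sweeps the mixing parameter alpha over {0, 0.1, ..., 1} and, for
each alpha, a decreasing lambda grid, scoring mean 10-fold
cross-validated binomial deviance; the final model is refit on a
stratified 70/30 training split at the tuned (alpha, lambda).
Adjustment covariates (cell-type fractions, smoking biomarker) may be
supplied separately and enter the model unpenalized.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

from ._enet import binomial_deviance, enet_logistic, fit_path, lambda_path


@dataclass
class ElasticNetPanel:
    alpha: float
    lam: float
    selected: pd.DataFrame           # feature, coefficient, importance
    train_ids: list
    test_ids: list
    train_deviance: float
    test_deviance: float
    cv_trace: pd.DataFrame | None = None
    covariate_coefs: dict = field(default_factory=dict)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def _design(features: pd.DataFrame, covariates: pd.DataFrame | None):
    names = list(features.columns)
    X = features.values.astype(float)
    pf = np.ones(X.shape[1])
    if covariates is not None:
        X = np.column_stack([X, covariates.values.astype(float)])
        names += list(covariates.columns)
        pf = np.concatenate([pf, np.zeros(covariates.shape[1])])
    return X, names, pf


def tune_elastic_net(features: pd.DataFrame, labels: pd.Series, seed: int = 0,
                     covariates: pd.DataFrame | None = None,
                     alphas: np.ndarray | None = None, n_folds: int = 10,
                     n_lambda: int = 20, rule: str = "1se"):
    """Grid search (alpha, lambda) by 10-fold CV binomial deviance.

    Returns (alpha, lambda, trace) where trace records the mean CV
    deviance per grid point. Reproducible given ``seed``. ``rule="min"``
    takes the grid point with minimum mean CV deviance outright;
    the default one-standard-error rule picks, among grid points whose
    mean deviance is within one standard error of that minimum, the most
    regularized one (largest alpha, then largest lambda), so that a
    signal-free input yields an empty or near-empty panel rather than a
    dense ridge fit.
    """
    y = np.asarray(labels, float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if alphas is None:
        alphas = np.round(np.linspace(0.0, 1.0, 11), 2)
    X_raw, _, pf = _design(features, covariates)
    Xs, _, _ = _standardize(X_raw)
    folds = list(KFold(n_splits=n_folds, shuffle=True,
                       random_state=seed).split(Xs))
    # standardized training matrices and their spectral norms, once per fold
    fold_data = []
    for tr, va in folds:
        Xtr, mu, sd = _standardize(X_raw[tr])
        Xva = (X_raw[va] - mu) / sd
        fold_data.append((Xtr, Xva, tr, va, float(np.linalg.norm(Xtr, 2))))
    rows = []
    per_alpha = []  # (min mean deviance, alpha, lambda chosen by rule)
    for alpha in alphas:
        lambdas = lambda_path(Xs, y, alpha, pf, n_lambda=n_lambda)
        dev = np.zeros((len(folds), len(lambdas)))
        for f, (Xtr, Xva, tr, va, xnorm) in enumerate(fold_data):
            path = fit_path(Xtr, y[tr], alpha, lambdas, pf,
                            tol=1e-5, max_iter=300, xnorm=xnorm)
            for i, (_, b, w) in enumerate(path):
                dev[f, i] = binomial_deviance(y[va], Xva @ w + b)
        mean = dev.mean(axis=0)
        se = dev.std(axis=0, ddof=1) / np.sqrt(len(folds))
        for lam, d, s in zip(lambdas, mean, se):
            rows.append({"alpha": float(alpha), "lambda": float(lam),
                         "cv_deviance": float(d), "cv_se": float(s)})
        i_min = int(mean.argmin())
        if rule == "min":
            lam_rule = lambdas[i_min]
        else:
            cutoff = mean[i_min] + se[i_min]
            lam_rule = lambdas[mean <= cutoff].max()
        per_alpha.append({"dev": float(mean[i_min]), "se": float(se[i_min]),
                          "alpha": float(alpha), "lam": float(lam_rule)})
    trace = pd.DataFrame(rows)
    best = min(per_alpha, key=lambda r: r["dev"])
    if rule == "min":
        return best["alpha"], best["lam"], trace
    # among alpha values statistically tied with the best, prefer the
    # sparsest (largest alpha) family, at its own one-SE lambda
    cutoff = best["dev"] + best["se"]
    tied = [r for r in per_alpha if r["dev"] <= cutoff]
    chosen = max(tied, key=lambda r: r["alpha"])
    return chosen["alpha"], chosen["lam"], trace


def select_features(features: pd.DataFrame, labels: pd.Series, alpha: float,
                    lam: float, split_seed: int = 0,
                    covariates: pd.DataFrame | None = None,
                    train_fraction: float = 0.7,
                    cv_trace: pd.DataFrame | None = None) -> ElasticNetPanel:
    """Fit the tuned model on a stratified 70/30 split and rank features.

    Importance is 100 * |standardized coefficient| / max over selected
    features, so the top feature scores 100. Held-out deviance on the
    test split is reported alongside the training deviance.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    y = np.asarray(labels, float)
    ids = np.asarray(features.index)
    train_idx, test_idx = train_test_split(
        np.arange(len(y)), train_size=train_fraction, stratify=y,
        random_state=split_seed)
    X_raw, names, pf = _design(features, covariates)
    Xtr, mu, sd = _standardize(X_raw[train_idx])
    Xte = (X_raw[test_idx] - mu) / sd
    ytr, yte = y[train_idx], y[test_idx]

    if lam > 0:
        # warm-started approach from above stabilizes the solution
        lambdas = lambda_path(Xtr, ytr, alpha, pf)
        lambdas = np.concatenate([lambdas[lambdas > lam], [lam]])
        path = fit_path(Xtr, ytr, alpha, lambdas, pf)
        _, b, w = path[-1]
    else:
        b, w = enet_logistic(Xtr, ytr, 0.0, alpha, pf, tol=1e-10,
                             max_iter=50_000)

    n_feat = features.shape[1]
    coefs = pd.Series(w[:n_feat], index=features.columns)
    nonzero = coefs[coefs != 0.0]
    if len(nonzero):
        imp = 100.0 * nonzero.abs() / nonzero.abs().max()
    else:
        imp = nonzero
    selected = pd.DataFrame({
        "feature": nonzero.index, "coefficient": nonzero.values,
        "importance": imp.values,
    }).sort_values("importance", ascending=False).reset_index(drop=True)
    covariate_coefs = dict(zip(names[n_feat:], w[n_feat:]))
    return ElasticNetPanel(
        alpha=float(alpha), lam=float(lam), selected=selected,
        train_ids=list(ids[train_idx]), test_ids=list(ids[test_idx]),
        train_deviance=binomial_deviance(ytr, Xtr @ w + b),
        test_deviance=binomial_deviance(yte, Xte @ w + b),
        cv_trace=cv_trace, covariate_coefs=covariate_coefs)


def panel_dmp_overlap(panel: ElasticNetPanel, dmp_ids) -> list:
    """Panel features that were also called as DMPs (set intersection)."""
    return sorted(set(panel.selected["feature"]) & set(dmp_ids))
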