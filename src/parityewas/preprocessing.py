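"""Sample/probe quality control, BMIQ normalization, batch-effect scan
and empirical-Bayes batch correction.

Filter order follows the analysis pipeline: low-quality samples first
(failed-to-successful detection ratio > 0.1), then probes (detection
p > 0.01 in any retained sample; bead count < 3 in >= 5% of samples;
non-CpG, SNP-related, non-autosomal and multi-hit probes). BMIQ fits a
three-state beta mixture per sample and quantile-maps the type-II probe
distribution onto the type-I fit. Batch factors are screened by testing
top right singular vectors of the probe-centered matrix against each
candidate factor, and corrected with a parametric empirical-Bayes
location/scale adjustment applied sequentially per batch variable.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import clip_beta

PROBE_REASONS = ("low_quality", "bead_count", "non_cpg", "snp_related",
                 "non_autosomal", "multi_hit")
AUTOSOMES = {str(c) for c in range(1, 23)}


class EmptyCohortError(RuntimeError):
    """All samples failed quality control."""


@dataclass
class QcReport:
    excluded_samples: list = field(default_factory=list)   # (id, reason)
    excluded_probes: list = field(default_factory=list)    # (id, reason)
    n_probes_before: int = 0
    n_probes_after: int = 0

    @property
    def retained_fraction(self) -> float:
        """Percent of probes retained."""
        if self.n_probes_before == 0:
            return 100.0
        return 100.0 * self.n_probes_after / self.n_probes_before

    def probes_by_reason(self) -> dict:
        out: dict = {}
        for pid, reason in self.excluded_probes:
            out.setdefault(reason, []).append(pid)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = ([("sample", sid, r) for sid, r in self.excluded_samples]
                + [("probe", pid, r) for pid, r in self.excluded_probes])
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def retention_percent(n_retained: float, n_total: float) -> float:
    """Probe retention as a percentage of the input probe count."""
    return 100.0 * n_retained / n_total


def filter_samples(beta: pd.DataFrame, detection_p: pd.DataFrame,
                   detection_threshold: float = 0.01,
                   ratio_threshold: float = 0.1):
    """Drop samples whose failed/successful probe ratio exceeds 0.1.

    A probe fails within a sample when its detection p exceeds 0.01; the
    exclusion rule is strict (> 0.1), so a sample exactly at 0.1 stays.
    """
    detection_p = detection_p.loc[beta.index, beta.columns]
    failed = (detection_p.values > detection_threshold).sum(axis=0)
    successful = detection_p.shape[0] - failed
    with np.errstate(divide="ignore"):
        ratio = np.where(successful > 0, failed / np.maximum(successful, 1),
                         np.inf)
    bad = ratio > ratio_threshold
    report = QcReport(
        excluded_samples=[(sid, "low_quality")
                          for sid in beta.columns[bad]],
        n_probes_before=beta.shape[0], n_probes_after=beta.shape[0])
    if bad.all():
        raise EmptyCohortError("every sample failed the detection-ratio filter")
    return beta.loc[:, ~bad], report


def filter_probes(beta: pd.DataFrame, detection_p: pd.DataFrame,
                  bead_counts: pd.DataFrame, annotation: pd.DataFrame,
                  detection_threshold: float = 0.01, bead_min: int = 3,
                  bead_fraction: float = 0.05) -> tuple:
    """Apply the probe exclusion rules with first-matching reasons.

    Reason precedence: low_quality (detection p > 0.01 in any retained
    sample), bead_count (< 3 beads in >= 5% of samples), non_cpg,
    snp_related, non_autosomal (chromosome outside 1..22), multi_hit.
    """
    missing = beta.index.difference(annotation.index)
    if len(missing):
        raise KeyError(
            f"annotation missing {len(missing)} probes present in beta "
            f"(first: {missing[0]!r})")
    detection_p = detection_p.loc[beta.index, beta.columns]
    bead_counts = bead_counts.loc[beta.index, beta.columns]
    anno = annotation.loc[beta.index]

    n = beta.shape[1]
    crit = {
        "low_quality": (detection_p.values > detection_threshold).any(axis=1),
        "bead_count": ((bead_counts.values < bead_min).sum(axis=1) / n
                       >= bead_fraction),
        "non_cpg": anno["non_cpg"].values.astype(bool),
        "snp_related": anno["snp_related"].values.astype(bool),
        "non_autosomal": ~anno["chrom"].astype(str).isin(AUTOSOMES).values,
        "multi_hit": anno["multi_hit"].values.astype(bool),
    }
    reason = np.full(beta.shape[0], "", dtype=object)
    for name in PROBE_REASONS:
        hit = crit[name] & (reason == "")
        reason[hit] = name
    excluded = reason != ""
    report = QcReport(
        excluded_probes=[(pid, r) for pid, r in
                         zip(beta.index[excluded], reason[excluded])],
        n_probes_before=beta.shape[0],
        n_probes_after=int((~excluded).sum()))
    return beta.loc[~excluded], report


# --------------------------------------------------------------------------
# BMIQ
# --------------------------------------------------------------------------

def _beta_mixture_em(x: np.ndarray, tol: float = 1e-4, max_iter: int = 500,
                     init_means=(0.1, 0.5, 0.9)):
    """EM fit of a 3-state (unmeth/hemi/meth) beta mixture.

    Beta parameters are updated by responsibility-weighted method of
    moments. Returns (weights, a, b, converged).
    """
    x = np.clip(x, 1e-3, 1 - 1e-3)
    k = len(init_means)
    w = np.full(k, 1.0 / k)
    a = np.empty(k)
    b = np.empty(k)
    for s, m in enumerate(init_means):
        v = 0.02
        c = m * (1 - m) / v - 1
        a[s], b[s] = m * c, (1 - m) * c
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        dens = np.stack([w[s] * stats.beta.pdf(x, a[s], b[s])
                         for s in range(k)])
        tot = dens.sum(axis=0)
        tot[tot <= 0] = 1e-300
        resp = dens / tot
        ll = float(np.log(tot).sum())
        nk = resp.sum(axis=1)
        w = nk / x.size
        for s in range(k):
            if nk[s] < 1e-8:
                continue
            m = float(resp[s] @ x / nk[s])
            v = float(resp[s] @ (x - m) ** 2 / nk[s])
            m = min(max(m, 1e-3), 1 - 1e-3)
            v = max(min(v, m * (1 - m) * 0.999), 1e-6)
            c = m * (1 - m) / v - 1
            a[s] = max(m * c, 0.1)
            b[s] = max((1 - m) * c, 0.1)
        if abs(ll - ll_old) < tol * (1 + abs(ll_old if np.isfinite(ll_old) else 0)):
            converged = True
            break
        ll_old = ll
    order = np.argsort(a / (a + b))
    return w[order], a[order], b[order], converged


def bmiq_normalize(beta: pd.DataFrame, annotation: pd.DataFrame,
                   max_fit_probes: int = 5000, tol: float = 1e-4,
                   max_iter: int = 500, random_state: int = 0) -> pd.DataFrame:
    """Per-sample BMIQ: map type-II probe values onto the type-I mixture.

    For each sample a 3-state beta mixture is fit (by EM) separately to
    the type-I and type-II probe distributions; each type-II value is
    assigned to its maximum-posterior state and mapped through that
    state's beta CDF onto the corresponding type-I state's quantile
    function. The mapped values are then re-assigned in rank order so
    the within-sample ordering of type-II probes is preserved exactly.
    Type-I values pass through unchanged. A sample whose EM does not
    converge is left unadjusted, with a warning.
    """
    design = annotation.loc[beta.index, "design_type"].astype(str)
    type1 = (design == "I").values
    type2 = (design == "II").values
    if not type1.any() or not type2.any():
        raise ValueError("both probe design types must be present for BMIQ")
    rng = np.random.default_rng(random_state)
    out = beta.copy()
    x1_all = beta.values[type1]
    x2_all = beta.values[type2]
    for j, sample in enumerate(beta.columns):
        x1 = x1_all[:, j]
        x2 = x2_all[:, j]
        f1 = x1 if x1.size <= max_fit_probes else rng.choice(
            x1, max_fit_probes, replace=False)
        f2 = x2 if x2.size <= max_fit_probes else rng.choice(
            x2, max_fit_probes, replace=False)
        w1, a1, b1, ok1 = _beta_mixture_em(f1, tol=tol, max_iter=max_iter)
        w2, a2, b2, ok2 = _beta_mixture_em(f2, tol=tol, max_iter=max_iter)
        if not (ok1 and ok2):
            warnings.warn(f"BMIQ EM did not converge for sample {sample!r}; "
                          "values left unadjusted", UserWarning)
            continue
        xc = np.clip(x2, 1e-3, 1 - 1e-3)
        dens = np.stack([w2[s] * stats.beta.pdf(xc, a2[s], b2[s])
                         for s in range(3)])
        state = dens.argmax(axis=0)
        mapped = np.empty_like(xc)
        for s in range(3):
            m = state == s
            if not m.any():
                continue
            q = stats.beta.cdf(xc[m], a2[s], b2[s])
            q = np.clip(q, 1e-12, 1 - 1e-12)
            mapped[m] = stats.beta.ppf(q, a1[s], b1[s])
        # preserve the original within-sample rank order exactly
        order = np.argsort(x2, kind="mergesort")
        result = np.empty_like(mapped)
        result[order] = np.sort(mapped)
        out.values[type2, j] = clip_beta(result, 1e-3)
    return out


# --------------------------------------------------------------------------
# SVD batch scan and ComBat
# --------------------------------------------------------------------------

def svd_batch_scan(beta: pd.DataFrame, sample_sheet: pd.DataFrame,
                   factors: list | None = None, k: int = 10,
                   p_threshold: float = 0.01) -> pd.DataFrame:
    """Associate top right singular vectors with candidate batch factors.

    Probes are mean-centered; each of the top-k right singular vectors is
    tested against each factor — a Kruskal–Wallis k-sample test for
    categorical factors, a linear-model F-test (via Pearson correlation)
    for continuous ones. Constant or all-unique categorical factors are
    skipped with a warning.
    """
    if factors is None:
        factors = [c for c in ("Plate", "Chip", "Position") if c in sample_sheet]
    k = min(k, min(beta.shape) - 1)
    X = beta.values - beta.values.mean(axis=1, keepdims=True)
    _, sv, vt = np.linalg.svd(X, full_matrices=False)
    rows = []
    sheet = sample_sheet.loc[beta.columns]
    for name in factors:
        col = sheet[name]
        categorical = (not pd.api.types.is_numeric_dtype(col)
                       or col.nunique() <= 2)
        if col.nunique() <= 1:
            warnings.warn(f"factor {name!r} is constant; skipped", UserWarning)
            continue
        if categorical and col.nunique() >= len(col):
            warnings.warn(f"factor {name!r} has one level per sample; skipped",
                          UserWarning)
            continue
        for comp in range(k):
            v = vt[comp]
            if categorical:
                groups = [v[(col == lev).values] for lev in col.unique()]
                groups = [g for g in groups if g.size > 0]
                try:
                    _, p = stats.kruskal(*groups)
                except ValueError:
                    p = 1.0
            else:
                _, p = stats.pearsonr(v, col.values.astype(float))
            rows.append({"component_index": comp + 1, "factor_name": name,
                         "association_p": float(p),
                         "significant": bool(p < p_threshold)})
    return pd.DataFrame(rows, columns=["component_index", "factor_name",
                                       "association_p", "significant"])


def _combat_one(X: np.ndarray, batch: np.ndarray,
                design: np.ndarray | None = None,
                max_iter: int = 100, tol: float = 1e-4) -> np.ndarray:
    """Parametric empirical-Bayes location/scale adjustment, one variable.

    ``design`` holds biological covariates to protect (e.g. the group
    indicator), entered alongside the batch indicators when the data are
    standardized so that batch-effect estimates are not contaminated by
    covariate signal.
    """
    levels, inv = np.unique(batch, return_inverse=True)
    if len(levels) < 2:
        return X
    counts = np.bincount(inv)
    if (counts < 2).any():
        bad = levels[counts < 2][0]
        raise ValueError(f"batch level {bad!r} has fewer than 2 samples")
    G, n = X.shape
    k = len(levels)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inv] = 1.0
    D = onehot if design is None else np.column_stack([onehot, design])
    B = X @ D @ np.linalg.pinv(D.T @ D)          # probes x params
    # batch-size-weighted grand mean plus covariate contribution
    grand = B[:, :k] @ (counts / n)
    stand_mean = grand[:, None] + (0 if design is None
                                   else B[:, k:] @ design.T)
    resid = X - B @ D.T
    pooled_var = (resid ** 2).sum(axis=1) / n
    pooled_sd = np.sqrt(np.maximum(pooled_var, 1e-12))
    Z = (X - stand_mean) / pooled_sd[:, None]

    Xadj = np.empty_like(Z)
    for i in range(len(levels)):
        m = inv == i
        ni = counts[i]
        g_hat = Z[:, m].mean(axis=1)
        d_hat = Z[:, m].var(axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        # hyperpriors by method of moments
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        v, s2 = d_hat.mean(), d_hat.var(ddof=1)
        lam = (v ** 2 + 2 * s2) / s2 if s2 > 0 else 1e12
        theta = (v ** 3 + v * s2) / s2 if s2 > 0 else v
        g_star, d_star = g_hat.copy(), d_hat.copy()
        if t2 > 0:
            for _ in range(max_iter):
                g_new = (ni * t2 * g_hat + d_star * g_bar) / (ni * t2 + d_star)
                ss = ((Z[:, m] - g_new[:, None]) ** 2).sum(axis=1)
                d_new = (theta + 0.5 * ss) / (ni / 2 + lam - 1)
                d_new = np.maximum(d_new, 1e-12)
                change = max(np.abs(g_new - g_star).max(),
                             np.abs(d_new - d_star).max())
                g_star, d_star = g_new, d_new
                if change < tol:
                    break
        Xadj[:, m] = (Z[:, m] - g_star[:, None]) / np.sqrt(d_star)[:, None]
    return Xadj * pooled_sd[:, None] + stand_mean


def combat_adjust(beta: pd.DataFrame, batch_labels,
                  covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Empirical-Bayes batch correction, sequential over batch variables.

    ``batch_labels`` is a Series (one variable) or DataFrame whose
    columns are applied in order (Plate, then chip, then position when
    using the conventional labels). ``covariates`` (numeric, per sample)
    are protected biological signal — typically the group indicator. A
    variable with a single level is a no-op. Output is clipped back into
    (0, 1).
    """
    if isinstance(batch_labels, pd.Series):
        batch_labels = batch_labels.to_frame()
    design = None
    if covariates is not None:
        design = covariates.loc[beta.columns].values.astype(float)
        design = design - design.mean(axis=0)
    X = beta.values.astype(float).copy()
    for col in batch_labels.columns:
        lab = batch_labels.loc[beta.columns, col].values
        X = _combat_one(X, lab, design)
    return pd.DataFrame(clip_beta(X), index=beta.index, columns=beta.columns)
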