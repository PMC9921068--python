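"""Whole-blood EWAS: covariate-adjusted per-CpG models, DMP calling,
region (DMR) calling from the DMP list, and the matched-pair
sensitivity scan.

Sign convention throughout: Δmeth = parous group mean beta minus
nulligravida group mean beta, so positive values mean hypermethylation
in the parous group.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import clip_beta

FRACTION_COVARIATES = ("CD4T", "CD8T", "NK", "B", "Mono")  # Gran = reference


def beta_to_m(beta: pd.DataFrame) -> pd.DataFrame:
    """M-values: log2(beta / (1 - beta)) after clipping to [1e-6, 1-1e-6]."""
    b = clip_beta(np.asarray(beta, dtype=float))
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    p = np.power(2.0, np.asarray(m, dtype=float))
    return p / (1.0 + p)


def _check_full_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the involved columns via near-zero singular directions
        _, sv, vt = np.linalg.svd(X, full_matrices=False)
        small = vt[np.abs(sv) < 1e-8 * max(sv.max(), 1.0)]
        involved = set()
        for row in small:
            involved.update(np.asarray(names)[np.abs(row) > 1e-6])
        if not involved:
            involved = set(names)
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(sorted(involved)))


def ols_by_probe(Y: np.ndarray, X: np.ndarray, term: int,
                 names: list | None = None):
    """Vectorized per-probe OLS of the rows of Y on the shared design X.

    Returns (coef, se, p) for column ``term`` of the design, computed
    from the classical normal-equations solution with the per-probe
    residual variance on n - p degrees of freedom.
    """
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    _check_full_rank(X, names)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtX_inv                           # probes x p
    resid = Y - B @ X.T
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[term, term], 1e-300))
    coef = B[:, term]
    t = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return coef, se, pvals


def fit_dmp_models(beta: pd.DataFrame, sample_sheet: pd.DataFrame,
                   fractions: pd.DataFrame) -> pd.DataFrame:
    """Per-probe linear model of beta on parity, adjusted for cell-type
    fractions (granulocytes dropped as the simplex reference) and the
    smoking biomarker. Reports the parity coefficient and its p-value,
    plus group mean betas and Δmeth.
    """
    sheet = sample_sheet.loc[beta.columns]
    fr = fractions.loc[beta.columns]
    cols = [c for c in FRACTION_COVARIATES if c in fr.columns]
    names = ["intercept", "parity", *cols, "smoking"]
    X = np.column_stack([
        np.ones(len(sheet)), sheet["parity"].values.astype(float),
        *[fr[c].values for c in cols], sheet["smoking"].values.astype(float),
    ])
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values")
    Y = beta.values
    coef, se, p = ols_by_probe(Y, X, term=1, names=names)
    parous = (sheet["parity"] == 1).values
    mean_p = Y[:, parous].mean(axis=1)
    mean_n = Y[:, ~parous].mean(axis=1)
    return pd.DataFrame({
        "coef": coef, "se": se, "p_value": p,
        "mean_parous": mean_p, "mean_nulligravida": mean_n,
        "delta_meth": mean_p - mean_n,
    }, index=beta.index)


def call_dmps(model_results: pd.DataFrame, annotation: pd.DataFrame,
              fdr_threshold: float = 0.05, delta_threshold: float = 0.01):
    """BH-adjust the per-probe p-values and call DMPs.

    A DMP satisfies fdr < ``fdr_threshold`` and |Δmeth| >= ``delta_threshold``.
    Returns (full per-probe table with fdr/direction/annotation columns
    and an ``is_dmp`` flag, summary dict with direction counts and
    CpG-island-context proportions among DMPs and among all tested probes).
    """
    res = model_results.copy()
    _, fdr, _, _ = multipletests(res["p_value"].values, method="fdr_bh")
    res["fdr"] = fdr
    res["direction"] = np.where(res["delta_meth"] > 0, "hyper", "hypo")
    anno = annotation.loc[res.index]
    for col in ("chrom", "pos", "gene", "feature", "island_context"):
        if col in anno:
            res[col] = anno[col]
    res["is_dmp"] = ((res["fdr"] < fdr_threshold)
                     & (res["delta_meth"].abs() >= delta_threshold))
    dmps = res[res["is_dmp"]]
    summary = {
        "n_tested": int(len(res)),
        "n_dmps": int(len(dmps)),
        "n_hyper": int((dmps["direction"] == "hyper").sum()),
        "n_hypo": int((dmps["direction"] == "hypo").sum()),
    }
    summary.update(direction_percentages(summary["n_hyper"], summary["n_hypo"]))
    if "island_context" in res:
        summary["island_context_dmps"] = context_percentages(
            dmps["island_context"]) if len(dmps) else {}
        summary["island_context_tested"] = context_percentages(
            res["island_context"])
    return res, summary


def direction_percentages(n_hyper: int, n_hypo: int) -> dict:
    """Percent hyper/hypomethylated among called DMPs."""
    total = n_hyper + n_hypo
    if total == 0:
        return {"pct_hyper": float("nan"), "pct_hypo": float("nan")}
    return {"pct_hyper": 100.0 * n_hyper / total,
            "pct_hypo": 100.0 * n_hypo / total}


def context_percentages(contexts: pd.Series) -> dict:
    """Percent of probes per CpG-island context class."""
    counts = contexts.value_counts()
    total = int(counts.sum())
    return {str(k): 100.0 * int(v) / total for k, v in counts.items()}


def call_dmrs(dmp_table: pd.DataFrame, annotation: pd.DataFrame | None = None,
              min_cpgs: int = 5, fdr_threshold: float = 0.01,
              max_gap: int = 1000) -> pd.DataFrame:
    """Call regions from the DMP list.

    A region is a maximal run, per chromosome and effect direction, of
    qualifying DMPs (fdr < 0.01, same Δmeth sign) in which consecutive
    members lie within 1000 bp of each other; runs of at least five
    members are emitted. Width is last minus first member position in bp
    (1-based coordinates, no endpoint correction). Input order does not
    matter; positions are sorted internally.
    """
    t = dmp_table
    if "is_dmp" in t.columns:
        t = t[t["is_dmp"]]
    if annotation is not None:
        missing = [c for c in ("chrom", "pos") if c not in t.columns]
        if missing:
            t = t.join(annotation[["chrom", "pos"]])
    need = {"chrom", "pos", "fdr", "delta_meth"}
    if not need.issubset(t.columns):
        raise KeyError(f"DMP table missing columns: {sorted(need - set(t.columns))}")
    qual = t[t["fdr"] < fdr_threshold]
    regions = []
    for (chrom, direction), grp in qual.groupby(
            ["chrom", np.where(qual["delta_meth"] > 0, "hyper", "hypo")],
            sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].values
        breaks = np.where(np.diff(pos) > max_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            if e - s < min_cpgs:
                continue
            run = grp.iloc[s:e]
            deltas = run["delta_meth"].values
            sgn = 1.0 if direction == "hyper" else -1.0
            regions.append({
                "chrom": chrom,
                "start": int(run["pos"].iloc[0]),
                "end": int(run["pos"].iloc[-1]),
                "width": int(run["pos"].iloc[-1] - run["pos"].iloc[0]),
                "n_cpgs": int(e - s),
                "probe_ids": list(run.index),
                "delta_max": float(sgn * np.abs(deltas).max()),
                "delta_mean": float(deltas.mean()),
                "direction": direction,
            })
    cols = ["chrom", "start", "end", "width", "n_cpgs", "probe_ids",
            "delta_max", "delta_mean", "direction"]
    out = pd.DataFrame(regions, columns=cols)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def paired_sensitivity_scan(beta: pd.DataFrame, pairs: list,
                            covariates: pd.DataFrame,
                            treatment_col: str = "treatment",
                            fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Matched-pair covariate sensitivity scan.

    ``pairs`` is a list of (nulligravida_id, parous_id) tuples;
    ``covariates`` is indexed by pair (same order as ``pairs``) with one
    column per covariate. For each pair the genome-wide mean Δmeth
    (parous minus nulligravida) is computed; each covariate is then
    tested against these pair-level summaries — Pearson correlation for
    continuous covariates, a one-way F-test for categorical ones. The
    treatment covariate uses only pairs concordant for treatment status.
    P-values are BH-adjusted across covariates.
    """
    deltas = np.array([
        beta[p].values - beta[n].values for n, p in pairs
    ])  # pairs x probes
    summary = deltas.mean(axis=1)
    rows = []
    for name in covariates.columns:
        col = covariates[name]
        use = np.ones(len(pairs), dtype=bool)
        if name == treatment_col:
            # covariate encodes pair concordance: keep only concordant pairs
            use = col.notna().values
        else:
            use = col.notna().values
        n_used = int(use.sum())
        if n_used < 3:
            warnings.warn(f"covariate {name!r} has fewer than 3 usable "
                          "pairs; skipped", UserWarning)
            continue
        vals = col[use]
        s = summary[use]
        if pd.api.types.is_numeric_dtype(vals) and vals.nunique() > 5:
            stat, p = stats.pearsonr(s, vals.values.astype(float))
            kind = "pearson_r"
        else:
            groups = [s[(vals == lev).values] for lev in vals.unique()]
            groups = [g for g in groups if g.size > 0]
            if len(groups) < 2:
                warnings.warn(f"covariate {name!r} has a single level among "
                              "usable pairs; skipped", UserWarning)
                continue
            stat, p = stats.f_oneway(*groups)
            kind = "anova_F"
        rows.append({"covariate": name, "statistic_type": kind,
                     "statistic": float(stat), "p_value": float(p),
                     "n_pairs": n_used})
    out = pd.DataFrame(rows, columns=["covariate", "statistic_type",
                                      "statistic", "p_value", "n_pairs"])
    if len(out):
        _, fdr, _, _ = multipletests(out["p_value"].values, method="fdr_bh")
        out["fdr"] = fdr
        out["significant"] = out["fdr"] < fdr_threshold
    return out


def concordant_treatment_covariate(sample_sheet: pd.DataFrame,
                                   pairs: list,
                                   treatment_col: str = "treatment") -> pd.Series:
    """Pair-level treatment status, NA where the pair is discordant."""
    vals = []
    for n, p in pairs:
        a = sample_sheet.loc[n, treatment_col]
        b = sample_sheet.loc[p, treatment_col]
        vals.append(a if a == b else np.nan)
    return pd.Series(vals, name=treatment_col)


def pairs_from_sheet(sample_sheet: pd.DataFrame) -> list:
    """(nulligravida, parous) sample-id tuples from the pair_id column."""
    pairs = []
    for _, grp in sample_sheet.groupby("pair_id"):
        n = grp.index[grp["parity"] == 0]
        p = grp.index[grp["parity"] == 1]
        if len(n) == 1 and len(p) == 1:
            pairs.append((n[0], p[0]))
    return pairs
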