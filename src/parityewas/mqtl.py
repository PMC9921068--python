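"""Genotype QC and conditional methylation-QTL analysis in ±5 kb
windows around called DMRs.

SNVs pass call-rate, monomorphism, minor-allele-frequency, exact
Hardy–Weinberg and autosome filters; within a window an LD-independent
subset (greedy by position, r² < 0.8) is tested against every member
CpG: a Kruskal–Wallis test of beta across dosage groups, then a linear
model beta ~ dosage + parity to ask whether the parity association
survives conditioning on genotype.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

SNV_REASONS = ("call_rate", "monomorphic", "low_maf", "hwe", "non_autosomal")
AUTOSOMES = {str(c) for c in range(1, 23)}


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test for Hardy–Weinberg equilibrium.

    Sums the probabilities, conditional on the observed allele counts, of
    every heterozygote configuration no more probable than the observed
    one (the standard exact HWE test).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa + n_Aa          # minor-allele count by convention below
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    # heterozygote count has the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    logprob = np.empty(hets.size)
    lg = math.lgamma
    for i, h in enumerate(hets):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        logprob[i] = (lg(n + 1) - lg(hom_rare + 1) - lg(h + 1)
                      - lg(hom_common + 1) + h * math.log(2)
                      + lg(rare + 1) + lg(2 * n - rare + 1) - lg(2 * n + 1))
    prob = np.exp(logprob - logprob.max())
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_Aa)]
    return float(min(prob[prob <= obs * (1 + 1e-12)].sum(), 1.0))


def genotype_counts(dosage: np.ndarray) -> tuple:
    """(n_AA, n_Aa, n_aa) from 0/1/2 dosages, ignoring missing values."""
    d = np.asarray(dosage, float)
    d = d[~np.isnan(d)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def qc_snvs(genotypes: pd.DataFrame, snv_annotation: pd.DataFrame | None = None,
            call_rate: float = 0.95, maf: float = 0.05, hwe_p: float = 1e-5,
            sample_call_rate: float = 0.95):
    """Sample call-rate filter, then SNV filters with first-matching
    reasons in the order: call_rate, monomorphic, low_maf, hwe,
    non_autosomal. Returns (filtered genotypes, exclusion report frame).
    """
    G = genotypes.copy()
    excluded = []
    # samples first
    samp_cr = 1.0 - G.isna().sum(axis=0) / max(G.shape[0], 1)
    bad_samples = samp_cr[samp_cr < sample_call_rate].index
    for sid in bad_samples:
        excluded.append({"kind": "sample", "id": sid, "reason": "call_rate"})
    G = G.drop(columns=bad_samples)

    reasons = {}
    n = G.shape[1]
    for snv in G.index:
        d = G.loc[snv].values.astype(float)
        obs = d[~np.isnan(d)]
        if n and obs.size / n < call_rate:
            reasons[snv] = "call_rate"
            continue
        if obs.size == 0 or np.ptp(obs) == 0:
            reasons[snv] = "monomorphic"
            continue
        p_alt = obs.sum() / (2 * obs.size)
        if min(p_alt, 1 - p_alt) < maf:
            reasons[snv] = "low_maf"
            continue
        if hwe_exact_test(*genotype_counts(obs)) < hwe_p:
            reasons[snv] = "hwe"
            continue
        if snv_annotation is not None:
            chrom = str(snv_annotation.loc[snv, "chrom"])
            if chrom not in AUTOSOMES:
                reasons[snv] = "non_autosomal"
                continue
    for snv, reason in reasons.items():
        excluded.append({"kind": "snv", "id": snv, "reason": reason})
    report = pd.DataFrame(excluded, columns=["kind", "id", "reason"])
    return G.drop(index=list(reasons)), report


def ld_independent_set(genotypes: pd.DataFrame,
                       snv_annotation: pd.DataFrame | None = None,
                       r2_threshold: float = 0.8) -> list:
    """Greedy LD pruning in position order.

    An SNV is kept when its squared dosage correlation with every
    already-kept SNV is below ``r2_threshold``. Deterministic: ties are
    broken by position (then id) order.
    """
    ids = list(genotypes.index)
    if snv_annotation is not None:
        order = snv_annotation.loc[ids].sort_values(["chrom", "pos"]).index
        ids = [i for i in order if i in genotypes.index]
    kept: list = []
    for snv in ids:
        x = genotypes.loc[snv].values.astype(float)
        ok = True
        for other in kept:
            y = genotypes.loc[other].values.astype(float)
            m = ~(np.isnan(x) | np.isnan(y))
            if m.sum() < 3 or np.ptp(x[m]) == 0 or np.ptp(y[m]) == 0:
                continue
            r = np.corrcoef(x[m], y[m])[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(snv)
    return kept


def assess_dmr_mqtl(beta: pd.DataFrame, genotypes: pd.DataFrame,
                    snv_annotation: pd.DataFrame, dmr: dict,
                    sample_sheet: pd.DataFrame, window: int = 5000,
                    alpha: float = 0.05,
                    r2_threshold: float = 0.8) -> pd.DataFrame:
    """Kruskal–Wallis and conditional-model scan for one called region.

    ``dmr`` needs chrom / start / end / probe_ids (as produced by the
    region caller). SNVs strictly inside [start - window, end + window]
    on the same chromosome are LD-pruned and each tested against every
    member CpG. Missing dosages are dropped pairwise.
    """
    chrom = str(dmr["chrom"])
    lo, hi = int(dmr["start"]) - window, int(dmr["end"]) + window
    anno = snv_annotation[snv_annotation["chrom"].astype(str) == chrom]
    in_window = anno[(anno["pos"] >= lo) & (anno["pos"] <= hi)].index
    in_window = [s for s in in_window if s in genotypes.index]
    cols = ["cpg_id", "snv_id", "kruskal_p", "conditional_parity_p",
            "conditional_genotype_p", "is_mqtl", "parity_independent"]
    if not in_window:
        return pd.DataFrame(columns=cols)
    independent = ld_independent_set(genotypes.loc[in_window], snv_annotation,
                                     r2_threshold)
    samples = [s for s in beta.columns if s in genotypes.columns]
    parity = sample_sheet.loc[samples, "parity"].values.astype(float)
    rows = []
    for snv in independent:
        dose = genotypes.loc[snv, samples].values.astype(float)
        for cpg in dmr["probe_ids"]:
            if cpg not in beta.index:
                continue
            y = beta.loc[cpg, samples].values.astype(float)
            m = ~np.isnan(dose)
            groups = [y[m & (dose == g)] for g in (0.0, 1.0, 2.0)]
            groups = [g for g in groups if g.size > 0]
            if len(groups) < 2:
                kw_p = np.nan
            else:
                _, kw_p = stats.kruskal(*groups)
            X = np.column_stack([np.ones(m.sum()), dose[m], parity[m]])
            XtX = X.T @ X
            coef, *_ = np.linalg.lstsq(X, y[m], rcond=None)
            resid = y[m] - X @ coef
            dof = m.sum() - 3
            sigma2 = resid @ resid / dof
            cov = sigma2 * np.linalg.inv(XtX)
            t_geno = coef[1] / np.sqrt(cov[1, 1])
            t_par = coef[2] / np.sqrt(cov[2, 2])
            p_geno = 2 * stats.t.sf(abs(t_geno), dof)
            p_par = 2 * stats.t.sf(abs(t_par), dof)
            rows.append({
                "cpg_id": cpg, "snv_id": snv, "kruskal_p": kw_p,
                "conditional_parity_p": p_par,
                "conditional_genotype_p": p_geno,
                "is_mqtl": bool(kw_p < alpha) if np.isfinite(kw_p) else False,
                "parity_independent": bool(p_par < alpha),
            })
    return pd.DataFrame(rows, columns=cols)
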