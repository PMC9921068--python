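"""Linear methylation-age clocks and methylation age acceleration (MAA).

A clock is an intercept plus per-CpG weights (years per unit beta);
methylation age is the weighted sum of beta values. MAA is the residual
from regressing methylation age on chronological age: a negative group
mean means that group is biologically younger than its chronology
predicts. Group comparison follows a normality-gated path: Shapiro–Wilk
on the residuals chooses between a one-tailed Welch t-test (alternative:
parous accelerate less) and a one-sided Mann–Whitney test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ClockModel:
    """A linear methylation-age clock."""

    name: str
    intercept: float            # years
    coefficients: pd.Series     # indexed by CpG id, years per beta unit

    def __post_init__(self) -> None:
        if self.coefficients.index.has_duplicates:
            raise ValueError("clock CpG ids must be unique")

    def to_csv(self, path) -> None:
        rows = pd.DataFrame({"cpg_id": ["(Intercept)", *self.coefficients.index],
                             "weight": [self.intercept, *self.coefficients.values]})
        rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "ClockModel":
        df = pd.read_csv(path)
        inter = df.loc[df["cpg_id"] == "(Intercept)", "weight"]
        intercept = float(inter.iloc[0]) if len(inter) else 0.0
        coef = df.loc[df["cpg_id"] != "(Intercept)"]
        return cls(name=name or str(path), intercept=intercept,
                   coefficients=pd.Series(coef["weight"].values,
                                          index=coef["cpg_id"].values))


def apply_clock(beta: pd.DataFrame, clock: ClockModel) -> pd.Series:
    """Predicted methylation age per sample (years).

    Requires at least 80% of the clock's CpGs in ``beta``; a missing
    clock CpG contributes the cohort grand-mean beta instead.
    """
    if len(clock.coefficients) == 0:
        raise ValueError("clock has no CpG coefficients")
    present = clock.coefficients.index.intersection(beta.index)
    frac = len(present) / len(clock.coefficients)
    if frac < 0.8:
        raise ValueError(
            f"only {frac:.1%} of clock '{clock.name}' CpGs present in the "
            "beta matrix; need at least 80%")
    grand_mean = float(beta.values.mean())
    vals = np.full((len(clock.coefficients), beta.shape[1]), grand_mean)
    locs = {p: i for i, p in enumerate(clock.coefficients.index)}
    rows = [locs[p] for p in present]
    vals[rows, :] = beta.loc[present].values
    ages = clock.intercept + clock.coefficients.values @ vals
    return pd.Series(ages, index=beta.columns, name=f"{clock.name}_age")


def compute_maa(methylation_ages: pd.Series, chronological_ages: pd.Series,
                groups: pd.Series | None = None,
                strict_wording: bool = False) -> pd.DataFrame:
    """MAA as residuals of an intercept-fit simple linear regression.

    Default regresses methylation age on chronological age, so residuals
    are in methylation-age years. ``strict_wording=True`` performs the
    literal reverse regression (chronological on methylation age)
    instead; the default is the standard age-acceleration definition.
    """
    ma = np.asarray(methylation_ages, float)
    ca = np.asarray(chronological_ages, float)
    if ma.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(ca) == 0:
        raise ValueError("chronological age has zero variance")
    if strict_wording:
        x, y = ma, ca
    else:
        x, y = ca, ma
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    out = pd.DataFrame({
        "methylation_age": ma, "chronological_age": ca, "maa": resid,
    }, index=methylation_ages.index)
    if groups is not None:
        out["group"] = groups.reindex(out.index)
    out.attrs["regression"] = ("chronological ~ methylation"
                               if strict_wording else "methylation ~ chronological")
    return out


def compare_maa(maa: pd.DataFrame, sample_sheet: pd.DataFrame,
                alpha: float = 0.05) -> dict:
    """Group comparison of MAA with the normality-gated test choice.

    Returns the Shapiro–Wilk p, the chosen test and its one-sided p
    (alternative: parous MAA < nulligravida MAA), the group-mean
    difference Δμ = mean(nulligravida) − mean(parous) in years, the
    Pearson correlation of MAA with years since last conception within
    the parous group, and a two-sample t-test across the age-50 split.
    """
    sheet = sample_sheet.loc[maa.index]
    parous = maa.loc[sheet["parity"] == 1, "maa"].values
    nulli = maa.loc[sheet["parity"] == 0, "maa"].values
    if parous.size == 0 or nulli.size == 0:
        raise ValueError("both groups must be present")

    sw_stat, sw_p = stats.shapiro(maa["maa"].values)
    if sw_p > alpha:
        test_name = "one-tailed Welch t"
        stat, p = stats.ttest_ind(parous, nulli, equal_var=False,
                                  alternative="less")
    else:
        test_name = "Mann-Whitney U"
        stat, p = stats.mannwhitneyu(parous, nulli, alternative="less")
    delta_mu = float(np.mean(nulli) - np.mean(parous))

    report = {
        "shapiro_p": float(sw_p),
        "test": test_name,
        "statistic": float(stat),
        "p_value": float(p),
        "delta_mu_years": delta_mu,
        "significant": bool(p < alpha),
    }

    ysc = sheet.loc[sheet["parity"] == 1, "years_since_conception"]
    usable = ysc.dropna()
    if usable.size >= 3 and usable.nunique() > 1:
        r, rp = stats.pearsonr(maa.loc[usable.index, "maa"].values,
                               usable.values)
        report["ysc_r"], report["ysc_p"] = float(r), float(rp)
    else:
        warnings.warn("no parous samples with conception dates; "
                      "years-since-conception correlation skipped", UserWarning)

    over50 = sheet["age"] >= 50
    if over50.any() and (~over50).any():
        t_stat, t_p = stats.ttest_ind(maa.loc[over50, "maa"].values,
                                      maa.loc[~over50, "maa"].values,
                                      equal_var=False)
        report["age50_t_p"] = float(t_p)
        report["n_under_50"] = int((~over50).sum())
        report["n_over_50"] = int(over50.sum())
    return report
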