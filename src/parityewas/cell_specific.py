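"""Cell-type-specific differential methylation via per-cell-type
interaction models on M-values.

One model is fit per cell type (never the joint all-cell-types model):

    M_CpG ~ parity + fraction + fraction x parity

The interaction coefficient carries the cell-specific parity contrast
(M-value units per unit cell fraction); significance uses the
genome-wide threshold p <= 9e-8 on the raw interaction p-value, with no
additional FDR layer.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import ols_by_probe

GENOME_WIDE_P = 9e-8


def call_csdmps(m_values: pd.DataFrame, fractions: pd.DataFrame,
                sample_sheet: pd.DataFrame, cell_type: str,
                p_threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Interaction-model scan for one cell type.

    Returns the full per-probe table (estimate, se, p_value, group mean
    M-values) with a ``significant`` flag at ``p_threshold``.
    """
    if cell_type not in fractions.columns:
        raise KeyError(f"no fraction column for cell type {cell_type!r}")
    sheet = sample_sheet.loc[m_values.columns]
    frac = fractions.loc[m_values.columns, cell_type].values.astype(float)
    if np.ptp(frac) == 0:
        raise ValueError(f"fraction column {cell_type!r} is constant; "
                         "interaction model is unidentifiable")
    parity = sheet["parity"].values.astype(float)
    X = np.column_stack([np.ones_like(parity), parity, frac, frac * parity])
    names = ["intercept", "parity", "fraction", "fraction:parity"]
    est, se, p = ols_by_probe(m_values.values, X, term=3, names=names)
    parous = parity == 1
    out = pd.DataFrame({
        "cell_type": cell_type,
        "estimate": est, "se": se, "p_value": p,
        "mean_m_nulligravida": m_values.values[:, ~parous].mean(axis=1),
        "mean_m_parous": m_values.values[:, parous].mean(axis=1),
    }, index=m_values.index)
    out["significant"] = out["p_value"] <= p_threshold
    return out


def call_csdmps_all(m_values: pd.DataFrame, fractions: pd.DataFrame,
                    sample_sheet: pd.DataFrame,
                    p_threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Run the per-cell-type scan for every fraction column; return the
    concatenated table of significant csDMPs."""
    hits = []
    for ct in fractions.columns:
        res = call_csdmps(m_values, fractions, sample_sheet, ct, p_threshold)
        hits.append(res[res["significant"]])
    out = pd.concat(hits) if hits else pd.DataFrame()
    return out.sort_values("p_value") if len(out) else out
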