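"""Synthetic parity-EWAS cohort generator.

Emits a complete ground-truth-annotated dataset with the statistical
structure the analysis pipeline assumes: a 6-cell-type whole-blood
mixture with group differences in fraction means, parity-associated
spiked positions and multi-CpG regions, plate/chip/position batch
shifts, detection-p and bead-count matrices with planted failures,
mQTL variants near the planted regions, and age-clock CpGs carrying a
chronological-age trend plus a group offset in biological age.

All effects — spikes, batch shifts, mQTL dosage effects, residual
noise — are additive on the logit(beta) scale and mapped back through
the logistic function, which keeps beta in (0, 1) and makes M-value
analyses linear in the planted effects.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import beta_logit, clip_beta, logistic, rng_for
from .config import ConfigurationError, SimulationConfig
from .clocks import ClockModel

ISLAND_CONTEXTS = ("island", "shore", "shelf", "opensea")
# genomic-context frequencies of tested CpGs on the array
ISLAND_PROBS = (0.192, 0.182, 0.068, 0.558)
FEATURES = ("Body", "TSS200", "TSS1500", "1stExon", "5'UTR", "IGR")

_AGE_CENTER = 47.5  # years; centers the clock-CpG trend


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    true_fractions: pd.DataFrame          # samples x cell types, rows sum to 1
    spiked_dmps: pd.DataFrame             # probe_id, delta (signed, beta scale)
    dmr_regions: list                     # dicts: chrom/start/end/probe_ids/...
    mqtl_pairs: pd.DataFrame              # snv_id, cpg_id, effect (logit/allele)
    true_methylation_ages: pd.Series      # biological age per sample, years
    batch_assignments: pd.DataFrame       # per-sample Plate/Chip/Position
    qc_fail_probes: dict = field(default_factory=dict)   # reason -> probe ids
    qc_fail_samples: list = field(default_factory=list)
    cs_probes: dict = field(default_factory=dict)        # cell type -> ids

    @property
    def true_dmp_ids(self) -> list:
        return list(self.spiked_dmps["probe_id"])


@dataclass
class SimulatedDataset:
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    bead_counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    annotation: pd.DataFrame
    reference: pd.DataFrame               # cell types x probes, beta scale
    clock: ClockModel
    truth: GroundTruth
    config: SimulationConfig
    genotypes: pd.DataFrame | None = None
    snv_annotation: pd.DataFrame | None = None


def probe_ids(n: int) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(n)], name="probe_id")


def _probe_layout(config: SimulationConfig) -> dict:
    """Deterministic partition of the probe index space.

    Signature probes come first (one block per cell type), then clock
    CpGs, then planted-region members, and the remainder is the plain
    pool from which spiked positions and QC failures are drawn.
    """
    n_sig = config.n_signature_per_type * config.n_cell_types
    n_clock = config.n_clock_cpgs
    n_dmr = sum(s.n_cpgs for s in config.dmr_specs)
    needed = n_sig + n_clock + n_dmr + config.n_spiked_dmps
    if needed > config.n_probes:
        raise ConfigurationError(
            f"n_probes={config.n_probes} too small for the requested structure "
            f"(needs at least {needed})")
    sig = {
        ct: np.arange(t * config.n_signature_per_type,
                      (t + 1) * config.n_signature_per_type)
        for t, ct in enumerate(config.cell_types)
    }
    clock = np.arange(n_sig, n_sig + n_clock)
    dmr_members, at = [], n_sig + n_clock
    for spec in config.dmr_specs:
        dmr_members.append(np.arange(at, at + spec.n_cpgs))
        at += spec.n_cpgs
    plain = np.arange(at, config.n_probes)
    return {"signature": sig, "clock": clock, "dmr": dmr_members, "plain": plain}


def generate_reference(config: SimulationConfig) -> pd.DataFrame:
    """Cell-type reference methylomes (cell types x probes, beta scale).

    Each cell type's signature block is strongly methylated in that type
    (0.65–0.95) and weakly in all others (0.05–0.35), so the between-type
    beta range on signature probes is at least 0.3 and deconvolution is
    identifiable. Non-signature probes follow a bimodal methylome with
    small between-type jitter on the logit scale.
    """
    if config.n_cell_types < 2:
        raise ConfigurationError("need at least 2 cell types")
    if config.n_probes < 100:
        raise ConfigurationError("need at least 100 probes")
    rng = rng_for(config.seed, 1)
    layout = _probe_layout(config)
    T, P = config.n_cell_types, config.n_probes

    # bimodal baseline shared across types
    comp = rng.choice(3, size=P, p=(0.4, 0.4, 0.2))
    base = np.where(
        comp == 0, rng.uniform(0.03, 0.15, P),
        np.where(comp == 1, rng.uniform(0.80, 0.97, P),
                 rng.uniform(0.25, 0.75, P)))
    # mid-range baselines where planted effects must fit
    for idx in (layout["clock"], *layout["dmr"]):
        base[idx] = rng.uniform(0.35, 0.60, idx.size)

    ref = logistic(beta_logit(base)[None, :] + rng.normal(0.0, 0.05, (T, P)))
    for t, ct in enumerate(config.cell_types):
        idx = layout["signature"][ct]
        ref[:, idx] = rng.uniform(0.05, 0.35, (T, idx.size))
        ref[t, idx] = rng.uniform(0.65, 0.95, idx.size)

    ref = pd.DataFrame(clip_beta(ref), index=list(config.cell_types),
                       columns=probe_ids(P))
    warn_if_degenerate_reference(ref)
    return ref


def warn_if_degenerate_reference(ref: pd.DataFrame) -> bool:
    """Warn when two cell-type rows are numerically indistinguishable."""
    rv = np.asarray(ref.values, dtype=float)
    degenerate = False
    for i in range(rv.shape[0]):
        for j in range(i + 1, rv.shape[0]):
            if np.allclose(rv[i], rv[j], atol=1e-6):
                degenerate = True
                warnings.warn(
                    f"reference rows {ref.index[i]} and {ref.index[j]} are "
                    "indistinguishable; deconvolution will not be identifiable",
                    UserWarning, stacklevel=2)
    return degenerate


def signature_probe_ids(config: SimulationConfig) -> pd.Index:
    layout = _probe_layout(config)
    idx = np.concatenate([layout["signature"][ct] for ct in config.cell_types])
    return probe_ids(config.n_probes)[np.sort(idx)]


def _make_sample_sheet(config: SimulationConfig, rng) -> pd.DataFrame:
    g = config.n_samples_per_group
    nulli = [f"N{i+1:03d}" for i in range(g)]
    parous = [f"P{i+1:03d}" for i in range(g)]
    age_n = rng.uniform(*config.age_range, g)
    age_p = np.clip(age_n + rng.uniform(-3.0, 3.0, g), *config.age_range)

    # interleave pairs with randomized within-pair order so no batch level
    # (chip, plate, array position) is confounded with group, emulating
    # randomized sample placement
    order, group, age, pair = [], [], [], []
    for i in range(g):
        members = [(nulli[i], "nulligravida", age_n[i]),
                   (parous[i], "parous", age_p[i])]
        if rng.random() < 0.5:
            members.reverse()
        for sid, grp, a in members:
            order.append(sid)
            group.append(grp)
            age.append(a)
            pair.append(i + 1)
    n = 2 * g
    sheet = pd.DataFrame({
        "group": group, "parity": [int(x == "parous") for x in group],
        "age": age, "pair_id": pair,
    }, index=pd.Index(order, name="sample_id"))

    levels = config.batch_levels
    pos_n = levels.get("Position", 8)
    chip_n = levels.get("Chip", max(1, int(np.ceil(n / pos_n))))
    plate_n = levels.get("Plate", 4)
    idx = np.arange(n)
    position = idx % pos_n
    chip = (idx // pos_n) % chip_n
    plate = chip % plate_n
    sheet["Plate"] = [f"PL{v+1}" for v in plate]
    sheet["Chip"] = [f"CH{v+1:02d}" for v in chip]
    sheet["Position"] = [f"R{v+1:02d}" for v in position]
    sheet["site"] = rng.choice(["RMH", "BHH", "JHH", "FMC"], n,
                               p=(0.38, 0.29, 0.13, 0.20))
    sheet["smoking"] = rng.normal(2.0, 8.0, n)  # DNAmPACKYRS-like biomarker
    sheet["armss"] = np.clip(rng.normal(6.5, 2.0, n), 0.1, 9.9)

    # treatment: concordant-on / concordant-off / discordant pairs
    n_on = min(config.n_pairs_treatment_on, g)
    n_off = min(config.n_pairs_treatment_off, max(0, g - n_on))
    pair_kind = np.array(["on"] * n_on + ["off"] * n_off
                         + ["disc"] * (g - n_on - n_off))
    rng.shuffle(pair_kind)
    treat = np.empty(n, dtype=int)
    for i in range(g):
        k = pair_kind[i]
        if k == "on":
            treat[2 * i:2 * i + 2] = 1
        elif k == "off":
            treat[2 * i:2 * i + 2] = 0
        else:
            treat[2 * i] = rng.integers(0, 2)
            treat[2 * i + 1] = 1 - treat[2 * i]
    sheet["treatment"] = treat

    ysc = np.full(n, np.nan)
    parous_mask = sheet["parity"].values == 1
    ysc[parous_mask] = np.minimum(
        rng.gamma(2.5, 7.0, parous_mask.sum()) + 1.5,
        np.maximum(sheet.loc[parous_mask, "age"].values - 18.0, 1.5))
    sheet["years_since_conception"] = ysc
    return sheet


def _make_annotation(config: SimulationConfig, rng) -> pd.DataFrame:
    layout = _probe_layout(config)
    P = config.n_probes
    pids = probe_ids(P)
    chrom = rng.integers(1, 23, P).astype(object)
    chrom = np.array([str(c) for c in chrom], dtype=object)
    pos = rng.integers(1_000_000, 240_000_000, P)

    # planted regions live in a reserved coordinate band so no plain probe
    # can fall inside or adjacent to them
    for k, spec in enumerate(config.dmr_specs):
        members = layout["dmr"][k]
        start = 250_000_000 + 100_000 * k
        positions = start + np.cumsum([0] + [spec.gap_bp] * (spec.n_cpgs - 1))
        chrom[members] = str(spec.chrom)
        pos[members] = positions

    anno = pd.DataFrame({
        "chrom": chrom, "pos": pos.astype(np.int64),
        "gene": ["" for _ in range(P)],
        "feature": rng.choice(FEATURES, P),
        "island_context": rng.choice(ISLAND_CONTEXTS, P, p=ISLAND_PROBS),
        "design_type": rng.choice(["I", "II"], P,
                                  p=(config.frac_type_i_probes,
                                     1 - config.frac_type_i_probes)),
        "non_cpg": False, "snp_related": False, "multi_hit": False,
    }, index=pids)
    with_gene = rng.random(P) < 0.45
    anno.loc[with_gene, "gene"] = [f"GENE{i:05d}" for i in
                                   rng.integers(0, 30_000, int(with_gene.sum()))]
    return anno


def _plant_qc_failures(config, rng, layout, anno, detection_p, bead_counts,
                       sheet) -> dict:
    """Flag/perturb plain-pool probes so each QC filter has known targets."""
    pool = layout["plain"].copy()
    rng.shuffle(pool)
    P = config.n_probes

    def take(frac):
        nonlocal pool
        k = int(round(frac * P))
        out, pool = pool[:k], pool[k:]
        return np.sort(out)

    fail = {}
    fail["low_quality"] = take(config.frac_detection_fail)
    fail["bead_count"] = take(config.frac_bead_fail)
    fail["non_cpg"] = take(config.frac_non_cpg)
    fail["snp_related"] = take(config.frac_snp_related)
    fail["multi_hit"] = take(config.frac_multi_hit)
    fail["non_autosomal"] = take(config.frac_non_autosomal)

    n = sheet.shape[0]
    for j in fail["low_quality"]:
        k = rng.integers(1, max(2, n // 10))
        cols = rng.choice(n, size=k, replace=False)
        detection_p.values[j, cols] = rng.uniform(0.011, 1.0, k)
    for j in fail["bead_count"]:
        k = max(int(np.ceil(0.10 * n)), 1)
        cols = rng.choice(n, size=k, replace=False)
        bead_counts.values[j, cols] = rng.integers(0, 3, k)
    anno.iloc[fail["non_cpg"], anno.columns.get_loc("non_cpg")] = True
    anno.iloc[fail["snp_related"], anno.columns.get_loc("snp_related")] = True
    anno.iloc[fail["multi_hit"], anno.columns.get_loc("multi_hit")] = True
    anno.iloc[fail["non_autosomal"], anno.columns.get_loc("chrom")] = "X"

    pids = anno.index
    return {reason: list(pids[idx]) for reason, idx in fail.items()}


def simulate_cohort(config: SimulationConfig,
                    reference: pd.DataFrame | None = None) -> SimulatedDataset:
    """Generate the full synthetic cohort.

    beta = logistic( logit(sum_t frac_t * ref_t) + parity spikes
                     + batch shifts + noise ),
    with clock CpGs carrying an explicit linear-in-biological-age trend on
    the beta scale, and companion detection-p / bead-count matrices with
    planted failures.
    """
    if reference is None:
        reference = generate_reference(config)
    if reference.shape != (config.n_cell_types, config.n_probes):
        raise ConfigurationError(
            f"reference shape {reference.shape} inconsistent with config "
            f"({config.n_cell_types} x {config.n_probes})")
    groups = config.dirichlet_params_by_group
    if set(groups) != {"nulligravida", "parous"}:
        raise ConfigurationError(
            "dirichlet_params_by_group must have keys 'nulligravida' and 'parous'")

    rng = rng_for(config.seed, 2)
    layout = _probe_layout(config)
    sheet = _make_sample_sheet(config, rng_for(config.seed, 3))
    anno = _make_annotation(config, rng_for(config.seed, 4))
    n = sheet.shape[0]
    P = config.n_probes
    pids = anno.index
    parous = sheet["parity"].values.astype(float)

    fracs = np.empty((n, config.n_cell_types))
    for g_name in ("nulligravida", "parous"):
        mask = (sheet["group"] == g_name).values
        fracs[mask] = rng.dirichlet(np.asarray(groups[g_name], float),
                                    int(mask.sum()))
    fractions = pd.DataFrame(fracs, index=sheet.index,
                             columns=list(config.cell_types))

    mix = fracs @ reference.values                       # samples x probes
    logit_m = beta_logit(mix)
    baseline = clip_beta(mix.mean(axis=0))

    # --- parity spikes at single positions -------------------------------
    mid = layout["plain"][(baseline[layout["plain"]] > 0.20)
                          & (baseline[layout["plain"]] < 0.70)]
    if mid.size < config.n_spiked_dmps:
        raise ConfigurationError("not enough mid-methylated probes to spike")
    spike_idx = np.sort(rng.choice(mid, config.n_spiked_dmps, replace=False))
    mags = rng.uniform(*config.spiked_delta_range, config.n_spiked_dmps)
    signs = np.where(rng.random(config.n_spiked_dmps) < 0.685, 1.0, -1.0)
    deltas = mags * signs
    target = clip_beta(baseline[spike_idx] + deltas, 0.02)
    shift = beta_logit(target) - beta_logit(baseline[spike_idx])
    logit_m[:, spike_idx] += np.outer(parous, shift)
    spiked = pd.DataFrame({"probe_id": pids[spike_idx], "delta": deltas})

    # --- planted regions -------------------------------------------------
    dmr_regions = []
    for k, spec in enumerate(config.dmr_specs):
        members = layout["dmr"][k]
        sgn = 1.0 if spec.direction == "hyper" else -1.0
        tgt = clip_beta(baseline[members] + sgn * spec.delta, 0.02)
        sh = beta_logit(tgt) - beta_logit(baseline[members])
        logit_m[:, members] += np.outer(parous, sh)
        dmr_regions.append({
            "chrom": str(spec.chrom),
            "start": int(anno["pos"].values[members].min()),
            "end": int(anno["pos"].values[members].max()),
            "probe_ids": list(pids[members]),
            "direction": spec.direction,
            "delta": sgn * spec.delta,
        })

    # --- cell-type-specific effects (bulk shift scales with fraction) ----
    cs_probes: dict = {}
    avail = np.setdiff1d(mid, spike_idx)
    for cell_type, cs_shift, n_cs in config.cs_effects:
        if cell_type not in config.cell_types:
            raise ConfigurationError(f"unknown cell type {cell_type!r}")
        chosen = np.sort(rng.choice(avail, int(n_cs), replace=False))
        avail = np.setdiff1d(avail, chosen)
        frac_ct = fractions[cell_type].values
        logit_m[:, chosen] += np.outer(parous * frac_ct * cs_shift,
                                       np.ones(chosen.size))
        cs_probes.setdefault(cell_type, []).extend(pids[chosen])

    # --- batch shifts ----------------------------------------------------
    batch_cols = [c for c in ("Plate", "Chip", "Position") if c in sheet]
    if config.batch_sd > 0:
        for col in batch_cols:
            for level in sheet[col].unique():
                gamma = rng.normal(0.0, config.batch_sd, P)
                logit_m[(sheet[col] == level).values] += gamma

    if config.noise_sd > 0:
        logit_m += rng.normal(0.0, config.noise_sd, logit_m.shape)
    beta = logistic(logit_m)

    # --- clock CpGs: linear-in-age beta trend ----------------------------
    bio_age = (sheet["age"].values + config.maa_offset_years * parous
               + rng.normal(0.0, config.maa_residual_sd, n))
    clock_idx = layout["clock"]
    K = clock_idx.size
    if K:
        c_j = rng.uniform(0.35, 0.65, K)
        d_j = rng.uniform(0.4, 0.8, K)
        vals = (c_j[None, :] + np.outer(bio_age - _AGE_CENTER, d_j) / 100.0
                + rng.normal(0.0, 0.01, (n, K)))
        beta[:, clock_idx] = clip_beta(vals, 0.01)
        weights = 100.0 / (K * d_j)
        intercept = _AGE_CENTER - float(weights @ c_j)
        clock = ClockModel(name="toy-synthetic-clock", intercept=intercept,
                           coefficients=pd.Series(weights, index=pids[clock_idx]))
    else:
        clock = ClockModel(name="toy-synthetic-clock", intercept=0.0,
                           coefficients=pd.Series(dtype=float))

    beta = pd.DataFrame(clip_beta(beta).T, index=pids, columns=sheet.index)

    # --- QC companion matrices ------------------------------------------
    qc_rng = rng_for(config.seed, 5)
    detection_p = pd.DataFrame(qc_rng.uniform(0.0, 1e-3, (P, n)),
                               index=pids, columns=sheet.index)
    bead_counts = pd.DataFrame(qc_rng.poisson(15.0, (P, n)).clip(min=3),
                               index=pids, columns=sheet.index)
    qc_fail = _plant_qc_failures(config, qc_rng, layout, anno,
                                 detection_p, bead_counts, sheet)
    fail_samples = []
    if config.n_failed_samples:
        fail_cols = qc_rng.choice(n, config.n_failed_samples, replace=False)
        for c in fail_cols:
            rows = qc_rng.choice(P, int(0.15 * P), replace=False)
            detection_p.values[rows, c] = qc_rng.uniform(0.011, 1.0, rows.size)
        fail_samples = list(sheet.index[np.sort(fail_cols)])

    truth = GroundTruth(
        true_fractions=fractions,
        spiked_dmps=spiked,
        dmr_regions=dmr_regions,
        mqtl_pairs=pd.DataFrame(columns=["snv_id", "cpg_id", "effect"]),
        true_methylation_ages=pd.Series(bio_age, index=sheet.index,
                                        name="biological_age"),
        batch_assignments=sheet[batch_cols].copy(),
        qc_fail_probes=qc_fail,
        qc_fail_samples=fail_samples,
        cs_probes=cs_probes,
    )
    return SimulatedDataset(beta=beta, detection_p=detection_p,
                            bead_counts=bead_counts, sample_sheet=sheet,
                            annotation=anno, reference=reference, clock=clock,
                            truth=truth, config=config)


def simulate_genotypes(config: SimulationConfig,
                       dataset: SimulatedDataset,
                       missing_rate: float = 0.01) -> pd.DataFrame:
    """Plant biallelic SNVs in ±5 kb windows around the planted regions.

    Genotypes are drawn under Hardy–Weinberg equilibrium at
    ``config.mqtl_maf``; each effect SNV shifts one member CpG's beta by
    ``config.mqtl_effect`` per alternate allele on the logit scale. Where
    a region receives more than one SNV, the second is an LD companion of
    the first (r² near 1) carrying no direct effect. Updates
    ``dataset.beta`` in place and attaches genotype/annotation frames.
    """
    if config.n_mqtl_snvs == 0:
        empty = pd.DataFrame(index=pd.Index([], name="snv_id"),
                             columns=dataset.sample_sheet.index)
        dataset.genotypes = empty
        dataset.snv_annotation = pd.DataFrame(columns=["chrom", "pos"])
        return empty
    if not dataset.truth.dmr_regions:
        raise ConfigurationError("n_mqtl_snvs > 0 requires dmr_specs")
    if not (0 < config.mqtl_maf <= 0.5):
        raise ConfigurationError("mqtl_maf must be in (0, 0.5]")

    rng = rng_for(config.seed, 6)
    sheet = dataset.sample_sheet
    n = sheet.shape[0]
    regions = dataset.truth.dmr_regions
    per_region = np.full(len(regions), config.n_mqtl_snvs // len(regions))
    per_region[:config.n_mqtl_snvs % len(regions)] += 1

    rows, annot_rows, pairs = [], [], []
    snv_i = 0
    for region, k in zip(regions, per_region):
        lo, hi = region["start"] - 5000, region["end"] + 5000
        members = region["probe_ids"]
        base_dose = None
        for j in range(int(k)):
            snv_id = f"rs{900000 + snv_i}"
            snv_i += 1
            pos = int(rng.integers(lo, hi + 1))
            if j == 1 and base_dose is not None:
                dose = base_dose.copy()          # LD companion
                flip = rng.random(n) < 0.02
                dose[flip] = rng.binomial(2, config.mqtl_maf, int(flip.sum()))
                effect = 0.0
            else:
                dose = rng.binomial(2, config.mqtl_maf, n).astype(float)
                if j == 0:
                    base_dose = dose.copy()
                effect = config.mqtl_effect
            if effect:
                cpg = members[j % len(members)]
                b = dataset.beta.loc[cpg].values
                dataset.beta.loc[cpg] = logistic(beta_logit(b) + effect * dose)
                pairs.append({"snv_id": snv_id, "cpg_id": cpg, "effect": effect})
            if missing_rate > 0:
                miss = rng.random(n) < missing_rate
                dose = dose.astype(object)
                dose[miss] = np.nan
            rows.append(pd.Series(dose, index=sheet.index, name=snv_id))
            annot_rows.append({"snv_id": snv_id, "chrom": region["chrom"],
                               "pos": pos})

    genotypes = pd.DataFrame(rows).astype(float)
    genotypes.index.name = "snv_id"
    snv_anno = pd.DataFrame(annot_rows).set_index("snv_id").sort_values(
        ["chrom", "pos"])
    genotypes = genotypes.loc[snv_anno.index]
    dataset.genotypes = genotypes
    dataset.snv_annotation = snv_anno
    dataset.truth.mqtl_pairs = pd.DataFrame(
        pairs, columns=["snv_id", "cpg_id", "effect"])
    return genotypes
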