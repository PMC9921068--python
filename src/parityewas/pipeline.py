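"""End-to-end orchestration: QC → BMIQ → batch scan/correction →
deconvolution → DMP → DMR → cell-specific models → mQTL → elastic net →
clocks, with a run manifest recording the seed and every threshold."""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cell_specific, clocks, deconvolution, differential, mqtl
from . import feature_selection as fs
from .config import PipelineConfig, SimulationConfig
from .io import read_dataset, write_dmr_bed, write_table
from .preprocessing import (bmiq_normalize, combat_adjust, filter_probes,
                            filter_samples, svd_batch_scan)
from .simulate import SimulatedDataset, simulate_cohort, simulate_genotypes

log = logging.getLogger("parityewas")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ResultBundle:
    beta: pd.DataFrame | None = None
    qc_report: pd.DataFrame | None = None
    qc_object: object = None
    batch_scan: pd.DataFrame | None = None
    fractions: pd.DataFrame | None = None
    effect_sizes: pd.DataFrame | None = None
    dmp_table: pd.DataFrame | None = None
    dmp_summary: dict = field(default_factory=dict)
    dmrs: pd.DataFrame | None = None
    csdmps: pd.DataFrame | None = None
    mqtl_results: pd.DataFrame | None = None
    panel: "fs.ElasticNetPanel | None" = None
    maa: pd.DataFrame | None = None
    maa_report: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig,
                 dataset: SimulatedDataset | None = None,
                 n_panel_probes: int = 300) -> ResultBundle:
    """Run the enabled stages in order on ``dataset``.

    When no dataset is given, one is loaded from ``config.input_dir`` or,
    failing that, simulated at ``config.seed``. On stage failure the
    bundle built so far is attached to the raised :class:`StageError`.
    """
    if dataset is None:
        if config.input_dir:
            dataset = read_dataset(config.input_dir)
        else:
            sim = SimulationConfig(seed=config.seed)
            dataset = simulate_cohort(sim)
            simulate_genotypes(sim, dataset)

    bundle = ResultBundle()
    stages = config.stages
    manifest = {"seed": config.seed, "thresholds": config.to_dict(),
                "stages_run": [], "counts": {}}
    bundle.manifest = manifest
    beta = dataset.beta
    sheet = dataset.sample_sheet

    def record(stage, **counts):
        manifest["stages_run"].append(stage)
        manifest["counts"].update(counts)
        log.info("stage %-14s %s", stage,
                 " ".join(f"{k}={v}" for k, v in counts.items()))

    try:
        stage = "qc"
        if stages.get("qc", True):
            beta, samp_rep = filter_samples(
                beta, dataset.detection_p, config.detection_p,
                config.sample_fail_ratio)
            beta, probe_rep = filter_probes(
                beta, dataset.detection_p, dataset.bead_counts,
                dataset.annotation, config.detection_p, config.bead_min,
                config.bead_fail_fraction)
            probe_rep.excluded_samples = samp_rep.excluded_samples
            bundle.qc_report = probe_rep.to_frame()
            bundle.qc_object = probe_rep
            sheet = sheet.loc[beta.columns]
            record(stage, probes_in=probe_rep.n_probes_before,
                   probes_out=probe_rep.n_probes_after,
                   samples_out=beta.shape[1],
                   retained_pct=round(probe_rep.retained_fraction, 2))

        beta_qc = beta  # clocks run on unnormalized (QC'd) betas: the clock
        # scale is defined on raw beta and BMIQ's within-sample remap would
        # rescale its CpGs

        stage = "bmiq"
        if stages.get("bmiq", True):
            beta = bmiq_normalize(beta, dataset.annotation)
            record(stage, probes=beta.shape[0])

        stage = "batch"
        if stages.get("batch", True):
            scan = svd_batch_scan(beta, sheet, k=config.svd_components,
                                  p_threshold=config.batch_p)
            bundle.batch_scan = scan
            sig = (scan[scan["significant"]]["factor_name"].unique()
                   if len(scan) else [])
            batch_cols = [c for c in ("Plate", "Chip", "Position") if c in sig]
            if batch_cols:
                beta = combat_adjust(beta, sheet[batch_cols],
                                     covariates=sheet[["parity"]])
            record(stage, significant_factors=",".join(batch_cols) or "none")

        stage = "deconvolution"
        if stages.get("deconvolution", True):
            bundle.fractions = deconvolution.estimate_cell_fractions(
                beta, dataset.reference, method=config.deconv_method)
            bundle.effect_sizes = deconvolution.group_effect_size(
                bundle.fractions, sheet, config.cohens_d_threshold)
            record(stage, cell_types=bundle.fractions.shape[1])

        stage = "dmp"
        if stages.get("dmp", True):
            models = differential.fit_dmp_models(beta, sheet, bundle.fractions)
            bundle.dmp_table, bundle.dmp_summary = differential.call_dmps(
                models, dataset.annotation, config.dmp_fdr, config.dmp_delta)
            record(stage, n_dmps=bundle.dmp_summary["n_dmps"])

        stage = "dmr"
        if stages.get("dmr", True) and bundle.dmp_table is not None:
            bundle.dmrs = differential.call_dmrs(
                bundle.dmp_table, min_cpgs=config.dmr_min_cpgs,
                fdr_threshold=config.dmr_fdr, max_gap=config.dmr_max_gap)
            record(stage, n_dmrs=len(bundle.dmrs))

        stage = "csdmp"
        if stages.get("csdmp", True) and bundle.fractions is not None:
            m = differential.beta_to_m(beta)
            bundle.csdmps = cell_specific.call_csdmps_all(
                m, bundle.fractions, sheet, config.csdmp_p)
            record(stage, n_csdmps=len(bundle.csdmps))

        stage = "mqtl"
        if (stages.get("mqtl", True) and bundle.dmrs is not None
                and dataset.genotypes is not None and len(dataset.genotypes)):
            geno, _ = mqtl.qc_snvs(dataset.genotypes, dataset.snv_annotation,
                                   config.call_rate, config.maf, config.hwe_p)
            results = []
            for _, dmr in bundle.dmrs.iterrows():
                results.append(mqtl.assess_dmr_mqtl(
                    beta, geno, dataset.snv_annotation, dmr.to_dict(), sheet,
                    config.mqtl_window, config.alpha_level, config.ld_r2))
            bundle.mqtl_results = (pd.concat(results, ignore_index=True)
                                   if results else pd.DataFrame())
            record(stage, n_tests=len(bundle.mqtl_results))

        stage = "elastic_net"
        if stages.get("elastic_net", True) and bundle.dmp_table is not None:
            # candidate features: top probes by single-probe evidence, a
            # tractable stand-in for the full probe set
            top = bundle.dmp_table.nsmallest(n_panel_probes, "p_value").index
            feats = beta.loc[top].T
            covs = None
            if bundle.fractions is not None:
                covs = bundle.fractions.drop(columns="Gran", errors="ignore")
                covs = covs.join(sheet["smoking"])
            alpha, lam, trace = fs.tune_elastic_net(
                feats, sheet["parity"], seed=config.seed, covariates=covs)
            bundle.panel = fs.select_features(
                feats, sheet["parity"], alpha, lam, split_seed=config.seed,
                covariates=covs, train_fraction=config.train_fraction,
                cv_trace=trace)
            record(stage, alpha=alpha, lam=round(lam, 4),
                   n_selected=bundle.panel.n_selected)

        stage = "clocks"
        if stages.get("clocks", True):
            ages = clocks.apply_clock(beta_qc, dataset.clock)
            bundle.maa = clocks.compute_maa(ages, sheet["age"], sheet["group"])
            bundle.maa_report = clocks.compare_maa(bundle.maa, sheet,
                                                   config.alpha_level)
            record(stage, delta_mu=round(bundle.maa_report["delta_mu_years"], 3))
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise StageError(stage, exc) from exc

    bundle.beta = beta
    return bundle


def write_results(bundle: ResultBundle, out_dir, config: PipelineConfig) -> dict:
    """Write every populated result table plus the machine-readable
    manifest; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = {k: v for k, v in config.to_dict().items()
          if isinstance(v, (int, float)) and not isinstance(v, bool)}
    paths = {}

    def save(name, df, index=False):
        path = out / name
        write_table(df, path, th, index=index)
        paths[name] = path

    if bundle.qc_report is not None:
        save("qc_report.csv", bundle.qc_report)
    if bundle.batch_scan is not None:
        save("batch_scan.csv", bundle.batch_scan)
    if bundle.fractions is not None:
        save("cell_fractions.csv", bundle.fractions, index=True)
        save("cell_effect_sizes.csv", bundle.effect_sizes)
    if bundle.dmp_table is not None:
        dmps = bundle.dmp_table[bundle.dmp_table["is_dmp"]]
        cols = [c for c in ("chrom", "pos", "gene", "feature", "delta_meth",
                            "fdr", "direction", "island_context") if c in dmps]
        save("dmps.csv", dmps[cols].rename_axis("CpG").reset_index())
    if bundle.dmrs is not None:
        d = bundle.dmrs.copy()
        if len(d):
            d["probe_ids"] = d["probe_ids"].map(";".join)
        save("dmrs.csv", d)
        write_dmr_bed(bundle.dmrs, out / "dmrs.bed")
        paths["dmrs.bed"] = out / "dmrs.bed"
    if bundle.csdmps is not None:
        save("csdmps.csv", bundle.csdmps.rename_axis("CpG").reset_index())
    if bundle.mqtl_results is not None:
        save("mqtl.csv", bundle.mqtl_results)
    if bundle.panel is not None:
        save("elastic_net_panel.csv", bundle.panel.selected)
        if bundle.panel.cv_trace is not None:
            save("elastic_net_trace.csv", bundle.panel.cv_trace)
    if bundle.maa is not None:
        save("maa.csv", bundle.maa, index=True)
    manifest = dict(bundle.manifest)
    manifest["maa_report"] = bundle.maa_report
    manifest["dmp_summary"] = bundle.dmp_summary
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    paths["manifest.json"] = out / "manifest.json"
    return paths
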