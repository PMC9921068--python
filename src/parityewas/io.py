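"""Readers and writers for the pipeline's on-disk formats.

Matrices are TSV with probes as rows (first column ``probe_id``, header
row of sample ids); the sample sheet is CSV; probe annotation is a
BED-like TSV with 1-based positions; genotypes are a TSV of 0/1/2
dosages with missing as NA. Result tables carry their thresholds in a
leading ``#`` comment block.
"""
from __future__ import annotations

import json
import os
from pathlib import Path

import pandas as pd
import yaml

from .clocks import ClockModel
from .config import SimulationConfig
from .simulate import GroundTruth, SimulatedDataset

FLOAT_FMT = "%.12g"


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r} in {path}")
    return df


def export_dataset(dataset: SimulatedDataset, out_dir, overwrite: bool = False) -> dict:
    """Write every component of a simulated dataset to ``out_dir``.

    Refuses a non-empty directory unless ``overwrite`` is set. Returns a
    dict of the paths written. Same config (and seed) in, byte-identical
    files out.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} is not empty; pass overwrite=True to replace its contents")
    paths = {}

    def p(name):
        paths[name.split(".")[0]] = out / name
        return out / name

    write_matrix(dataset.beta, p("beta.tsv"))
    write_matrix(dataset.detection_p, p("detection_p.tsv"))
    write_matrix(dataset.bead_counts, p("bead_counts.tsv"))
    dataset.sample_sheet.to_csv(p("sample_sheet.csv"), float_format=FLOAT_FMT)
    dataset.annotation.to_csv(p("annotation.tsv"), sep="\t")
    dataset.reference.T.to_csv(p("reference.tsv"), sep="\t",
                               float_format=FLOAT_FMT, index_label="probe_id")
    dataset.clock.to_csv(p("clock.csv"))
    if dataset.genotypes is not None and len(dataset.genotypes):
        dataset.genotypes.to_csv(p("genotypes.tsv"), sep="\t",
                                 float_format="%g", na_rep="NA")
        dataset.snv_annotation.to_csv(p("snv_annotation.tsv"), sep="\t")
    truth = dataset.truth
    truth_obj = {
        "true_fractions": truth.true_fractions.round(12).to_dict(orient="index"),
        "spiked_dmps": truth.spiked_dmps.to_dict(orient="records"),
        "dmr_regions": truth.dmr_regions,
        "mqtl_pairs": truth.mqtl_pairs.to_dict(orient="records"),
        "true_methylation_ages": truth.true_methylation_ages.round(9).to_dict(),
        "qc_fail_probes": truth.qc_fail_probes,
        "qc_fail_samples": truth.qc_fail_samples,
        "cs_probes": {k: list(v) for k, v in truth.cs_probes.items()},
    }
    with open(p("ground_truth.json"), "w") as fh:
        json.dump(truth_obj, fh, indent=1, sort_keys=True)
    with open(p("config.yaml"), "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=False)
    return paths


def read_dataset(in_dir) -> SimulatedDataset:
    """Load an exported dataset, realigning every matrix to the sample
    sheet's sample order and the beta matrix's probe order."""
    d = Path(in_dir)
    beta = read_matrix(d / "beta.tsv")
    sheet = pd.read_csv(d / "sample_sheet.csv", index_col=0)
    missing = beta.columns.difference(sheet.index)
    if len(missing):
        raise ValueError(
            f"samples present in beta but absent from the sample sheet: "
            f"{list(missing)[:5]}")
    beta = beta.loc[:, sheet.index.intersection(beta.columns)]
    beta = beta[sheet.index[sheet.index.isin(beta.columns)]]

    def aligned(name):
        m = read_matrix(d / name)
        missing_probes = beta.index.difference(m.index)
        if len(missing_probes):
            raise ValueError(f"{name} missing probes: {list(missing_probes)[:5]}")
        return m.loc[beta.index, beta.columns]

    detection_p = aligned("detection_p.tsv")
    bead_counts = aligned("bead_counts.tsv")
    anno = pd.read_csv(d / "annotation.tsv", sep="\t", index_col=0)
    missing_probes = beta.index.difference(anno.index)
    if len(missing_probes):
        raise ValueError(f"annotation missing probes: {list(missing_probes)[:5]}")
    reference = read_matrix(d / "reference.tsv").T
    clock = ClockModel.from_csv(d / "clock.csv", name="clock")

    genotypes = snv_anno = None
    if (d / "genotypes.tsv").exists():
        genotypes = pd.read_csv(d / "genotypes.tsv", sep="\t", index_col=0,
                                na_values="NA")
        snv_anno = pd.read_csv(d / "snv_annotation.tsv", sep="\t", index_col=0)

    truth = None
    if (d / "ground_truth.json").exists():
        with open(d / "ground_truth.json") as fh:
            t = json.load(fh)
        truth = GroundTruth(
            true_fractions=pd.DataFrame.from_dict(t["true_fractions"],
                                                  orient="index").loc[sheet.index],
            spiked_dmps=pd.DataFrame(t["spiked_dmps"],
                                     columns=["probe_id", "delta"]),
            dmr_regions=t["dmr_regions"],
            mqtl_pairs=pd.DataFrame(t["mqtl_pairs"],
                                    columns=["snv_id", "cpg_id", "effect"]),
            true_methylation_ages=pd.Series(t["true_methylation_ages"]).loc[sheet.index],
            batch_assignments=sheet[[c for c in ("Plate", "Chip", "Position")
                                     if c in sheet]],
            qc_fail_probes=t["qc_fail_probes"],
            qc_fail_samples=t["qc_fail_samples"],
            cs_probes=t["cs_probes"],
        )
    config = None
    if (d / "config.yaml").exists():
        with open(d / "config.yaml") as fh:
            config = SimulationConfig.from_dict(yaml.safe_load(fh))
    return SimulatedDataset(beta=beta, detection_p=detection_p,
                            bead_counts=bead_counts, sample_sheet=sheet,
                            annotation=anno, reference=reference, clock=clock,
                            truth=truth, config=config, genotypes=genotypes,
                            snv_annotation=snv_anno)


def write_table(df: pd.DataFrame, path, thresholds: dict | None = None,
                index: bool = False) -> None:
    """CSV with a leading comment block naming the thresholds used."""
    with open(path, "w") as fh:
        for k, v in (thresholds or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=index, float_format=FLOAT_FMT)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """BED export of called regions: 0-based half-open on write only."""
    with open(path, "w") as fh:
        for _, row in dmrs.iterrows():
            name = f"DMR_chr{row['chrom']}_{row['direction']}"
            fh.write(f"chr{row['chrom']}\t{int(row['start']) - 1}\t"
                     f"{int(row['end'])}\t{name}\t0\t.\n")
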