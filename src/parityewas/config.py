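"""Configuration objects for the simulator and the pipeline.

Defaults encode the study conditions of a 192-sample (96 nulligravida /
96 parous), age-matched whole-blood methylation cohort profiled on a
two-chemistry array, with granulocyte-dominated 6-cell-type mixtures.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import yaml

CELL_TYPES = ("CD4T", "CD8T", "NK", "B", "Mono", "Gran")


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its valid domain."""


@dataclass
class DmrSpec:
    """A planted differentially methylated region.

    Member CpGs are placed consecutively on ``chrom`` with inter-CpG gaps
    drawn up to ``gap_bp`` (≤ 1000 so the region satisfies the DMR calling
    rule by construction), each shifted by ``delta`` (beta scale) in the
    parous group.
    """

    chrom: int = 17
    n_cpgs: int = 7
    gap_bp: int = 200
    direction: str = "hyper"
    delta: float = 0.02

    def __post_init__(self) -> None:
        if self.n_cpgs < 5:
            raise ConfigurationError("a DMR spec needs n_cpgs >= 5")
        if not (0 < self.gap_bp <= 1000):
            raise ConfigurationError("inter-CpG gap must be in (0, 1000] bp")
        if self.direction not in ("hyper", "hypo"):
            raise ConfigurationError("direction must be 'hyper' or 'hypo'")
        if self.delta <= 0:
            raise ConfigurationError("delta is a magnitude; must be > 0")


def _default_dirichlet() -> dict:
    # Concentration 30 around Table-1-like mixture means; the parous group
    # shifts NK (+0.020, Cohen's d ~ 0.4), Mono (+0.010) and CD8 (+0.004)
    # at the expense of granulocytes.
    nulli = {"CD4T": 0.080, "CD8T": 0.035, "NK": 0.080,
             "B": 0.095, "Mono": 0.110, "Gran": 0.600}
    parous = {"CD4T": 0.080, "CD8T": 0.039, "NK": 0.100,
              "B": 0.095, "Mono": 0.120, "Gran": 0.566}
    conc = 30.0
    return {
        "nulligravida": [conc * nulli[c] for c in CELL_TYPES],
        "parous": [conc * parous[c] for c in CELL_TYPES],
    }


def _default_dmr_specs() -> list:
    return [
        DmrSpec(chrom=17, n_cpgs=7, gap_bp=205, direction="hyper", delta=0.02),
        DmrSpec(chrom=19, n_cpgs=14, gap_bp=75, direction="hypo", delta=0.025),
    ]


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic parity-EWAS cohort."""

    n_samples_per_group: int = 96
    n_probes: int = 10_000
    n_cell_types: int = 6
    dirichlet_params_by_group: dict = field(default_factory=_default_dirichlet)
    n_spiked_dmps: int = 300
    spiked_delta_range: tuple = (0.01, 0.16)
    dmr_specs: list = field(default_factory=_default_dmr_specs)
    n_mqtl_snvs: int = 6
    mqtl_effect: float = 0.5       # logit-scale shift per alternate allele
    mqtl_maf: float = 0.3
    batch_levels: dict = field(default_factory=lambda: {"Plate": 4, "Chip": 24, "Position": 8})
    batch_sd: float = 0.05         # logit-scale per-probe, per-level shift sd
    noise_sd: float = 0.10         # logit-scale residual sd
    n_clock_cpgs: int = 50
    maa_offset_years: float = -2.0  # negative: parous biologically younger
    maa_residual_sd: float = 4.0    # per-sample biological-age deviation, years
    age_range: tuple = (25.0, 70.0)
    # cell-specific effects: list of (cell_type, logit shift, n probes)
    cs_effects: list = field(default_factory=list)
    # planted QC failures (fractions of probes)
    frac_detection_fail: float = 0.01
    frac_bead_fail: float = 0.005
    frac_non_cpg: float = 0.005
    frac_snp_related: float = 0.010
    frac_multi_hit: float = 0.005
    frac_non_autosomal: float = 0.020
    n_failed_samples: int = 0
    # treatment concordance among matched pairs (both on / both off)
    n_pairs_treatment_on: int = 40
    n_pairs_treatment_off: int = 14
    frac_type_i_probes: float = 0.16
    n_signature_per_type: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples_per_group", "n_probes", "n_cell_types"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_spiked_dmps < 0 or self.n_clock_cpgs < 0 or self.n_mqtl_snvs < 0:
            raise ConfigurationError("counts must be non-negative")
        lo, hi = self.spiked_delta_range
        if not (0 < lo <= hi < 0.2):
            raise ConfigurationError("spiked_delta_range must lie within (0, 0.2)")
        if not (0 < self.mqtl_maf <= 0.5):
            raise ConfigurationError("mqtl_maf must be in (0, 0.5]")
        for group, params in self.dirichlet_params_by_group.items():
            if len(params) != self.n_cell_types:
                raise ConfigurationError(
                    f"dirichlet parameters for {group!r} have length "
                    f"{len(params)}, expected n_cell_types={self.n_cell_types}")
            if any(p <= 0 for p in params):
                raise ConfigurationError("dirichlet parameters must be strictly positive")
        self.dmr_specs = [
            d if isinstance(d, DmrSpec) else DmrSpec(**d) for d in self.dmr_specs
        ]
        if self.noise_sd < 0 or self.batch_sd < 0:
            raise ConfigurationError("noise_sd and batch_sd must be >= 0")

    @property
    def cell_types(self) -> Sequence[str]:
        if self.n_cell_types == len(CELL_TYPES):
            return CELL_TYPES
        return tuple(f"CT{i+1}" for i in range(self.n_cell_types))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dmr_specs"] = [dataclasses.asdict(s) for s in self.dmr_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("spiked_delta_range", "age_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "cs_effects" in d:
            d["cs_effects"] = [tuple(e) for e in d["cs_effects"]]
        return cls(**d)


@dataclass
class PipelineConfig:
    """End-to-end pipeline thresholds, stage toggles, and input paths.

    Threshold defaults are the analysis constants: detection p 0.01,
    bead-count rule 3 beads in >= 5% of samples, DMP rule FDR < 0.05 and
    |Δmeth| >= 1%, DMR rule >= 5 member CpGs at FDR < 0.01 within 1000 bp,
    Cohen's d 0.15, cell-specific threshold p <= 9e-8, mQTL window 5 kb,
    HWE 1e-5, MAF 0.05, call rate 0.95, 70/30 split, alpha-level 0.05.
    """

    input_dir: str = ""
    output_dir: str = "results"
    detection_p: float = 0.01
    sample_fail_ratio: float = 0.1
    bead_min: int = 3
    bead_fail_fraction: float = 0.05
    dmp_fdr: float = 0.05
    dmp_delta: float = 0.01
    dmr_min_cpgs: int = 5
    dmr_fdr: float = 0.01
    dmr_max_gap: int = 1000
    cohens_d_threshold: float = 0.15
    csdmp_p: float = 9e-8
    mqtl_window: int = 5000
    hwe_p: float = 1e-5
    maf: float = 0.05
    call_rate: float = 0.95
    train_fraction: float = 0.7
    alpha_level: float = 0.05
    ld_r2: float = 0.8
    svd_components: int = 10
    batch_p: float = 0.01
    deconv_method: str = "nnls"
    stages: dict = field(default_factory=lambda: {
        "qc": True, "bmiq": True, "batch": True, "deconvolution": True,
        "dmp": True, "dmr": True, "csdmp": True, "mqtl": True,
        "elastic_net": True, "clocks": True,
    })
    seed: int = 0

    _DOMAINS = {
        "detection_p": (0, 1), "sample_fail_ratio": (0, 10),
        "bead_fail_fraction": (0, 1), "dmp_fdr": (0, 1), "dmp_delta": (0, 1),
        "dmr_fdr": (0, 1), "cohens_d_threshold": (0, 10), "csdmp_p": (0, 1),
        "hwe_p": (0, 1), "maf": (0, 0.5), "call_rate": (0, 1),
        "train_fraction": (0, 1), "alpha_level": (0, 1), "ld_r2": (0, 1),
        "batch_p": (0, 1),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._DOMAINS.items():
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ConfigurationError(f"{name}={v} outside ({lo}, {hi}]")
        for name in ("bead_min", "dmr_min_cpgs", "dmr_max_gap", "mqtl_window",
                     "svd_components"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.deconv_method not in ("nnls", "svr"):
            raise ConfigurationError("deconv_method must be 'nnls' or 'svr'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
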