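# parityewas

Whole-blood and immune-cell-type-specific epigenome-wide association
analysis (EWAS) of **parity** — whether a woman has given birth — in a
matched cohort of women with multiple sclerosis, implemented as a
reusable, tested Python pipeline with a synthetic-cohort generator so
that every stage can be validated by parameter recovery without access
to patient-level data.

It is written for methylation analysts who want the full analysis chain
of such a study as inspectable, scriptable code: quality control and
normalization of array beta values, batch correction, reference-based
cell-type deconvolution, covariate-adjusted differential methylation,
region calling, per-cell-type interaction models, conditional mQTL
analysis, penalized feature selection, and methylation-age
acceleration.

## The analysis in brief

Methylation at probe *g* in sample *i* is a beta value
β<sub>gi</sub> ∈ (0,1) (M = log₂(β/(1−β)) where variance stabilization
matters). After QC (samples with failed/successful detection ratio
> 0.1; probes with detection p > 0.01, bead count < 3 in ≥ 5 % of
samples, non-CpG / SNP-related / non-autosomal / multi-hit), BMIQ
normalization and empirical-Bayes batch correction, the pipeline fits
per CpG

> β<sub>g</sub> ~ parity + CD4T + CD8T + NK + B + Mono + DNAmPACKYRS

with cell fractions estimated by reference-based deconvolution and
DNAmPACKYRS a methylation-derived smoking biomarker. Differentially
methylated positions (DMPs) satisfy Benjamini–Hochberg FDR < 0.05 and
|Δmeth| ≥ 1 % (Δmeth = parous − nulligravida mean β). Regions (DMRs)
are runs of ≥ 5 DMPs with FDR < 0.01, the same direction, and ≤ 1000 bp
between neighbours. Cell-type-specific DMPs come from one model per
cell type,

> M<sub>g</sub> ~ parity + fraction + fraction × parity,   csDMP ⇔ p ≤ 9×10⁻⁸,

mQTLs from Kruskal–Wallis and conditional β ~ genotype + parity models
in ±5 kb windows around called DMRs, a CpG panel from CV-tuned
elastic-net logistic regression (70/30 split), and methylation age
acceleration (MAA) as the residual of regressing clock-predicted age on
chronological age, compared between groups with a Shapiro–Wilk-gated
one-tailed test.

## Worked example

Simulate a cohort at the study's design size (96 nulligravida + 96
parous; 2,000 probes for speed here), run the stages, and look at the
planted-versus-recovered quantities:

```python
import numpy as np
from parityewas import SimulationConfig, simulate_cohort, simulate_genotypes
from parityewas import deconvolution as dec, differential as diff
from parityewas.clocks import apply_clock, compute_maa, compare_maa

cfg = SimulationConfig(n_probes=2000, n_samples_per_group=96,
                       n_spiked_dmps=100, n_signature_per_type=50, seed=1)
ds = simulate_cohort(cfg)
simulate_genotypes(cfg, ds)

fractions = dec.estimate_cell_fractions(ds.beta, ds.reference)
models = diff.fit_dmp_models(ds.beta, ds.sample_sheet, fractions)
table, summary = diff.call_dmps(models, ds.annotation)
dmrs = diff.call_dmrs(table)
print(f"DMPs: {summary['n_dmps']} ({summary['pct_hyper']:.1f}% hyper)")
print(f"DMRs: {len(dmrs)} with member counts {list(dmrs['n_cpgs'])}")

ages = apply_clock(ds.beta, ds.clock)
maa = compute_maa(ages, ds.sample_sheet["age"])
rep = compare_maa(maa, ds.sample_sheet)
print(f"MAA Δμ = {rep['delta_mu_years']:.2f} y (p = {rep['p_value']:.1e})")
```

Output:

```
DMPs: 114 (64.9% hyper)
DMRs: 2 with member counts [5, 12]
MAA Δμ = 2.35 y (p = 8.4e-06)
```

114 planted effects pass both thresholds (100 spiked positions with
|Δmeth| up to 16 %, ~68.5 % of them hypermethylated, plus most planted
region members), both planted regions — 7 hypermethylated and 14
hypomethylated CpGs, mirroring the reported TMC8- and ZNF577-like
regions — are called (here with 5 and 12 of their members crossing
FDR < 0.01: the planted per-CpG deltas of 2–2.5 % sit near the
detection edge at n = 192, as in the study), and the planted −2-year
parous offset in biological age is estimated at Δμ = 2.35 years
(one-seed Monte-Carlo error ≈ 0.6 y) and detected.

The same run is available from the shell:

```bash
parity-ewas simulate --seed 1 --n-probes 2000 --out cohort/
parity-ewas run-all --in cohort/ --out results/ --seed 1
```

which writes `dmps.csv`, `dmrs.csv` (+ BED), `csdmps.csv`,
`cell_fractions.csv`, `mqtl.csv`, `elastic_net_panel.csv`, `maa.csv`, a
QC report and a reproducibility manifest.

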