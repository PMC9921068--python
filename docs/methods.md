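# Methods

`parityewas` reimplements, as a tested library and CLI, a whole-blood and
immune-cell-type-specific epigenome-wide association study (EWAS) of
parity in women with multiple sclerosis, together with a synthetic-cohort
generator that gives every analysis stage a parameter-recovery test
surface. This note records the models, the generator's assumptions, the
numerical choices, and the places where the design was genuinely open.

## The analysis model

Methylation is carried as beta values β ∈ (0,1) (fraction methylated per
CpG) and, where variance stabilization matters, as M-values
M = log2(β/(1−β)).

**Quality control.** Samples are removed when their failed-to-successful
probe ratio exceeds 0.1 (a probe fails within a sample when its
detection p exceeds 0.01; the comparison is strict). Probes are then
removed, with first-matching reasons recorded in this order: detection
p > 0.01 in any retained sample; bead count < 3 in ≥ 5 % of samples;
non-CpG; SNP-related; non-autosomal (chromosome outside 1–22);
multi-hit. Samples are filtered before probes, matching the order the
filters are conventionally listed; the multi-hit list is an input, not a
computation.

**BMIQ.** Per sample, a three-state (unmethylated / hemimethylated /
methylated) beta-mixture is fit by EM separately to the type-I and
type-II probe distributions. Each type-II value is assigned to its
maximum-posterior state and mapped through that state's fitted beta CDF
onto the corresponding type-I state's quantile function; type-I values
pass through unchanged. The mapped values are then re-assigned in rank
order, so the within-sample ordering of type-II probes is preserved
exactly (state-wise quantile maps alone cannot guarantee monotonicity at
state boundaries). EM details: responsibilities with weighted
method-of-moments beta-parameter updates, states initialised at means
0.1/0.5/0.9, values clamped to [0.001, 0.999] before fitting,
convergence at 1e-4 relative change in log-likelihood, 500 iterations
maximum; a non-converging sample is left unadjusted with a warning. For
speed the mixture is fit on at most 5000 probes per type and applied to
all.

**Batch effects.** The probe-centered beta matrix is decomposed by SVD
and each of the top k (default 10) right singular vectors is tested
against each candidate factor — Kruskal–Wallis for categorical factors,
a correlation test for continuous ones — at p < 0.01. Significant
factors are corrected with parametric empirical-Bayes location/scale
adjustment (ComBat), applied sequentially per batch variable in the
order Plate, chip, position. The standardization step includes the
parity indicator as a protected covariate, so batch estimates are not
contaminated by group signal — without this, small chip-level batches
visibly attenuate planted group effects. Output is clipped back into
(0,1).

**Deconvolution.** Six cell-type fractions (CD4+ T, CD8+ T, NK, B,
monocyte, granulocyte) are estimated per sample on a signature-probe
subset of the cell-type reference. The default solver is non-negative
least squares renormalized to the unit simplex — deterministic and
dependency-light; a nu-SVR mode (linear kernel, ν = 0.5) emulating the
support-vector deconvolution family is available and agrees with NNLS
within 0.02 on noiseless mixtures. Signature probes are the top 100 per
cell type by absolute one-vs-rest mean difference in the reference
(capped at 600). With one reference profile per type there is no
within-type variance, so an F-statistic degenerates to exactly this
contrast. Group differences in fractions are summarized by Cohen's d
with the pooled-SD denominator; |d| > 0.15 is flagged non-negligible.

**Whole-blood DMPs.** Per probe, an ordinary least-squares model of beta
on the parity indicator, five cell fractions (granulocytes dropped as
the simplex reference — including all six is rank-deficient and raises),
and the smoking biomarker (a methylation-derived pack-years estimate).
The "logistic" label sometimes attached to this model in array
pipelines is a misnomer for beta-scale outcomes; OLS on beta is what the
underlying pipeline computes, and moderated (empirical-Bayes) variances
are deliberately not used — the difference is documented rather than
hidden. All per-probe fits share one design matrix, so the whole scan is
a single vectorized normal-equations solve. Δmeth is defined as parous
minus nulligravida mean beta; positive means hypermethylated in the
parous group, consistently across DMPs, DMRs and the sensitivity scan.
DMPs satisfy Benjamini–Hochberg FDR < 0.05 and |Δmeth| ≥ 0.01 (BH is
used wherever "FDR" appears).

**DMRs.** From the DMP list only: per chromosome and effect direction,
maximal runs of DMPs with FDR < 0.01 and the same Δmeth sign, in which
consecutive members lie within 1000 bp; runs of ≥ 5 members are
regions. Width is last minus first member position (1-based, no +1
endpoint correction — validated against the printed widths 1233 and
979 bp). Non-significant CpGs between members do not break a run: the
rule is stated purely over DMPs. The caller is order-invariant and is
tested against an all-windows brute-force enumeration.

**Cell-type-specific DMPs.** One interaction model per cell type on
M-values: M ~ parity + fraction + fraction×parity, with the interaction
coefficient as the cell-specific parity contrast ("Est" in the
corresponding result tables is read as this coefficient). The joint
all-cell-types model is deliberately not used — one model per type
avoids overburdening a 192-sample design. Estimated (not true)
fractions enter the model, propagating deconvolution error as in
practice. Significance is raw p ≤ 9×10⁻⁸ (the array genome-wide
threshold); no FDR layer is added.

**Sensitivity scan.** For each matched (nulligravida, parous) pair the
genome-wide mean Δmeth is computed; each covariate is tested against
these pair-level summaries — Pearson for continuous, one-way F for
categorical covariates — with BH-FDR 0.05 across covariates. Treatment
status is tested only on pairs concordant for treatment.

**mQTL.** SNVs pass sample call-rate ≥ 95 %, then per-SNV filters:
call rate ≥ 95 %, non-monomorphic, MAF ≥ 0.05, exact Hardy–Weinberg
p ≥ 1e-5 (Wigginton-style exact conditional test, validated against full
enumeration), autosomal. Monomorphism is recorded before MAF so the
degenerate case gets the more informative label; the retained set is
unaffected by this ordering. Within [start−5 kb, end+5 kb] of each
called region, a greedy position-ordered LD-pruning keeps SNVs whose
dosage r² with every kept SNV is < 0.8 (the threshold is unstated in
the source analysis; 0.8 is the common pruning default). Each kept SNV
is tested against every member CpG: Kruskal–Wallis of beta across
dosage groups (empty groups dropped), then OLS beta ~ dosage(additive)
+ parity, α = 0.05 throughout; missing dosages are dropped pairwise,
never imputed. Beta (not M) is the outcome, matching "methylation as
the dependent variable".

**Elastic net.** Penalized logistic regression of parity on CpG
features with the glmnet objective
λ·Σⱼ pfⱼ·(α|wⱼ| + (1−α)/2 wⱼ²); cell fractions and the smoking
biomarker enter with penalty factor 0 (unpenalized), preserving their
adjustment semantics. The solver is FISTA proximal gradient with warm
starts along a 20-point log-spaced lambda path from λ_max; at λ = 0 it
reproduces the unpenalized maximum-likelihood fit to 1e-4. Tuning
sweeps α ∈ {0, 0.1, …, 1} with 10-fold cross-validated binomial
deviance; for each α the one-standard-error lambda is taken
(cv.glmnet's rule), and the final α is the largest one statistically
tied (within one SE) with the global CV optimum — on signal-free input
this returns an empty or near-empty panel instead of a dense ridge fit,
while a plain argmin (`rule="min"`) is available. The final model is
refit on a stratified 70/30 split (192 samples → 134 train / 58 test,
matching the study's split); importance is 100·|standardized
coefficient| / max over selected features. The two cross-validation
phases both use 10 folds (the source is ambiguous between "10
iterations" and unstated-k k-fold).

**Clocks and MAA.** A clock is an intercept plus per-CpG weights (years
per beta unit); methylation age is the weighted sum, with ≥ 80 % of
clock CpGs required and missing ones imputed at the cohort grand-mean
beta. MAA is the residual of regressing methylation age on
chronological age — the standard direction, yielding residuals in
methylation-age years; the literal reverse regression (chronological on
methylation) is available as `strict_wording=True` because the source
describes it that way. Group comparison is gated by Shapiro–Wilk on the
residuals: normal → one-tailed Welch t (alternative: parous accelerate
less; equal variances are not assumed), otherwise one-sided
Mann–Whitney. Δμ is reported as nulligravida mean minus parous mean, so
a planted −2-year parous offset is recovered as +2. Within the parous
group MAA is correlated (Pearson) with years since last conception, and
an age-50 dichotomy (menopause proxy) is tested by two-sample t-test.
In the pipeline the clocks stage consumes QC'd but un-BMIQ'd betas: the
bundled clock is defined on the raw beta scale and BMIQ's within-sample
quantile remap would rescale its CpGs — mirroring real clocks, which
prescribe their own preprocessing.

## The synthetic cohort

The generator's defaults are the study conditions: 96 + 96 age-matched
samples (uniform 25–70 years, pair partners within 3 years), 10,000
probes (a deliberate scale-down of the ~747,000 retained array probes;
planted-structure counts scale accordingly), six cell types with
Dirichlet-distributed fractions (concentration 30 around
granulocyte-dominated means; the parous concentrations shift NK by
+0.020 — targeting Cohen's d ≈ 0.4 — monocytes by +0.010 and CD8 by
+0.004), 300 spiked positions with |Δmeth| ∈ (0.01, 0.16) and a 68.5 %
hypermethylation probability, and two planted regions mirroring the
reported ones (7 hypermethylated CpGs at ~205 bp spacing; 14
hypomethylated CpGs at ~75 bp spacing).

All effects — spikes, batch shifts, mQTL dosage effects, residual noise
(sd 0.1 on the logit scale ≈ 1–2.5 % beta-scale technical noise) — are
additive on logit(β) and mapped back through the logistic function.
Spike magnitudes are specified on the beta scale and converted to logit
shifts at each probe's baseline, so the realized group difference
matches the requested Δmeth. Batch structure: per-probe Gaussian shifts
(sd 0.05) per level of Plate (4), Chip (24, 8 samples each) and
Position (8), with randomized within-pair sample placement so no batch
level is confounded with group (deterministic interleavings confound
array position with parity exactly). Detection p-values are
Uniform(0,1)·1e-3 for good probe/sample cells and Uniform(0.01,1) at
planted failures; bead counts are Poisson(15) floored at 3, with
planted low-count probes; flags (non-CpG, SNP-related, multi-hit,
chromosome X) are planted at configurable fractions on probes carrying
no other structure, so QC recovery is checkable probe-for-probe.

Clock CpGs (50) carry a linear trend in "biological age"
A = age + offset·parous + N(0, 4 yr) on the beta scale (slopes 0.4–0.8
per 100 years around mid-range baselines, 0.01 beta noise), and the
bundled toy clock's weights invert that construction, so
clock(β) ≈ A + small noise and the chronological-age correlation is
~0.95 (the study's clocks print 0.77 and 0.91). The default MAA offset
is −2.0 years (parous biologically younger), inside the reported
1.44–2.27-year range.

mQTL SNVs are drawn under Hardy–Weinberg equilibrium at MAF 0.3 within
±5 kb of the planted regions; each effect SNV shifts one member CpG by
0.5 logit units per alternate allele, and where a region receives two
SNVs the second is an LD companion (r² near 1, no direct effect) to
exercise the pruning step. Cell-type-specific effects multiply a logit
shift by the sample's cell fraction; the test suite plants CD8 shifts
of 4.0 logit units — an interaction estimate of ≈ 5.8 M-value units per
unit fraction, inside the printed csDMP estimate range (|Est| 2.1–8.3).
Smaller shifts (e.g. 1.5) sit below the 9×10⁻⁸ detection edge at this
design size, which matches the marginal |t| ≈ 4.7–5.7 implied by the
printed estimates and standard errors.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: raw-intensity (IDAT) structure and
dye-bias; probe-wise variance heterogeneity (one noise_sd is exposed
rather than an empirical variance distribution); genomic correlation of
methylation beyond the planted regions; haplotype-level LD beyond
pairwise-correlated SNV pairs; longitudinal pregnancy dynamics; and the
type-I/type-II distributional offset that motivates BMIQ (BMIQ tests
construct their own two-chemistry fixtures).

## Numerical choices and degenerate inputs

- Beta values are clipped to [1e-6, 1−1e-6] before logit/M transforms;
  BMIQ clamps to [0.001, 0.999] before mixture fitting.
- Per-probe OLS scans are one vectorized normal-equations solve; rank
  deficiency is detected first and reported with the collinear column
  names. Agreement with statsmodels OLS is asserted to 1e-8 in tests.
- The exact HWE test computes all heterozygote configurations in log
  space; ties at the observed probability are included with a 1e-12
  relative tolerance. Symmetry under allele relabeling is a property
  test.
- ComBat's empirical-Bayes fixed point iterates to 1e-4 with a cap of
  100 iterations; batch variables with one level are no-ops; a batch
  level with one sample is an error naming the level.
- The DMR caller sorts internally; unsorted input is never an error.
- FISTA runs at tolerance 1e-5/300 iterations inside cross-validation
  (warm-started) and 1e-8/5000 for final fits; the Lipschitz constant
  is the spectral norm of the standardized design, computed once per
  fold.
- Elastic-net candidate features in the full pipeline are the top 300
  probes by single-probe p-value — a tractable stand-in for feeding all
  retained probes to the solver at full array scale.

## Problem sizes in the test and acceptance suites

Recovery and calibration suites run at the study's sample size
(96 + 96) with probe counts of 1,200–10,000 chosen per check: FDR
calibration uses 20 null cohorts of 10,000 probes; spike recovery 8
cohorts of 2,000 probes at |Δ| = 0.05; region recovery 20 cohorts with
two planted 5-CpG regions; cell-specific power 20 cohorts of 1,500
probes; MAA recovery 20 cohorts of 1,200 probes. These sizes give each
binomial acceptance bound a comfortable margin while keeping the full
suite within a few minutes on one CPU.

## Known limitations

- BMIQ here is a faithful re-derivation, not a port; its hemimethylated
  state handling (beta-CDF mapping plus rank reassignment) differs in
  detail from the original's dilation step.
- Ordinary (not moderated) variances in all per-probe models; at n=192
  the difference is small but real for low-variance probes.
- The deconvolution reference is synthetic; absolute fraction accuracy
  on real arrays depends on reference quality in ways the tests cannot
  measure.
- The elastic-net solver is first-order; at extreme conditioning (near
  lambda 0 with p ≈ n) it needs many iterations, which the tests bound
  but real full-array use would want a coordinate-descent backend for.
- Headline cohort counts (2965 DMPs, 12 csDMPs, the exact Δμ values)
  depend on the unpublished patient-level data and are not reproduced;
  the package reproduces the rules, thresholds, and printed worked
  examples, and demonstrates parameter recovery under its own
  generative model.
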