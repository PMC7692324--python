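# Methods

## The quartile filter

The central procedure is a supervised, distribution-free feature selection
over CpG probes. For each probe and each (cancer, tissue) group the first
and third quartiles (Q1, Q3) of the group's beta values are computed;
missing values are dropped per group first, and a group with fewer than
`min_group_size` (default 2) non-missing values makes the probe uncallable
for any target that needs it — a logged "none", never an error or a silent
call. The four class rules (README table) are then evaluated per target
cancer with strict inequalities: a quartile exactly equal to a threshold
does not fire a rule. Reading "Q1 > 0.6" as "more than 75% of the group is
above 0.6" is what makes the selection outlier-robust: a single aberrant
sample cannot create or destroy a call in a group of reasonable size.

**Assumptions.** Groups are treated as exchangeable samples of one
population per (cancer, tissue); no normalization, batch correction or
purity adjustment is attempted (inputs are assumed preprocessed). The rules
quantify over "every other cancer", so at least two cancer types are
required and a run with one errors out; up to 12 are accepted.

**Parameters.** `hyper_threshold` (beta, default 0.6) and `hypo_threshold`
(beta, default 0.3) with 0 ≤ hypo < hyper ≤ 1; raising hyper or lowering
hypo can only shrink the called set (monotonicity, property-tested).
`quantile_method` defaults to linear interpolation between order statistics
(the numpy/pandas default); a nearest-rank mode is available because calls
near a threshold can depend on the convention, and the chosen method is
echoed into the calls export header.

**Precedence.** For a single target cancer the four rule sets are mutually
exclusive whenever hypo < hyper (each pair demands contradictory
inequalities of some group), which the suite asserts empirically. Across
targets a probe could in principle satisfy pairs for different targets; the
winning call is the first satisfied (target, class) pair taking targets in
manifest order and classes in the order cancer-hyper, cancer-hypo,
tissue-hyper, tissue-hypo, while every satisfied pair is retained in the
long-format output.

## Comparative differential methylation

Per probe and cancer, tumor vs normal is compared with a two-sided
Mann–Whitney U test, where U counts (tumor, normal) pairs with tumor >
normal (ties ½). The p-value is exact — the permutation distribution of U —
whenever the pooled values are untied and the smaller group has at most 25
samples; beta values are continuous so ties are rare, and at these cohort
sizes the exact test keeps the true size close to the nominal level (at
n = 20 vs 10 the exact test's size at α = 0.05 is 0.049 against 0.044 for
the continuity-corrected normal approximation). Larger or tied samples use
the normal approximation with tie and continuity correction.

Multiple testing is adjusted with Benjamini–Hochberg step-up FDR, applied
within each cancer across the probes of the analysed subset (not
genome-wide); the scope is recorded in the run manifest. The effect size is
log2((mean_T + ε)/(mean_N + ε)) of group mean betas with ε = 10⁻⁶ guarding
zero means; a median-ratio mode exists. The volcano call is hyper when the
gating value (BH q by default; raw p in `adjust='none'` mode) is < α = 0.05
and log2 FC > 1, hypo when < −1, both cutoffs strict. The default gate is
FDR because that is what headline counts of such analyses usually report;
the raw-p mode matches volcano-plot conventions.

## Clustering

"Semi-unsupervised": probes (rows) are clustered agglomeratively — Euclidean
distance, average linkage, scipy's deterministic ordering — while samples
(columns) stay in known (cancer, tissue) blocks, in manifest order and
stable within each block. Missing cells are mean-imputed per probe before
distance computation (recorded in the run manifest); the merge tree is
exportable as Newick, and the heatmap's TSV twin is the bit-exact reordered
input matrix.

## Methylation–expression integration

Each filtered probe is paired with every expression feature of its
annotated genes (case-insensitive symbol match; a feature→gene map handles
transcript-level matrices, otherwise feature ids are taken as gene
symbols). Pearson r is computed per pair over shared non-missing samples
(≥ 3 required) after a log2(FPKM+1) transform — raw mode behind a flag —
and pairs are reported when |r| ≥ the cutoff (default 0.6). Pairs with a
zero-variance vector are dropped with a logged reason. This is deliberately
a plain per-pair correlation on matched samples, not a latent-component
correlation from a multi-omics factorization; the pairs TSV header says so.

## Synthetic cohorts

The generator emulates the group structure the filter assumes: for 2–12
cancer types, paired tumor/normal groups whose beta values are drawn from
Beta distributions — high state Beta(50, 5) (mean ≈ 0.909), low state
Beta(2, 30) (mean 0.0625), background Beta(10, 10) (mean 0.5). The
high/low means clear the 0.6/0.3 thresholds by a wide margin, so planted
patterns are the study's "strong separation" condition. Each planted probe
assigns its groups to high/low states according to its class (e.g.
cancer-hyper: target tumor high, all seven other groups low); background
probes draw all groups from the mid state. Planted probes receive a
synthetic one-gene, CpG-island, promoter annotation; background probes are
open-sea and unannotated. Default cohort sizes used throughout the tests
and the acceptance script: 4 cancers, 20 tumor + 10 normal each, 500
background + 40 planted probes (10 per class).

Matched expression is generated per planted gene as a latent
log2-expression that is an affine function of the probe's standardized
betas plus Gaussian noise scaled so the expected Pearson correlation equals
ρ (default −0.9; noise 0 with |ρ| = 1 gives exactly ±1), then mapped to
FPKM as 2^latent − 1 so the downstream log2(FPKM+1) transform recovers the
latent scale exactly.

One random stream per matrix, seeded from the config seed, draws probes in
a fixed order (planted first), so enlarging the background never perturbs
planted draws; a separate stream drives missingness. Same config ⇒
bit-identical output.

**What the generator does not emulate** — and hence what passing tests do
not show about real 450K data: probe–probe covariance along the genome,
batch and array effects, tumor purity mixtures, the empirical bimodal
beta-value landscape, and sample pairing within patients (groups are
independent draws). Recovery results on synthetic cohorts demonstrate
algorithmic correctness under the stated group model, not expected yield on
TCGA-scale data.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics by default;
  NaNs excluded before quantiles.
* Strict threshold inequalities everywhere (filter rules, volcano cutoffs).
* Mann–Whitney with an empty group errors; with all values tied across both
  groups returns U = n₁n₂/2, p = 1.
* BH adjustment rejects p outside [0, 1]; q is capped at 1 and never below
  the raw p.
* log2 fold change guards zero means with ε = 10⁻⁶.
* Clustering requires ≥ 2 items; identical rows merge at height 0.
* Correlation pairs need ≥ 3 shared samples and non-zero variance.
* Beta-matrix reading rejects values outside [0, 1] and duplicate
  probe/sample ids by name; merge keeps the probe intersection by default
  (union with missing cells behind a flag) because downstream quartiles
  need complete groups.
* "Promoter region" is operationalized as any TSS200/TSS1500/5'UTR gene
  region in the 450K annotation; the CpG-island filter is exposed
  independently, since island membership and promoter association are
  related but not identical.

## Problem sizes

The test suite and `scripts/acceptance.py` run entirely on simulated data
at desk scale: the standard 540-probe × 120-sample cohort above, a
2000-probe null cohort for the type-I check, 100 gene–probe pairs over 60
samples for correlation recovery, ≤ 20 items against the O(n³) clustering
oracle, and 10⁴ random probes for the rule-oracle equivalence property.
Both complete in well under five minutes on one CPU.

## Known limitations

Rule-based calls carry no significance measure by design; the filter is a
screen, not a test. Counts from real cohorts depend on preprocessing
(normalization, probe masking) that is out of scope here. The integration
step's plain Pearson correlation is not comparable to latent-space
correlations reported by multi-omics factorization tools. IDAT parsing,
DMR aggregation, covariate adjustment and paired-sample testing are not
implemented.
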