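# Methods

This note documents the models and procedures implemented in
`spatialrisk`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Spatial eQTL calling

A candidate SNP is assigned to the unique restriction fragment containing
its position (0-based half-open intervals; a position on a fragment
boundary belongs to the right-hand fragment). A (SNP, gene) pair is
*spatially supported* when some Hi-C contact links the SNP's fragment to a
fragment overlapping the gene body, subject to two exclusions:

- **Adjacency.** Same-chromosome contacts with fragment-index separation
  < 2 (self and immediate neighbours) are ignored: proximity ligation
  cannot distinguish a real contact between contiguous restriction sites
  from an undigested site. The cutoff of two indices is this package's
  operationalisation; the underlying artefact argument fixes only the
  self/neighbour cases.
- **Intragenic pairs.** A SNP inside its target gene is testable only if
  the gene overlaps ≥ 3 fragments; shorter genes admit only self/adjacent
  contacts, which the first rule removes.

Contacts from multiple Hi-C libraries are unioned, and the supporting
library labels are aggregated per pair. The spatially supported subset of
a tissue-specific eQTL table is corrected with the Benjamini–Hochberg
step-up procedure **jointly across all retained (SNP, gene, tissue) rows**
(one pooled FDR per run; a per-tissue variant is available via
`per_tissue_fdr=True`), keeping q < 0.05. Associations are labelled *cis*
when SNP and gene share a chromosome and |pos − TSS| ≤ 1 Mb (inclusive;
TSS is strand-aware, GTEx convention — measuring from the nearest gene
edge instead would reclassify a small boundary set), else *trans*. The
data model deliberately permits one gene to be cis-regulated by one SNP
and trans-regulated by another.

## Genotype QC

Filters run on an integer dosage matrix (0/1/2, missing): sample filters
first (missingness > 5%, then inbreeding F outside [−0.04, 0.025], then
PI_HAT > 0.08), then SNP filters (missingness > 5%, MAF < 1%, exact HWE
p < 10⁻⁶) with frequencies recomputed on the retained samples. Each
removal cites exactly one rule, the first that fired.

- **Inbreeding F** is the method-of-moments estimator
  (O_hom − E_hom)/(N − E_hom) with finite-sample-corrected expected
  heterozygosity 2pq·n/(n−1) at cohort allele frequencies.
- **PI_HAT** estimates P(IBD=1)/2 + P(IBD=2) from IBS-state counts and
  cohort allele frequencies, clipping each IBD-class probability to [0, 1]
  and renormalising. Of a flagged pair, the member with higher missingness
  (ties: lexicographically later id) is removed. A vectorised all-pairs
  implementation (indicator-matrix products) makes cohort-scale
  relatedness screening feasible.
- **HWE** is the exact conditional test: given allele counts, the p-value
  sums the probabilities of all heterozygote counts no more likely than
  the observed one. Monomorphic SNPs return 1 by convention. The
  implementation uses log-gamma arithmetic and is checked against an
  exact integer-arithmetic enumeration oracle.

**Marker-count guards.** F and PI_HAT are moment estimators whose null
sampling noise scales as ~1/√m in the number of informative SNPs m (and
several-fold worse for PI_HAT, which divides by the expected count of the
rare opposite-homozygote IBS class). At the thresholds above, cohorts with
only hundreds of SNPs would have most *unrelated, non-inbred* samples
flagged purely by noise — empirically the maximum null PI_HAT across ~5,000
pairs is ≈ 0.12 at 2,000 SNPs and ≈ 0.04 at 20,000. Both filters are
therefore skipped (and noted in the QC report) when fewer than 10,000
informative SNPs are present (`QcThresholds.f_min_snps`,
`pihat_min_snps`). These filters are meaningful on genome-wide data, which
is where the thresholds originate. Ancestry-outlier and sex-check removal
require reference panels and sex chromosomes outside this package's data
model; the report carries hook fields for them. No LD pruning precedes
relatedness estimation because synthetic SNPs are unlinked by
construction — on real data, pruning first is advisable. No imputation is
performed, so the imputation-quality filter reduces to an optional
per-SNP quality threshold.

## Weighted feature matrix

Only SNPs with complete dosage data across the cohort are used. A SNP
with k ≥ 1 significant eQTL records contributes k columns valued
dosage × NES (one per SNP–gene–tissue triple); a SNP with none contributes
its bare dosage under the pseudo-tissue "SNPs". Columns are sorted by key
and the construction is purely deterministic. Dosages count ALT alleles
as written in the VCF; no re-orientation to a risk allele is attempted
(the NES sign already encodes direction relative to the tabulated effect
allele; whether a real analysis must first harmonise effect alleles to the
cohort's ALT alleles is a data-preparation question outside the matrix
construction). No per-column standardisation is applied by default, so
the regulariser sees NES-scaled features — the direct weighting the matrix
is meant to encode; `standardize=True` enables z-scoring for sensitivity
analysis.

## Predictors and ensembles

Feature relevance is scored per column with a two-sided Mann–Whitney U
test (case vs control values): exact enumeration when both groups have
≤ 20 samples *and* the column is tie-free, otherwise the tie-corrected
normal approximation with continuity correction; constant columns get
p = 1. Columns with BH q ≤ 0.2 are retained (an optional top-N cap
exists for sensitivity analyses but is off by default).

The classifier is logistic regression with elastic-net penalty, SAGA
solver, unpenalised intercept, tolerance 10⁻⁶ and a fixed internal seed.
When every weight is shrunk to zero the intercept is set to the empirical
log-odds in closed form (SAGA stalls on the intercept once the weight
vector freezes at zero). Hyperparameters default to C = 1, l1_ratio = 1,
max_iter = 500 and can be grid-searched (default grid C ∈ {0.01, 0.1, 1,
10} × l1_ratio ∈ {0.2, 0.5, 0.8, 1}) with stratified 10-fold CV, maximising
mean validation AUC; ties prefer the sparser model (larger l1_ratio, then
smaller C).

The ensemble is repeats × k stratified k-fold cross-validation (default
10 × 5 = 50 predictors). Feature selection is re-run inside each training
fold, so the held-out 20% never influences the fitted weights; a
`freeze_selection` flag reproduces the leaky alternative (select once on
the full matrix) for comparison. AUC is computed by the rank/trapezoid
method, with case–control score ties counting one half; it equals the
Mann–Whitney U statistic divided by n₁n₀, and that identity is enforced
in the tests.

## Tissue contributions and ablation

A predictor's tissue contribution is Σ|w| over the tissue's features as a
percent of Σ|w| over all features, with bare-SNP features grouped under
"SNPs" and included in the denominator. Percents are computed **per
predictor first, then averaged** across the ensemble (an all-zero
predictor is flagged degenerate and reports 0% everywhere); the
alternative — summing raw |w| across predictors before normalising —
would let high-weight predictors dominate the ranking, which is why
per-predictor normalisation is the default. Tissues are ranked by mean
percent, ties broken lexicographically.

The ablation experiment drops one feature column and refits the entire
ensemble **with the same seed, hence identical fold assignments** (a
paired design that removes fold-composition variance from the
comparison). Per-tissue percent samples and AUC samples are compared by
two-sided Welch t-tests and by a Bayesian two-group model (below).

## Bayesian AUC model

A set of AUCs y₁…yₙ is modelled as y ~ Normal(μ, σ) with μ ~ Uniform(0, 1)
and σ ~ HalfNormal(scale s₀), s₀ = 0.01 by default — a tight scale prior
appropriate for cross-validation AUC dispersion, exposed as a parameter
(for percent-scale contribution samples the group comparison uses
s₀ = 0.05 after rescaling to [0, 1]). The posterior is sampled with a
2-D random-walk Metropolis sampler: joint Gaussian proposals whose scales
start at the asymptotic posterior SDs (σ̂/√n, σ̂/√2n), are adapted towards
~35% acceptance during 1,000 warmup iterations, and are **frozen before
the retained draws** (default 1,000, unthinned), so the kept chain
satisfies detailed balance for the exact posterior. Correctness is pinned
against a dense 2-D grid-quadrature oracle; determinism is guaranteed by
a single integer seed. Effective sample size (initial-positive-sequence
estimator) and acceptance rate are reported as diagnostics.

95% HPD intervals are the narrowest contiguous interval containing
⌈0.95·n⌉ sorted draws, found by brute force over windows, ties broken by
the lowest window. The two-group comparison fits each group
independently, forms Δ = μ_A − μ_B from paired draws, and reports the
posterior mean, 95% HPD of Δ and P(Δ > 0). Percent-scale inputs are
divided by 100 for fitting and Δ restored to the input scale.

A zero-variance sample is accepted (μ concentrates at the common value);
note its σ posterior is improper at the origin, so only the location
summaries are meaningful in that degenerate case.

## Synthetic data: what it emulates

The generator produces a two-chromosome diploid toy genome tiled by
fixed-length restriction fragments; genes alternate through a configurable
set of fragment spans (default 2 and 4, so both sides of the ≥ 3-fragment
intragenic rule always exist); SNPs fall inside genes with probability
0.25 and are otherwise intergenic. Contacts are Poisson per SNP (default
2 expected random partners) plus constructed instances of every geometric
configuration (self, adjacent, distal cis, trans) and a guaranteed contact
for every planted pair. The eQTL table holds NES ~ Normal(0, 0.5) with
p ~ Uniform(0, 1) for null rows and p = 10⁻⁸ for planted rows; a
configurable fraction of null rows (`null_significant_fraction`, default
0) can be made eQTL-significant-but-disease-null, reflecting that most
real expression QTLs carry no disease effect and populating the feature
matrix with many tissues.

Disease labels follow a logistic model over the planted features: on the
dosage scale each planted feature carries b_f = ±(total effect)/(number of
planted features), with the feature-scale coefficient b_f/NES_f recorded
as ground truth. Defaults plant 3 features on one tissue with total
|b| = 3, planted SNP MAFs drawn from the upper half of the MAF range and
planted |NES| resampled to ≥ 0.2: by liability-scale arithmetic
(σ_logit ≈ √(Σ b²·2pq) ≈ 1.1) the Bayes-optimal AUC is ≈ 0.72, so a
well-fitted sparse model should clear 0.7 at n = 2,000 — the regime the
recovery tests probe. Individuals are drawn genotype-first (HWE at each
SNP's MAF), labelled Bernoulli(sigmoid(baseline + Σ b·dosage)), and
accepted into the case or control arm until both quotas are met exactly;
this rejection scheme preserves the generative model at the cost of
discarding draws from the majority arm. Missingness is injected only into
non-core SNPs (planted SNPs and a configurable core fraction stay
complete), so the complete-SNPs-only rule of the feature stage is
exercised without emptying the matrix.

Every stage derives its RNG stream from (seed, stage index), so each
output is a pure function of the configuration and byte-identical across
runs.

**Not emulated:** linkage disequilibrium, population stratification,
imputation uncertainty, sex chromosomes, Hi-C read-level noise, and
genuine expression data (eQTL associations arrive as a precomputed
table). Consequently the recovery experiments demonstrate that the
pipeline's inference machinery is correct and leak-free under its own
assumptions — not that the thresholds transfer untouched to real cohorts,
where LD, stratification and allele-orientation harmonisation all bite.

## Problem sizes

The test suite exercises the full pipeline at 2,000 samples × 200 SNPs ×
10 tissues (50-predictor ensembles fit in a few seconds), oracle
equivalence suites at 500–1,000 random instances each, and the Bayesian
recovery at 20 replicates of 30 values; these sizes give stable
assertions while keeping the whole suite under a minute of CPU.
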