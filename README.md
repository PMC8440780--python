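# spatialrisk

Tissue-resolved regulatory disease-risk modelling from spatially
constrained eQTLs.

Genome-wide association studies identify disease-associated SNPs, but most
of them are non-coding: their effect on risk is mediated by gene
regulation, often in tissues nobody suspected for the disease. This
package implements, end to end, a pipeline for ranking the contribution of
individual tissues' gene-regulatory effects to case/control disease risk:

1. **Spatial eQTL calling** (`spatialrisk.spatial`) — a SNP and a gene are
   paired when the Hi-C restriction fragment carrying the SNP physically
   contacts a fragment overlapping the gene. Contacts between a fragment
   and itself or its immediate neighbour are uninformative (ligation of
   contiguous restriction sites is indistinguishable from an undigested
   site), so same-chromosome contacts require a fragment-index separation
   ≥ 2, and a SNP inside its own target gene is testable only when the
   gene is covered by ≥ 3 fragments. Pairs are intersected with a
   tissue-specific eQTL table (SNP, gene, tissue, normalized effect size
   *NES*, p), corrected with Benjamini–Hochberg FDR (*q* < 0.05 pooled
   over tissues) and classified *cis* (same chromosome, |SNP − TSS| ≤ 1 Mb)
   or *trans*.
2. **Genotype QC** (`spatialrisk.qc`) — PLINK-style filters on a dosage
   matrix: method-of-moments inbreeding coefficient
   F = (O_hom − E_hom)/(N − E_hom) (remove F < −0.04 or F > 0.025),
   pairwise method-of-moments IBD (remove one of each pair with
   PI_HAT > 0.08), exact conditional Hardy–Weinberg test (remove
   p < 10⁻⁶), MAF < 1% and missingness > 5% filters.
3. **Weighted features** (`spatialrisk.features`) — each individual is
   encoded as dosage × NES per significant (SNP, gene, tissue) eQTL, plus
   bare dosages for candidate SNPs without eQTLs (pseudo-tissue "SNPs");
   only SNPs with complete dosage data enter the matrix.
4. **Risk prediction** (`spatialrisk.mlcore`) — Mann–Whitney U feature
   selection (BH FDR ≤ 0.2) feeding elastic-net logistic regression (SAGA;
   grid-searched hyperparameters, with C = 1, l1_ratio = 1 — the lasso
   limit — as defaults), evaluated by out-of-sample AUC over ten repeats
   of stratified 5-fold cross-validation: 50 predictors, each trained on
   80% and scored on the held-out 20%.
5. **Tissue decomposition** (`spatialrisk.decompose`) — a tissue's
   contribution to a predictor is the sum of |weights| over its features
   as a percent of the predictor's total |weight|; percents are averaged
   across the 50-predictor ensemble, and single-feature ablation
   experiments compare paired ensembles by Welch t-tests and Bayesian
   posteriors.
6. **Bayesian AUC estimation** (`spatialrisk.bayes`) — AUC sets are
   modelled as y ~ Normal(μ, σ) with μ ~ U(0, 1), σ ~ HalfNormal(0.01);
   the posterior is sampled by MCMC and summarised with means and 95%
   highest-posterior-density (HPD) intervals.

Because the cohorts such a study uses (WTCCC/UK Biobank genotypes, GTEx,
published Hi-C libraries) are access-restricted, the package ships a
first-class synthetic-data generator (`spatialrisk.synthdata`) producing
every input — fragment maps, gene annotations, contacts, eQTL tables and
case/control genotypes in HWE — with a *planted* tissue-specific risk
architecture whose ground truth is recorded for parameter-recovery
testing.

## Worked example

Run the whole pipeline on a synthetic cohort of 1,000 cases and 1,000
controls, 200 candidate SNPs and 10 tissues, with a total planted log-odds
mass of 3 on `tissue_0`:

```python
from spatialrisk.synthdata import SimConfig, simulate_all
from spatialrisk import spatial, qc, features, mlcore, decompose
from spatialrisk.bayes import AucSample, estimate_auc_posterior

cfg = SimConfig(n_cases=1000, n_controls=1000, n_snps=200, n_genes=60,
                n_tissues=10, planted_tissue="tissue_0",
                planted_effect_total=3.0, null_significant_fraction=0.3,
                contact_density=3.0, seed=17)
ref, contacts, eqtls, cohort = simulate_all(cfg)

pairs = spatial.find_spatial_pairs(ref.snps, ref.genes, ref.fragments, contacts)
records, report = spatial.call_spatial_eqtls(pairs, eqtls, ref.snps, ref.genes)
clean, _ = qc.apply_qc(cohort.genotypes)
fm = features.build_feature_matrix(clean, records, [s.id for s in ref.snps],
                                   cohort.labels)
ens = mlcore.repeated_kfold_ensemble(fm, seed=17)
dist = decompose.contribution_distribution(ens)
post = estimate_auc_posterior(AucSample(ens.aucs), prior_sd_scale=0.05, seed=17)
```

which prints (via the summary statements in the example script):

```
spatial pairs: 390, significant spatial eQTLs: 8
feature matrix: 2000 samples x 162 features
ensemble: 50 predictors, mean out-of-sample AUC = 0.743
  tissue_0    98.6% +- 2.40
  SNPs         1.4% +- 2.40
  tissue_1     0.0% +- 0.00
Bayesian AUC posterior: mu = 0.743, 95% HPD [0.737, 0.750]
```

The 50 out-of-sample AUCs average 0.743 — the planted architecture is
genuinely predictive — and the contribution decomposition ranks the
planted tissue first by a wide margin, with the bare-SNP pseudo-tissue
absorbing the remainder. The Bayesian summary gives the posterior of the
ensemble's mean AUC with its 95% HPD interval.

The same pipeline is scriptable from a shell via the `spatialrisk` CLI
(`simulate`, `spatial-eqtl`, `qc`, `build-matrix`, `train`,
`contributions`, `ablate`, `bayes-auc`); see `spatialrisk --help`.

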