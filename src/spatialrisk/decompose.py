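"""Tissue-specific contribution decomposition and feature-ablation analysis.

A fitted sparse logistic predictor assigns one weight per (SNP, gene,
tissue) feature; the contribution of a tissue is the sum of the absolute
weights over its features, expressed as a percent of the predictor's total
absolute weight (bare-SNP features are grouped under the pseudo-tissue
"SNPs" and included in the denominator).  Percents are computed per
predictor first and then averaged across the cross-validation ensemble, so
every predictor contributes on the same 0-100 scale regardless of its
overall weight mass.

The ablation experiment removes a single feature column, refits the whole
ensemble with identical fold assignments (paired design), and compares
per-tissue contribution percents and out-of-sample AUCs between baseline
and ablated ensembles by Welch t-tests and by Bayesian two-group posterior
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ttest_ind

from . import bayes
from .features import FeatureKey, FeatureMatrix, drop_feature
from .mlcore import EnsembleResult, Hyperparams, TrainedPredictor, repeated_kfold_ensemble

__all__ = [
    "ContributionTable",
    "ContributionDistribution",
    "AblationComparison",
    "tissue_contributions",
    "contribution_distribution",
    "ablation_experiment",
]


@dataclass
class ContributionTable:
    """Per-tissue absolute-weight sums and percents for one predictor."""

    abs_weight: dict[str, float]
    percent: dict[str, float]
    degenerate: bool = False  # all weights zero

    def top_tissue(self) -> str:
        return max(sorted(self.percent), key=lambda t: self.percent[t])


@dataclass
class ContributionDistribution:
    mean_percent: dict[str, float]
    sd_percent: dict[str, float]
    ranking: list[str]  # tissues by mean percent, descending; ties lexicographic
    samples: dict[str, np.ndarray]  # per-tissue percent across predictors


@dataclass
class AblationComparison:
    key: FeatureKey
    baseline: ContributionDistribution
    ablated: ContributionDistribution
    baseline_aucs: np.ndarray
    ablated_aucs: np.ndarray
    tissue_t_pvals: dict[str, float]
    auc_t_pval: float
    tissue_bayes: dict[str, bayes.GroupComparison] = field(default_factory=dict)
    auc_bayes: bayes.GroupComparison | None = None


def tissue_contributions(
    predictor: TrainedPredictor, tissues: list[str] | None = None
) -> ContributionTable:
    """Sum |weight| per tissue and normalise to percent of the total.

    ``tissues`` fixes the label set so tissues with no selected feature
    report exactly 0%; by default the labels present on the predictor's
    own features are used.
    """
    labels = set(tissues or [])
    labels.update(k.group_tissue for k in predictor.keys)
    sums = {t: 0.0 for t in sorted(labels)}
    for key, w in zip(predictor.keys, predictor.weights):
        sums[key.group_tissue] += abs(float(w))
    total = sum(sums.values())
    if total <= 0:
        return ContributionTable(sums, {t: 0.0 for t in sums}, degenerate=True)
    return ContributionTable(sums, {t: 100.0 * v / total for t, v in sums.items()})


def contribution_distribution(
    ensemble: EnsembleResult, tissues: list[str] | None = None
) -> ContributionDistribution:
    """Mean and SD of per-predictor contribution percents across the ensemble."""
    if not ensemble.predictors:
        raise ValueError("empty ensemble")
    labels = sorted(set(tissues or ensemble.tissues or []))
    if not labels:
        labels = sorted({k.group_tissue for p in ensemble.predictors for k in p.keys})
    per_pred = [tissue_contributions(p, labels) for p in ensemble.predictors]
    samples = {
        t: np.array([tbl.percent.get(t, 0.0) for tbl in per_pred]) for t in labels
    }
    mean = {t: float(v.mean()) for t, v in samples.items()}
    sd = {t: float(v.std(ddof=1)) if v.size > 1 else 0.0 for t, v in samples.items()}
    ranking = sorted(labels, key=lambda t: (-mean[t], t))
    return ContributionDistribution(mean, sd, ranking, samples)


def ablation_experiment(
    matrix: FeatureMatrix,
    key: FeatureKey,
    hp: Hyperparams | None = None,
    k: int = 5,
    repeats: int = 10,
    fdr: float = 0.2,
    seed: int | None = None,
    run_bayes: bool = True,
    bayes_draws: int = 1000,
) -> AblationComparison:
    """Paired ensemble comparison with one feature column removed.

    Both ensembles use the same seed, hence identical repeated-stratified-
    k-fold assignments; differences are attributable to the ablated column
    alone.  Per-tissue percents and AUCs are compared by two-sided Welch
    t-tests and, optionally, Bayesian two-group posterior comparison.
    """
    if key not in matrix.keys:
        raise KeyError(f"feature {key} not present in matrix")
    base_ens = repeated_kfold_ensemble(matrix, hp, k=k, repeats=repeats, fdr=fdr, seed=seed)
    ablated_matrix = drop_feature(matrix, key)
    abl_ens = repeated_kfold_ensemble(
        ablated_matrix, hp, k=k, repeats=repeats, fdr=fdr, seed=seed
    )
    tissues = matrix.tissues()
    base = contribution_distribution(base_ens, tissues)
    abl = contribution_distribution(abl_ens, tissues)

    t_pvals = {}
    for t in tissues:
        a, b = base.samples[t], abl.samples[t]
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            t_pvals[t] = 1.0
        else:
            t_pvals[t] = float(ttest_ind(a, b, equal_var=False).pvalue)
    auc_p = float(ttest_ind(base_ens.aucs, abl_ens.aucs, equal_var=False).pvalue)
    if np.isnan(auc_p):
        auc_p = 1.0

    comparison = AblationComparison(
        key=key,
        baseline=base,
        ablated=abl,
        baseline_aucs=base_ens.aucs,
        ablated_aucs=abl_ens.aucs,
        tissue_t_pvals=t_pvals,
        auc_t_pval=auc_p,
    )
    if run_bayes:
        rng = np.random.default_rng(seed)
        for t in tissues:
            comparison.tissue_bayes[t] = bayes.compare_groups(
                bayes.AucSample(base.samples[t], f"base:{t}"),
                bayes.AucSample(abl.samples[t], f"ablated:{t}"),
                prior_sd_scale=0.05,
                draws=bayes_draws,
                seed=int(rng.integers(2**31 - 1)),
            )
        comparison.auc_bayes = bayes.compare_groups(
            bayes.AucSample(base_ens.aucs, "base:auc"),
            bayes.AucSample(abl_ens.aucs, "ablated:auc"),
            draws=bayes_draws,
            seed=int(rng.integers(2**31 - 1)),
        )
    return comparison
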