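"""Regularised logistic disease-risk predictors over weighted eQTL features.

The modelling recipe: (1) univariate feature relevance by two-sided
Mann–Whitney U tests (case vs control feature values) with BH FDR control
at q <= 0.2; (2) elastic-net logistic regression (SAGA solver) on the
relevant subset, hyperparameters chosen by grid search with stratified
10-fold CV; (3) an ensemble of repeats x k predictors from repeated
stratified k-fold cross-validation (default 10 x 5 = 50), each trained on
80% of the cohort with feature selection re-run inside the training fold
(no leakage into the held-out 20%) and scored by out-of-sample AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

from .features import FeatureKey, FeatureMatrix
from .spatial import bh_adjust

__all__ = [
    "Hyperparams",
    "TrainedPredictor",
    "EnsembleResult",
    "DEFAULT_GRID",
    "select_features_mwu",
    "fit_logistic_elasticnet",
    "grid_search",
    "evaluate_auc",
    "split_train_validate",
    "repeated_kfold_ensemble",
]

#: group size at or below which the exact MWU null distribution is used
EXACT_MWU_MAX_N = 20


@dataclass(frozen=True)
class Hyperparams:
    """Elastic-net logistic hyperparameters (C = 1, l1_ratio = 1 is the
    lasso limit found optimal on the weighted genotype matrix)."""

    C: float = 1.0
    l1_ratio: float = 1.0
    max_iter: int = 500

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 0 <= self.l1_ratio <= 1:
            raise ValueError("l1_ratio must lie in [0, 1]")
        if self.max_iter <= 0:
            raise ValueError("max_iter must be positive")


DEFAULT_GRID: tuple[Hyperparams, ...] = tuple(
    Hyperparams(C=c, l1_ratio=r)
    for c in (0.01, 0.1, 1.0, 10.0)
    for r in (0.2, 0.5, 0.8, 1.0)
)


@dataclass
class TrainedPredictor:
    keys: list[FeatureKey]  # selected features, in matrix order
    weights: np.ndarray  # one weight per selected feature
    intercept: float
    hyperparams: Hyperparams
    training_auc: float
    converged: bool = True

    def decision_scores(self, matrix: FeatureMatrix) -> np.ndarray:
        if not self.keys:
            return np.zeros(len(matrix.sample_ids))
        sub = matrix.restrict(self.keys)
        return sub.values @ self.weights + self.intercept

    def weight_of(self, key: FeatureKey) -> float:
        try:
            return float(self.weights[self.keys.index(key)])
        except ValueError:
            return 0.0


@dataclass
class EnsembleResult:
    predictors: list[TrainedPredictor]
    aucs: np.ndarray  # out-of-sample AUC per predictor
    assignments: list[tuple[int, int, np.ndarray]]  # (repeat, fold, test indices)
    seed: int | None
    k: int
    repeats: int
    tissues: list[str] = field(default_factory=list)

    @property
    def n_predictors(self) -> int:
        return len(self.predictors)


def select_features_mwu(matrix: FeatureMatrix, fdr: float = 0.2) -> list[FeatureKey]:
    """Columns whose case/control value distributions differ at BH q <= fdr.

    Per column a two-sided Mann–Whitney U test compares case and control
    values: exact null enumeration when both groups have <= 20 samples,
    otherwise the tie-corrected normal approximation with continuity
    correction.  Constant columns get p = 1 and are never selected.
    """
    y = matrix.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present for feature selection")
    cases = matrix.values[y == 1]
    controls = matrix.values[y == 0]
    method = "exact" if max(len(cases), len(controls)) <= EXACT_MWU_MAX_N else "asymptotic"
    pvals = np.ones(matrix.n_features)
    for j in range(matrix.n_features):
        a, b = cases[:, j], controls[:, j]
        pooled = matrix.values[:, j]
        if np.all(pooled == pooled[0]):
            continue  # constant column, p stays 1
        # exact enumeration assumes no ties; fall back to the tie-corrected
        # normal approximation whenever the column has repeated values
        m = method if method == "asymptotic" or len(np.unique(pooled)) == len(pooled) else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=m)
        pvals[j] = res.pvalue
    qvals = bh_adjust(pvals)
    return [k for k, q in zip(matrix.keys, qvals) if q <= fdr]


def fit_logistic_elasticnet(
    matrix: FeatureMatrix, hp: Hyperparams | None = None
) -> TrainedPredictor:
    """Fit elastic-net logistic regression (SAGA) on the given features.

    Minimises the mean negative log-likelihood plus
    (1/(C n)) [l1_ratio ||w||_1 + (1 - l1_ratio)/2 ||w||_2^2] with an
    unpenalised intercept; deterministic (fixed solver seed, tol 1e-6).
    Non-convergence is recorded on the predictor, not raised.
    """
    hp = hp or Hyperparams()
    y = matrix.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit")
    if matrix.n_features == 0:
        # fully degenerate: intercept-only predictor at the empirical log-odds
        frac = y.mean()
        intercept = float(np.log(frac / (1 - frac))) if 0 < frac < 1 else 0.0
        return TrainedPredictor([], np.zeros(0), intercept, hp, 0.5)
    model = LogisticRegression(
        solver="saga",
        C=hp.C,
        l1_ratio=hp.l1_ratio,
        max_iter=hp.max_iter,
        tol=1e-6,
        random_state=1,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(matrix.values, y)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    weights = model.coef_.ravel().astype(float)
    intercept = float(model.intercept_[0])
    if np.all(weights == 0.0):
        # fully shrunk model: SAGA stalls on the intercept once every weight
        # is zero, but the optimal unpenalised intercept is then exactly the
        # empirical log-odds
        frac = y.mean()
        if 0 < frac < 1:
            intercept = float(np.log(frac / (1 - frac)))
    scores = matrix.values @ weights + intercept
    return TrainedPredictor(
        keys=list(matrix.keys),
        weights=weights,
        intercept=intercept,
        hyperparams=hp,
        training_auc=evaluate_auc(scores, y),
        converged=converged,
    )


def evaluate_auc(scores, labels) -> float:
    """Area under the ROC curve; ties between a case and a control count 1/2."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def split_train_validate(
    matrix: FeatureMatrix, fraction: float = 0.8, seed: int | None = None
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Random stratified split into train (fraction) and held-out sets."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(matrix.labels):
        idx = np.flatnonzero(matrix.labels == cls)
        perm = rng.permutation(idx)
        n_train = int(round(fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else n_train
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx, test_idx = sorted(train_idx), sorted(test_idx)

    def take(idx):
        return FeatureMatrix(
            [matrix.sample_ids[i] for i in idx],
            list(matrix.keys),
            matrix.values[idx],
            matrix.labels[idx],
        )

    return take(train_idx), take(test_idx)


def grid_search(
    matrix: FeatureMatrix,
    grid: tuple[Hyperparams, ...] = DEFAULT_GRID,
    k: int = 10,
    seed: int | None = None,
) -> Hyperparams:
    """Hyperparameters maximising mean validation AUC over stratified k-fold CV.

    Ties prefer the sparser model: larger l1_ratio first, then smaller C.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    y = matrix.labels
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(splitter.split(matrix.values, y))
    for _, test in folds:
        if len(np.unique(y[test])) < 2:
            raise ValueError("a CV fold lacks one of the classes")
    results = []
    for hp in grid:
        aucs = []
        for train, test in folds:
            sub = FeatureMatrix(
                [matrix.sample_ids[i] for i in train], list(matrix.keys),
                matrix.values[train], y[train],
            )
            pred = fit_logistic_elasticnet(sub, hp)
            scores = matrix.values[test] @ pred.weights + pred.intercept
            aucs.append(evaluate_auc(scores, y[test]))
        results.append((np.mean(aucs), hp.l1_ratio, -hp.C, hp))
    results.sort(key=lambda t: (t[0], t[1], t[2]))
    return results[-1][3]


def repeated_kfold_ensemble(
    matrix: FeatureMatrix,
    hp: Hyperparams | None = None,
    k: int = 5,
    repeats: int = 10,
    fdr: float = 0.2,
    seed: int | None = None,
    freeze_selection: bool = False,
) -> EnsembleResult:
    """Repeats x k cross-validated predictors with out-of-sample AUCs.

    Each of the repeats x k folds trains on (k-1)/k of the cohort and is
    evaluated on the remaining held-out fold.  Feature selection runs on
    the training portion of each fold; ``freeze_selection`` instead selects
    once on the full matrix (leaky variant, for sensitivity analysis).
    """
    hp = hp or Hyperparams()
    y = matrix.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(f"need at least k={k} samples per class")
    frozen = select_features_mwu(matrix, fdr) if freeze_selection else None

    splitter = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    predictors: list[TrainedPredictor] = []
    aucs: list[float] = []
    assignments: list[tuple[int, int, np.ndarray]] = []
    for fold_id, (train, test) in enumerate(splitter.split(matrix.values, y)):
        train_matrix = FeatureMatrix(
            [matrix.sample_ids[i] for i in train], list(matrix.keys),
            matrix.values[train], y[train],
        )
        selected = frozen if frozen is not None else select_features_mwu(train_matrix, fdr)
        pred = fit_logistic_elasticnet(train_matrix.restrict(selected), hp)
        if pred.keys:
            sel_idx = [matrix.keys.index(key) for key in pred.keys]
            scores = matrix.values[np.ix_(test, sel_idx)] @ pred.weights + pred.intercept
        else:
            scores = np.zeros(len(test))
        aucs.append(evaluate_auc(scores, y[test]) if len(np.unique(y[test])) == 2 else 0.5)
        predictors.append(pred)
        assignments.append((fold_id // k, fold_id % k, np.asarray(test)))
    return EnsembleResult(
        predictors=predictors,
        aucs=np.asarray(aucs),
        assignments=assignments,
        seed=seed,
        k=k,
        repeats=repeats,
        tissues=matrix.tissues(),
    )
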