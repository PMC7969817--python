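"""The four feature-ranking classifiers and their shared evaluation harness.

Disease-vs-control (and disease-vs-disease) models are fit with four
algorithms that all expose a per-feature importance: random forest (Gini
importance), gradient boosting (XGBoost total gain), L2-regularised
logistic regression ("ridge", |coefficient| after per-feature
standardisation) and an RBF-kernel SVM wrapped in recursive feature
elimination with a step of 2. Hyperparameters are tuned by grid search
under sevenfold, 3-times-repeated stratified cross-validation scored by
AUC; performance is reported on a held-out stratified 10% test split as
AUC and macro F1.

Before any fit, near-zero-variance features are removed with the caret
rule: drop a feature when its most-frequent/second-most-frequent value
ratio exceeds 19 AND its fraction of distinct values is below 10% (constant
features always go).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import (
    GridSearchCV,
    RepeatedStratifiedKFold,
    StratifiedKFold,
    cross_val_score,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import (
    ConfigurationError,
    EmptyFeatureError,
    EvaluationError,
    InsufficientDataError,
)

logger = logging.getLogger(__name__)

ALGORITHMS = ("random_forest", "gradient_boosting", "ridge_logistic", "svm_rfe")


@dataclass
class ModelSpec:
    """One algorithm plus its tuning protocol.

    ``hyperparameter_grid=None`` selects the built-in default grid for the
    algorithm (the published tuning grids are not available; defaults are
    explicit, overridable stand-ins).
    """

    algorithm: str
    hyperparameter_grid: dict[str, list] | None = None
    cv_folds: int = 7
    cv_repeats: int = 3
    rfe_step: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.cv_folds < 2:
            raise ConfigurationError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.rfe_step < 1:
            raise ConfigurationError(f"rfe_step must be >= 1, got {self.rfe_step}")


@dataclass
class FitResult:
    """A trained classifier with its tuning outcome and feature importances.

    ``importance`` maps every feature in ``features_used`` to a non-negative
    score (for SVM-RFE: p - rank + 1, i.e. reverse elimination order).
    ``auc``/``macro_f1``/``test_sample_ids`` are filled by :func:`evaluate`.
    """

    algorithm: str
    tuned_parameters: dict
    importance: pd.Series
    features_used: list[str]
    train_sample_ids: list[str]
    model: object
    selected_features: list[str] | None = None  # SVM-RFE best subset
    auc: float | None = None
    macro_f1: float | None = None
    test_sample_ids: list[str] = field(default_factory=list)

    def predict_scores(self, x: pd.DataFrame) -> np.ndarray:
        """Probability-like score of the positive class for each sample."""
        cols = self.selected_features if self.selected_features is not None else self.features_used
        return np.asarray(self.model.predict_proba(x[cols].to_numpy())[:, 1])


def remove_near_zero_variance(
    matrix: pd.DataFrame,
    freq_ratio_cutoff: float = 19.0,
    unique_fraction_cutoff: float = 0.10,
) -> tuple[pd.DataFrame, list[str]]:
    """Drop near-zero-variance features (caret's ``nearZeroVar`` rule)."""
    if matrix.shape[0] < 2:
        raise InsufficientDataError("NZV filter needs at least 2 samples")
    n = matrix.shape[0]
    removed: list[str] = []
    for col in matrix.columns:
        counts = matrix[col].value_counts().to_numpy()
        if len(counts) == 1:
            removed.append(col)  # constant feature
            continue
        freq_ratio = counts[0] / counts[1]
        unique_fraction = len(counts) / n
        if freq_ratio > freq_ratio_cutoff and unique_fraction < unique_fraction_cutoff:
            removed.append(col)
    kept = matrix.drop(columns=removed)
    if kept.shape[1] == 0:
        raise EmptyFeatureError("near-zero-variance filter removed every feature")
    if removed:
        logger.info("NZV filter removed %d of %d features", len(removed), matrix.shape[1])
    return kept, removed


def split_train_test(
    profile_data: pd.DataFrame,
    labels: pd.Series,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Stratified train/test split (default 90%/10%), deterministic per seed.

    Per-class test sizes are rounded to the nearest integer with at least
    one test sample per class.
    """
    if not 0 < test_fraction < 1:
        raise ConfigurationError(f"test_fraction must be in (0,1), got {test_fraction}")
    labels = labels.loc[profile_data.index]
    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for cls in sorted(labels.unique()):
        ids = list(labels.index[labels == cls])
        n_test = max(1, int(round(len(ids) * test_fraction)))
        if n_test >= len(ids):
            raise InsufficientDataError(
                f"class {cls!r} has only {len(ids)} samples; cannot hold out {n_test}"
            )
        test_ids.extend(rng.choice(ids, size=n_test, replace=False))
    test_set = set(test_ids)
    train_idx = [sid for sid in profile_data.index if sid not in test_set]
    test_idx = [sid for sid in profile_data.index if sid in test_set]
    return (
        profile_data.loc[train_idx],
        labels.loc[train_idx],
        profile_data.loc[test_idx],
        labels.loc[test_idx],
    )


def encode_labels(labels: pd.Series, positive: str) -> np.ndarray:
    """0/1 encoding with ``positive`` as class 1."""
    uniq = set(labels.unique())
    if positive not in uniq or len(uniq) != 2:
        raise EvaluationError(f"need binary labels containing {positive!r}, got {sorted(uniq)}")
    return (labels == positive).astype(int).to_numpy()


def _median_heuristic_gamma(x: np.ndarray, rng: np.random.Generator) -> float:
    """RBF width via the median pairwise squared distance (subsampled)."""
    n = x.shape[0]
    idx = rng.choice(n, size=min(n, 200), replace=False)
    sub = x[idx]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(axis=2)
    med = np.median(d2[np.triu_indices(len(sub), k=1)])
    return 1.0 / med if med > 0 else 1.0


def default_grid(algorithm: str, x: np.ndarray, seed: int = 0) -> dict[str, list]:
    """Built-in tuning grids (explicit stand-ins, config-overridable)."""
    p = x.shape[1]
    if algorithm == "random_forest":
        return {"max_features": sorted({"sqrt", max(1, p // 4), max(1, p // 2)}, key=str)}
    if algorithm == "gradient_boosting":
        return {
            "learning_rate": [0.05, 0.3],
            "max_depth": [3, 6],
            "n_estimators": [100, 300],
        }
    if algorithm == "ridge_logistic":
        return {"logit__C": [float(c) for c in np.logspace(-3, 3, 10)]}
    if algorithm == "svm_rfe":
        g = _median_heuristic_gamma(x, np.random.default_rng(seed))
        return {"C": [0.25, 1.0, 4.0], "gamma": [g / 2, g, 2 * g]}
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


def _base_estimator(algorithm: str, seed: int):
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    if algorithm == "gradient_boosting":
        return XGBClassifier(
            tree_method="hist",
            eval_metric="logloss",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if algorithm == "ridge_logistic":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("logit", LogisticRegression(solver="lbfgs", max_iter=5000)),  # L2 by default
            ]
        )
    if algorithm == "svm_rfe":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


def _quiet_fit(estimator, x: np.ndarray, y: np.ndarray) -> None:
    """Fit while silencing sklearn's SVC(probability=True) deprecation chatter."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=FutureWarning, message=".*probability.*")
        estimator.fit(x, y)


def univariate_auc_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature |AUC - 0.5| filter importance (rank-based, ties at 1/2)."""
    n1 = int(y.sum())
    n0 = len(y) - n1
    scores = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j])
        auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        scores[j] = abs(auc - 0.5)
    return scores


def svm_rfe(
    train: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
) -> tuple[pd.Series, list[str], list[tuple[int, float]]]:
    """Recursive feature elimination around an RBF-SVM.

    Features are scored by the univariate |AUC - 0.5| filter (an RBF-SVM has
    no native per-feature coefficients); each round trains the SVM on the
    surviving set to record its 3-fold CV AUC, then eliminates the
    ``rfe_step`` lowest-scoring features. Returns (ranking, best_subset,
    path) where rank 1 is the last survivor, within-batch ties are ordered
    by that round's scores, and best_subset is the surviving set with the
    highest CV AUC along the path (ties -> the smaller set).
    """
    features = list(train.columns)
    p = len(features)
    if p < 4:
        raise InsufficientDataError(f"SVM-RFE needs >= 4 features, got {p}")
    x = train.to_numpy(dtype=float)
    scores = pd.Series(univariate_auc_scores(x, y), index=features)
    cv = StratifiedKFold(n_splits=3, shuffle=True, random_state=spec.seed)

    surviving = list(features)
    ranks: dict[str, int] = {}
    next_rank = p  # worst rank assigned first
    path: list[tuple[int, float]] = []
    subsets: dict[int, list[str]] = {}
    while True:
        est = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=spec.seed)
        auc = float(
            np.mean(cross_val_score(est, x[:, [features.index(f) for f in surviving]], y,
                                    scoring="roc_auc", cv=cv))
        )
        path.append((len(surviving), auc))
        subsets[len(surviving)] = list(surviving)
        if len(surviving) == 1:
            ranks[surviving[0]] = 1
            break
        k = min(spec.rfe_step, len(surviving) - 1)
        by_score = sorted(surviving, key=lambda f: (scores[f], f))
        victims = by_score[:k]
        for f in victims:  # ascending score: worst gets the largest rank
            ranks[f] = next_rank
            next_rank -= 1
        surviving = [f for f in surviving if f not in set(victims)]

    best_size = max(path, key=lambda t: (t[1], -t[0]))[0]
    ranking = pd.Series({f: ranks[f] for f in features}, index=features, dtype=float)
    return ranking, subsets[best_size], path


def fit_model(spec: ModelSpec, train: pd.DataFrame, y: np.ndarray) -> FitResult:
    """Grid-search, fit and extract importances for one algorithm.

    The grid is scored by mean cross-validated AUC over ``cv_folds`` x
    ``cv_repeats`` stratified folds and the winning point is refit on the
    full training set.
    """
    if set(np.unique(y)) - {0, 1}:
        raise EvaluationError("fit_model expects 0/1-encoded binary labels")
    x = train.to_numpy(dtype=float)
    features = list(train.columns)
    grid = spec.hyperparameter_grid or default_grid(spec.algorithm, x, spec.seed)

    selected: list[str] | None = None
    if spec.algorithm == "svm_rfe":
        ranking, best_subset, _ = svm_rfe(train, y, spec)
        selected = best_subset
        x_fit = train[best_subset].to_numpy(dtype=float)
    else:
        x_fit = x

    est = _base_estimator(spec.algorithm, spec.seed)
    n_combos = math.prod(len(v) for v in grid.values()) if grid else 1
    if n_combos > 1:
        cv = RepeatedStratifiedKFold(
            n_splits=spec.cv_folds, n_repeats=spec.cv_repeats, random_state=spec.seed
        )
        search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, n_jobs=1, refit=True)
        _quiet_fit(search, x_fit, y)
        model = search.best_estimator_
        tuned = dict(search.best_params_)
    else:
        tuned = {k: v[0] for k, v in grid.items()}
        model = est.set_params(**tuned)
        _quiet_fit(model, x_fit, y)

    if spec.algorithm == "random_forest":
        importance = pd.Series(model.feature_importances_, index=features)
    elif spec.algorithm == "gradient_boosting":
        gain = model.get_booster().get_score(importance_type="total_gain")
        importance = pd.Series(
            [gain.get(f"f{j}", 0.0) for j in range(len(features))], index=features
        )
    elif spec.algorithm == "ridge_logistic":
        importance = pd.Series(np.abs(model.named_steps["logit"].coef_[0]), index=features)
    else:  # svm_rfe: reverse elimination order as a non-negative score
        importance = pd.Series(len(features) + 1, index=features, dtype=float) - ranking
    logger.info("fit %s: tuned=%s", spec.algorithm, tuned)

    return FitResult(
        algorithm=spec.algorithm,
        tuned_parameters=tuned,
        importance=importance,
        features_used=features,
        train_sample_ids=list(train.index),
        model=model,
        selected_features=selected,
    )


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Probability-ranking AUC with ties counted 1/2 (Mann-Whitney form)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    n1 = int(y_true.sum())
    n0 = len(y_true) - n1
    if n1 == 0 or n0 == 0:
        raise EvaluationError("AUC undefined: one class absent")
    ranks = stats.rankdata(scores)
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def macro_f1_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Unweighted mean of the two per-class F1 scores; an unpredicted or
    absent class contributes F1 = 0."""
    f1s = []
    for cls in (0, 1):
        tp = int(((y_true == cls) & (y_pred == cls)).sum())
        fp = int(((y_true != cls) & (y_pred == cls)).sum())
        fn = int(((y_true == cls) & (y_pred != cls)).sum())
        denom = 2 * tp + fp + fn
        f1s.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(f1s))


def evaluate(fit: FitResult, test: pd.DataFrame, y_test: np.ndarray) -> tuple[float, float]:
    """Held-out AUC and macro F1 (class decision at score >= 0.5)."""
    if len(test) == 0:
        raise EvaluationError("empty test set")
    if len(np.unique(y_test)) < 2:
        raise EvaluationError("test set contains a single class")
    overlap = set(test.index) & set(fit.train_sample_ids)
    if overlap:
        raise EvaluationError(f"test samples seen in training: {sorted(overlap)[:3]}")
    scores = fit.predict_scores(test)
    fit.auc = auc_score(y_test, scores)
    fit.macro_f1 = macro_f1_score(y_test, (scores >= 0.5).astype(int))
    fit.test_sample_ids = list(test.index)
    return fit.auc, fit.macro_f1


def run_model_suite(
    data: pd.DataFrame,
    labels: pd.Series,
    positive: str,
    algorithms: Sequence[str] = ALGORITHMS,
    test_fraction: float = 0.10,
    seed: int = 0,
    cv_folds: int = 7,
    cv_repeats: int = 3,
    rfe_step: int = 2,
    grids: dict[str, dict] | None = None,
) -> tuple[dict[str, FitResult], list[str]]:
    """NZV -> split -> fit -> evaluate for each requested algorithm.

    All algorithms share the same NZV-filtered feature set and the same
    train/test split, so their importances are comparable taxon-by-taxon.
    Returns the per-algorithm fits and the list of NZV-removed features.
    """
    filtered, removed = remove_near_zero_variance(data)
    x_train, y_train, x_test, y_test = split_train_test(filtered, labels, test_fraction, seed)
    y_tr = encode_labels(y_train, positive)
    y_te = encode_labels(y_test, positive)
    fits: dict[str, FitResult] = {}
    for algo in algorithms:
        spec = ModelSpec(
            algorithm=algo,
            hyperparameter_grid=(grids or {}).get(algo),
            cv_folds=cv_folds,
            cv_repeats=cv_repeats,
            rfe_step=rfe_step,
            seed=seed,
        )
        fit = fit_model(spec, x_train, y_tr)
        evaluate(fit, x_test, y_te)
        fits[algo] = fit
    return fits, removed
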