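"""Confound controls: the mock study-prediction model and the random-label null.

Two sanity checks guard the biological conclusions:

* a "mock" random-forest model predicts *study of origin* (ignoring disease
  status) and taxa whose Gini importance falls in the top percentile
  (default: top 1%) are flagged as batch-driven rather than disease-driven;
  flagged taxa stay visible downstream but are asterisked and excluded from
  biological interpretation;
* the random-label null retrains the disease classifier after uniformly
  permuting the class labels; a sound pipeline yields held-out AUCs of ~0.5,
  so any real signal cannot be an artifact of the modeling machinery.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import model_suite
from .errors import ConsistencyError
from .model_suite import ModelSpec

logger = logging.getLogger(__name__)


@dataclass
class ConfoundFlags:
    """Per-taxon study-model importances with the percentile cutoff applied."""

    table: pd.DataFrame  # columns: max_study_importance, flagged
    cutoff_value: float
    cutoff_percentile: float

    @property
    def flagged_taxa(self) -> set[str]:
        return set(self.table.index[self.table["flagged"]])

    @classmethod
    def empty(cls, taxa: list[str], percentile: float) -> "ConfoundFlags":
        table = pd.DataFrame(
            {"max_study_importance": 0.0, "flagged": False}, index=pd.Index(taxa, name="taxon")
        )
        return cls(table, cutoff_value=float("nan"), cutoff_percentile=percentile)


def fit_study_model(
    data: pd.DataFrame,
    metadata: pd.DataFrame,
    seed: int = 0,
    n_estimators: int = 500,
) -> pd.Series | None:
    """Random forest predicting study_id on all samples, disease ignored.

    Returns per-taxon Gini importances, or None when only one study is
    present (confound analysis not applicable).
    """
    studies = metadata.loc[data.index, "study_id"]
    if studies.nunique() < 2:
        logger.warning("confound analysis skipped: single study")
        return None
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(data.to_numpy(dtype=float), studies.to_numpy())
    return pd.Series(model.feature_importances_, index=data.columns)


def flag_confounded(importances: pd.Series, percentile: float = 99.0) -> ConfoundFlags:
    """Flag taxa strictly above the given percentile of importance values.

    The percentile (linear interpolation) is computed over all importance
    values; the realised absolute cutoff is reported for transparency (the
    percentile parameterisation replaces any dataset-specific absolute
    threshold).
    """
    if importances.empty:
        raise ConsistencyError("no importances to flag")
    cutoff = float(np.percentile(importances.to_numpy(dtype=float), percentile))
    table = pd.DataFrame(
        {
            "max_study_importance": importances,
            "flagged": importances > cutoff,
        }
    )
    table.index.name = "taxon"
    logger.info(
        "confound flags: percentile %.4g -> cutoff %.6g, %d/%d taxa flagged",
        percentile, cutoff, int(table["flagged"].sum()), len(table),
    )
    return ConfoundFlags(table, cutoff_value=cutoff, cutoff_percentile=percentile)


def random_label_null(
    data: pd.DataFrame,
    labels: pd.Series,
    positive: str,
    spec: ModelSpec,
    n_repeats: int = 20,
    seed: int = 0,
    test_fraction: float = 0.10,
) -> tuple[list[float], float]:
    """Held-out AUCs of models retrained on uniformly permuted labels.

    Each repeat permutes the class labels, reruns NZV -> stratified split ->
    fit -> evaluate, and records the held-out AUC. Returns (aucs, mean).
    """
    labels = labels.loc[data.index]
    aucs: list[float] = []
    for r in range(n_repeats):
        rep_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(r,)).generate_state(1)[0] % 2**31)
        rng = np.random.default_rng(rep_seed)
        permuted = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        fits, _ = model_suite.run_model_suite(
            data,
            permuted,
            positive,
            algorithms=[spec.algorithm],
            test_fraction=test_fraction,
            seed=rep_seed,
            cv_folds=spec.cv_folds,
            cv_repeats=spec.cv_repeats,
            rfe_step=spec.rfe_step,
            grids={spec.algorithm: spec.hyperparameter_grid} if spec.hyperparameter_grid else None,
        )
        aucs.append(float(fits[spec.algorithm].auc))
    mean = float(np.mean(aucs))
    logger.info("random-label null: mean AUC %.3f over %d repeats", mean, n_repeats)
    return aucs, mean
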