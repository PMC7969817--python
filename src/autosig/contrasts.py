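"""Pairwise disease-vs-disease models and cross-model overlap sets.

Comparing each disease against the others (not just against healthy
controls) separates taxa that mark a *specific* disease from taxa shared
across autoimmunity: a disease-specific taxon should surface in the
disease-vs-healthy model AND in that disease's contrasts against the other
diseases. A taxon is called "consistently identified" for a disease when
it appears in the top-k of at least ``min_models`` of its three contrast
models (default 2 of 3); the full three-way intersection is reported
alongside.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import abundance_io, consensus, model_suite
from .abundance_io import HEALTHY_LABEL, TaxonomicProfile
from .errors import ConfigurationError

#: Diseases whose models are restricted to adult samples.
ADULT_ONLY_DISEASES = frozenset({"MS", "RA"})


def pairwise_model(
    profile: TaxonomicProfile,
    metadata: pd.DataFrame,
    disease_a: str,
    disease_b: str,
    algorithms: Sequence[str] = ("random_forest",),
    seed: int = 0,
    top_k: int = 30,
    adults_only: bool | None = None,
    test_fraction: float = 0.10,
    cv_folds: int = 7,
    cv_repeats: int = 3,
    rfe_step: int = 2,
    grids: dict[str, dict] | None = None,
) -> tuple[dict[str, model_suite.FitResult], pd.DataFrame]:
    """One disease-vs-disease (or disease-vs-healthy) model plus consensus.

    The larger class is randomly subsampled to balance the classes, then the
    model suite and consensus ranking run exactly as for the primary
    disease-vs-healthy models. ``adults_only=None`` applies the adult-only
    restriction automatically when either side is an adult-only disease.
    ``disease_a`` is the positive class.
    """
    if disease_a == disease_b:
        raise ConfigurationError(f"cannot contrast {disease_a!r} against itself")
    if adults_only is None:
        adults_only = bool({disease_a, disease_b} & ADULT_ONLY_DISEASES)
    sub, meta = abundance_io.filter_cohort(
        profile, metadata, {disease_a, disease_b}, adults_only=adults_only
    )
    sub, meta = abundance_io.balance_classes(sub, meta, seed=seed)
    labels = meta["disease"]
    fits, _ = model_suite.run_model_suite(
        sub.data,
        labels,
        positive=disease_a,
        algorithms=algorithms,
        test_fraction=test_fraction,
        seed=seed,
        cv_folds=cv_folds,
        cv_repeats=cv_repeats,
        rfe_step=rfe_step,
        grids=grids,
    )
    table = consensus.build_consensus(
        {a: f.importance for a, f in fits.items()},
        sub.data,
        labels,
        positive=disease_a,
        k=top_k,
    )
    return fits, table


def overlap(
    top_sets: Mapping[str, set[str]],
    min_models: int = 2,
    flagged: set[str] | None = None,
    directions: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Count, per taxon, how many contrast top-k sets contain it.

    ``top_sets`` maps a contrast name (e.g. ``"IBD_vs_healthy"``) to its
    top-k taxon set for one disease. Output rows carry ``n_models_present``,
    the ``consistent`` call (present in >= ``min_models`` contrasts), the
    study-confound flag (flagged taxa are kept but marked) and, when
    ``directions`` (taxon -> log2FC vs healthy) is given, the sign of the
    change. Symmetric in contrast order.
    """
    if min_models < 1:
        raise ConfigurationError(f"min_models must be >= 1, got {min_models}")
    counts: dict[str, int] = {}
    membership: dict[str, list[str]] = {}
    for contrast in sorted(top_sets):
        for taxon in top_sets[contrast]:
            counts[taxon] = counts.get(taxon, 0) + 1
            membership.setdefault(taxon, []).append(contrast)
    rows = []
    for taxon in sorted(counts):
        rows.append(
            {
                "taxon": taxon,
                "n_models_present": counts[taxon],
                "contrasts": ",".join(sorted(membership[taxon])),
                "consistent": counts[taxon] >= min_models,
                "in_all": counts[taxon] == len(top_sets),
                "study_flagged": taxon in (flagged or set()),
                "direction": (
                    int(pd.Series([directions[taxon]]).iloc[0] > 0) * 2 - 1
                    if directions and taxon in directions
                    else 0
                ),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "taxon", "n_models_present", "contrasts", "consistent",
            "in_all", "study_flagged", "direction",
        ],
    ).set_index("taxon")
    return out


def disease_contrast_names(disease: str, others: Sequence[str]) -> list[str]:
    """The three contrast names considered for one disease."""
    return [f"{disease}_vs_{HEALTHY_LABEL}"] + [f"{disease}_vs_{o}" for o in sorted(others)]
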