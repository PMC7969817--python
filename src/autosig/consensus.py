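"""Consensus feature ranking across the four classifiers.

Each algorithm measures importance on its own scale, so importances are
first converted to ranks (1 = most important, ties averaged) within each
model, then aggregated by the arithmetic mean rank across models. The
``k`` taxa with the smallest mean rank (default 30) form the consensus
signature, annotated with the disease-vs-healthy log2 fold change of mean
relative abundance and, downstream, with the study-confound flag.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, EvaluationError

__all__ = ["importance_to_ranks", "aggregate", "log_fold_change", "build_consensus"]


def importance_to_ranks(importance: pd.Series) -> pd.Series:
    """Descending-importance ranks; tied importances share the average of
    the rank positions they cover (so ranks always sum to p(p+1)/2)."""
    if (importance < 0).any():
        raise ConsistencyError("importances must be non-negative")
    return pd.Series(
        stats.rankdata(-importance.to_numpy(), method="average"),
        index=importance.index,
    )


def aggregate(rank_maps: dict[str, pd.Series], k: int = 30) -> pd.DataFrame:
    """Mean-rank aggregation over models; rows sorted ascending by mean rank.

    All rank maps must cover the same taxon set. The ``k`` smallest mean
    ranks are flagged ``selected``; ties at the boundary break by
    lexicographic taxon name (the sort is by (mean_rank, taxon)).
    """
    if not rank_maps:
        raise ConsistencyError("no rank maps to aggregate")
    names = sorted(rank_maps)
    base = set(rank_maps[names[0]].index)
    for name in names[1:]:
        if set(rank_maps[name].index) != base:
            raise ConsistencyError(f"rank map {name!r} covers a different taxon set")
    table = pd.DataFrame({f"rank_{name}": rank_maps[name] for name in names})
    table["mean_rank"] = table.mean(axis=1)
    table = (
        table.assign(_taxon=table.index.astype(str))
        .sort_values(["mean_rank", "_taxon"], kind="mergesort")
        .drop(columns="_taxon")
    )
    table["selected"] = False
    table.iloc[: min(k, len(table)), table.columns.get_loc("selected")] = True
    table.index.name = "taxon"
    return table


def log_fold_change(
    data: pd.DataFrame,
    labels: pd.Series,
    positive: str,
    pseudocount: float | None = None,
) -> pd.Series:
    """log2((mean_disease + eps) / (mean_healthy + eps)) per taxon.

    ``eps`` defaults to half the smallest nonzero value in the matrix; a
    taxon absent from both classes therefore gets exactly 0 (eps/eps).
    """
    labels = labels.loc[data.index]
    classes = set(labels.unique())
    if positive not in classes or len(classes) != 2:
        raise EvaluationError(f"need two classes containing {positive!r}, got {sorted(classes)}")
    if pseudocount is None:
        values = data.to_numpy()
        nonzero = values[values > 0]
        pseudocount = float(nonzero.min()) / 2 if nonzero.size else 1e-9
    mean_pos = data.loc[labels == positive].mean(axis=0)
    mean_neg = data.loc[labels != positive].mean(axis=0)
    return np.log2((mean_pos + pseudocount) / (mean_neg + pseudocount))


def build_consensus(
    importances: dict[str, pd.Series],
    data: pd.DataFrame,
    labels: pd.Series,
    positive: str,
    k: int = 30,
    flagged: set[str] | None = None,
) -> pd.DataFrame:
    """Full consensus table: per-model ranks, mean rank, top-k flag, log2
    fold change and the study-confound flag."""
    ranks = {name: importance_to_ranks(imp) for name, imp in importances.items()}
    table = aggregate(ranks, k=k)
    lfc = log_fold_change(data[list(table.index)], labels, positive)
    table["log2_fold_change"] = lfc.loc[table.index]
    table["study_flagged"] = [t in (flagged or set()) for t in table.index]
    return table
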