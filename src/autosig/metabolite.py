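"""Taxa-metabolite association: candidates, prevalence filter, Spearman+BH.

The downstream question is what the disease-predictive taxa might be doing
metabolically. Candidate taxa are genus-level features that recur across
disease contrasts, minus any flagged as study-confounded; taxa detected in
fewer than 10% of the correlation cohort's samples are dropped; every
remaining (taxon, metabolite) pair is tested by Spearman correlation with
a single Benjamini-Hochberg adjustment across the whole pair family and
called significant at adjusted p < 0.05.
"""
from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance_io import RANK_NAMES, TaxonLineage
from .controls import ConfoundFlags
from .errors import DimensionError

logger = logging.getLogger(__name__)

__all__ = ["select_candidates", "prevalence_filter", "spearman_bh"]


def _is_at_level(taxon: str, letter: str) -> bool:
    lineage = TaxonLineage.parse(taxon)
    return lineage.depth_letter == letter and bool(lineage.ranks[-1][1])


def select_candidates(
    overlap_table: pd.DataFrame,
    available_taxa: set[str],
    flags: ConfoundFlags | None = None,
    min_models: int = 2,
    level: str = "genus",
) -> list[str]:
    """Genus-level taxa recurring in >= min_models contrasts, present in the
    correlation cohort, minus study-flagged taxa."""
    letter = RANK_NAMES.get(level, level)
    flagged = flags.flagged_taxa if flags is not None else set()
    out = []
    for taxon, row in overlap_table.iterrows():
        if row["n_models_present"] < min_models:
            continue
        if not _is_at_level(str(taxon), letter):
            continue
        if taxon not in available_taxa:
            continue
        if taxon in flagged:
            logger.info("candidate %s excluded: study-based predictive power", taxon)
            continue
        out.append(str(taxon))
    if not out:
        logger.warning("no taxon-metabolite candidates survived selection")
    return sorted(out)


def prevalence_filter(taxa_matrix: pd.DataFrame, min_fraction: float = 0.10) -> list[str]:
    """Keep taxa with nonzero abundance in at least ``min_fraction`` of
    samples (>=, not >); zeros are treated as non-detection."""
    n = taxa_matrix.shape[0]
    frac = (taxa_matrix > 0).sum(axis=0) / n
    kept = sorted(frac.index[frac >= min_fraction])
    dropped = sorted(set(taxa_matrix.columns) - set(kept))
    if dropped:
        logger.info("prevalence filter (<%.0f%%) dropped %s", 100 * min_fraction, dropped)
    return kept


@lru_cache(maxsize=8)
def _exact_null_counts(n: int) -> np.ndarray:
    """Null distribution of sum(d^2) of ranks over all n! permutations
    (chunked enumeration; used only for n <= 10)."""
    base = np.arange(1, n + 1)
    sums = []
    perms = itertools.permutations(base)
    while True:
        chunk = np.array(list(itertools.islice(perms, 200_000)))
        if chunk.size == 0:
            break
        sums.append(((chunk - base) ** 2).sum(axis=1))
    return np.concatenate(sums)


def _spearman_pair(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> tuple[float, float]:
    """Spearman rho (average-tied ranks) with a two-sided p-value: exact
    permutation null for n <= exact_max_n and tie-free data, otherwise the
    t-approximation."""
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= exact_max_n and not ties:
        rx = stats.rankdata(x)
        order = np.argsort(rx)
        ry = stats.rankdata(y)[order]  # y-ranks against sorted x-ranks
        d2_obs = ((np.arange(1, n + 1) - ry) ** 2).sum()
        null = _exact_null_counts(n)
        center = n * (n**2 - 1) / 6  # sum d^2 at rho = 0
        p = float((np.abs(null - center) >= abs(d2_obs - center) - 1e-9).mean())
        return rho, min(1.0, p)
    if abs(rho) >= 1.0:
        return rho, 0.0 if n > 2 else 1.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def spearman_bh(
    taxa_matrix: pd.DataFrame,
    metabolite_matrix: pd.DataFrame,
    alpha: float = 0.05,
    per_taxon_adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise taxon-metabolite Spearman correlations, BH-adjusted.

    BH runs once across the full pair family by default
    (``per_taxon_adjust=True`` adjusts within each taxon instead).
    Zero-variance vectors make rho undefined; those pairs are dropped with
    a warning. Rows are sorted by descending |rho| within taxon.
    """
    if list(taxa_matrix.index) != list(metabolite_matrix.index):
        if set(taxa_matrix.index) == set(metabolite_matrix.index):
            metabolite_matrix = metabolite_matrix.loc[taxa_matrix.index]
        else:
            raise DimensionError("taxa and metabolite matrices cover different samples")
    if taxa_matrix.shape[0] < 3:
        raise DimensionError("need >= 3 samples for correlation")

    rows = []
    for taxon in taxa_matrix.columns:
        x = taxa_matrix[taxon].to_numpy(dtype=float)
        if np.all(x == x[0]):
            logger.warning("taxon %s has zero variance; its pairs are dropped", taxon)
            continue
        for metab in metabolite_matrix.columns:
            y = metabolite_matrix[metab].to_numpy(dtype=float)
            if np.all(y == y[0]):
                logger.warning("metabolite %s has zero variance; pair dropped", metab)
                continue
            rho, p = _spearman_pair(x, y)
            rows.append({"taxon": taxon, "metabolite": metab, "rho": rho, "p_value": p})
    table = pd.DataFrame(rows, columns=["taxon", "metabolite", "rho", "p_value"])
    if table.empty:
        table["p_adjusted"] = []
        table["significant"] = []
        return table

    if per_taxon_adjust:
        adjusted = np.empty(len(table))
        for taxon, idx in table.groupby("taxon").groups.items():
            adjusted[np.asarray(idx)] = multipletests(
                table.loc[idx, "p_value"], method="fdr_bh"
            )[1]
        table["p_adjusted"] = adjusted
    else:
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["significant"] = table["p_adjusted"] < alpha
    table["_abs_rho"] = table["rho"].abs()
    table = (
        table.sort_values(["taxon", "_abs_rho", "metabolite"], ascending=[True, False, True])
        .drop(columns="_abs_rho")
        .reset_index(drop=True)
    )
    return table
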