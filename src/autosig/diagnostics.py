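"""Batch-effect diagnostics: Bray-Curtis, PCoA and PERMANOVA, from scratch.

Multi-study cohorts carry technical structure (platform, primers,
population) that can masquerade as biology. This module quantifies it the
standard way: Bray-Curtis dissimilarities between samples, classical
principal-coordinate ordination, and a permutational multivariate ANOVA
(the "Adonis" test) of a grouping factor such as study of origin.

All three are implemented directly (no external distance/ordination
dependency); Bray-Curtis is not a metric (triangle inequality can fail),
which is documented rather than asserted.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance_io import TaxonomicProfile
from .errors import DimensionError, GroupingError

__all__ = ["DistanceMatrix", "PermanovaResult", "bray_curtis", "pcoa", "permanova"]


@dataclass
class DistanceMatrix:
    """A symmetric, zero-diagonal sample x sample dissimilarity matrix."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise DimensionError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DimensionError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise DimensionError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise DimensionError("negative dissimilarities")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(frame.index), frame.to_numpy(dtype=float))


@dataclass
class PermanovaResult:
    """Pseudo-F, variance explained and permutation p-value of one factor."""

    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def bray_curtis(profile: TaxonomicProfile) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0,1].

    A pair of all-zero samples has dissimilarity 0 by convention.
    """
    if profile.n_samples < 2:
        raise DimensionError("bray_curtis needs at least 2 samples")
    x = profile.data.to_numpy(dtype=float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den == 0, 1.0, den), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(profile.sample_ids, d)


def pcoa(dm: DistanceMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Classical scaling (principal coordinate analysis).

    Double-centres -D^2/2, eigendecomposes, and returns the coordinates on
    the top-``k`` positive-eigenvalue axes (columns ordered by descending
    eigenvalue; axes with non-positive eigenvalues are zero-filled) together
    with the full descending eigenvalue spectrum. Negative eigenvalues are
    reported so the caller can judge how non-Euclidean the input was.
    """
    n = len(dm.sample_ids)
    if k >= n:
        raise DimensionError(f"k={k} must be smaller than n={n}")
    d2 = dm.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    coords = np.zeros((n, k))
    for axis in range(k):
        if eigval[axis] > 1e-12:
            coords[:, axis] = eigvec[:, axis] * math.sqrt(eigval[axis])
    return coords, eigval


def _permanova_stat(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes."""
    n = len(codes)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0 or ss_within <= 0:
        return math.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def permanova(
    dm: DistanceMatrix,
    grouping: list[str] | np.ndarray | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA (Adonis) on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n and SS_within sums the analogous
    within-group terms; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)).
    The p-value uses the add-one estimator
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) over seeded uniform label
    permutations, so it can never be exactly 0. With ``exhaustive=True`` all
    distinct label arrangements are enumerated instead and p is the exact
    fraction with F >= F_obs (the observed arrangement included).
    """
    grouping = np.asarray(pd.Series(list(grouping)).astype(str))
    n = len(dm.sample_ids)
    if len(grouping) != n:
        raise DimensionError(f"grouping length {len(grouping)} != n samples {n}")
    levels, codes = np.unique(grouping, return_inverse=True)
    if len(levels) < 2:
        raise GroupingError("PERMANOVA needs at least 2 groups")
    if n_perm < 1 and not exhaustive:
        raise GroupingError("n_perm must be >= 1")
    d2 = dm.d**2
    a = len(levels)
    f_obs = _permanova_stat(d2, codes, a)

    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    if exhaustive:
        seen: set[tuple[int, ...]] = set()
        ge = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            if _permanova_stat(d2, np.asarray(perm), a) >= f_obs - 1e-12:
                ge += 1
        p = ge / len(seen)
        n_used = len(seen)
    else:
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_perm):
            if _permanova_stat(d2, rng.permutation(codes), a) >= f_obs - 1e-12:
                ge += 1
        p = (1 + ge) / (1 + n_perm)
        n_used = n_perm
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p_value=float(p), n_permutations=n_used)
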