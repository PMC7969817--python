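"""Reading, harmonising and preprocessing taxonomic abundance tables.

This module is the data layer of the pipeline: it parses per-study
abundance matrices (Greengenes-style ``k__A;p__B;...`` or MetaPhlAn-style
``k__A|p__B`` lineages), merges studies into one cohort, and applies the
standard preprocessing chain used throughout the analysis —

    first-timepoint selection -> rarefaction to a fixed depth ->
    taxonomic collapse (genus/species) -> relative abundance ->
    cohort filtering (disease subset, adults only) -> class balancing.

Rarefaction is a without-replacement (multivariate hypergeometric)
subsample to exactly ``depth`` reads; samples below the depth are dropped.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataError,
    DuplicateSampleError,
    DuplicateTaxonError,
    EmptyProfileError,
    FormatError,
    IncompatibleProfilesError,
    InsufficientDataError,
)

logger = logging.getLogger(__name__)

#: Rank letters in lineage order, kingdom -> species.
RANK_LETTERS: tuple[str, ...] = ("k", "p", "c", "o", "f", "g", "s")

#: Human-readable rank names accepted by :func:`collapse`.
RANK_NAMES: dict[str, str] = {
    "kingdom": "k",
    "phylum": "p",
    "class": "c",
    "order": "o",
    "family": "f",
    "genus": "g",
    "species": "s",
}

_TOKEN_RE = re.compile(r"^([a-z])__(.*)$")

#: Columns a metadata table must provide (``adult`` is derived).
METADATA_COLUMNS = ("study_id", "subject_id", "time_index", "disease", "age_years")

HEALTHY_LABEL = "healthy"


@dataclass(frozen=True)
class TaxonLineage:
    """An ordered kingdom->species lineage.

    ``ranks`` is a tuple of ``(rank_letter, name)`` pairs; letters appear in
    the fixed order of :data:`RANK_LETTERS` with no gaps (a rank may be
    present with an empty name, e.g. ``g__``, but interior ranks cannot be
    skipped entirely).
    """

    ranks: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        letters = tuple(r for r, _ in self.ranks)
        if letters != RANK_LETTERS[: len(letters)]:
            raise FormatError(
                f"lineage ranks must follow {RANK_LETTERS} without gaps, got {letters}"
            )

    @classmethod
    def parse(cls, text: str) -> "TaxonLineage":
        """Parse a semicolon- (Greengenes/QIIME) or pipe- (MetaPhlAn) delimited lineage."""
        text = text.strip()
        if not text:
            raise FormatError("empty lineage string")
        sep = "|" if "|" in text else ";"
        ranks: list[tuple[str, str]] = []
        for token in text.split(sep):
            token = token.strip()
            m = _TOKEN_RE.match(token)
            if m is None:
                raise FormatError(f"unparseable lineage token {token!r} in {text!r}")
            letter, name = m.group(1), m.group(2).strip()
            if letter == "t":  # MetaPhlAn strain level: out of scope, ignore
                continue
            if letter not in RANK_LETTERS:
                raise FormatError(f"unknown rank letter {letter!r} in {text!r}")
            ranks.append((letter, name))
        return cls(tuple(ranks))

    @property
    def canonical_string(self) -> str:
        """Semicolon-joined ``k__X;p__Y;...`` form; :meth:`parse` round-trips it."""
        return ";".join(f"{r}__{n}" for r, n in self.ranks)

    @property
    def depth_letter(self) -> str:
        """Letter of the deepest rank present (named or not)."""
        return self.ranks[-1][0]

    def name_at(self, letter: str) -> str | None:
        """Name at rank ``letter``, or None if the rank is absent."""
        for r, n in self.ranks:
            if r == letter:
                return n
        return None

    def truncate(self, letter: str) -> "TaxonLineage":
        """Truncate at rank ``letter``; unnamed target ranks fall back to the
        deepest named ancestor (so unassigned-genus mass is retained under its
        family rather than discarded)."""
        idx = RANK_LETTERS.index(letter)
        kept = self.ranks[: idx + 1]
        # drop trailing unnamed ranks so "k__A;f__F;g__" groups under the family
        while len(kept) > 1 and not kept[-1][1]:
            kept = kept[:-1]
        return TaxonLineage(kept)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_string


@dataclass
class TaxonomicProfile:
    """A samples x taxa abundance matrix.

    ``data`` holds samples as rows and canonical lineage strings as columns;
    ``value_kind`` is ``"counts"`` (non-negative integers) or ``"relative"``
    (rows sum to 1, or 0 for an empty sample).
    """

    data: pd.DataFrame
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "relative"):
            raise ConfigurationError(f"value_kind must be counts|relative, got {self.value_kind!r}")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateSampleError(f"duplicate sample IDs: {dupes}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DuplicateTaxonError(f"duplicate taxa: {dupes}")
        values = self.data.to_numpy()
        if values.size and (values < 0).any():
            raise DataError("negative abundance values")
        if self.value_kind == "counts" and values.size:
            if not np.allclose(values, np.round(values)):
                raise DataError("counts matrix contains non-integer values")
        if self.value_kind == "relative" and values.size:
            sums = values.sum(axis=1)
            bad = ~(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12))
            if bad.any():
                raise DataError(
                    f"relative-abundance rows must sum to 1 (or 0): {self.data.index[bad].tolist()}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[TaxonLineage]:
        return [TaxonLineage.parse(c) for c in self.data.columns]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]


def _looks_like_lineage(label: str) -> bool:
    try:
        TaxonLineage.parse(str(label))
        return True
    except FormatError:
        return False


def read_profile(path: str | Path, dialect: str = "semicolon-lineage") -> TaxonomicProfile:
    """Read a TSV abundance table, normalising lineages to canonical form.

    The table may be samples x taxa or taxa x samples; orientation is
    auto-detected by matching lineage patterns against the header row and
    index column. ``dialect`` is ``"semicolon-lineage"`` (Greengenes/QIIME)
    or ``"pipe-lineage"`` (MetaPhlAn); both are accepted by the parser, the
    argument only documents intent.
    """
    if dialect not in ("semicolon-lineage", "pipe-lineage"):
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty abundance file") from None
    if frame.empty and frame.shape[1] == 0:
        raise FormatError(f"{path}: abundance table has no data")

    cols_are_taxa = all(_looks_like_lineage(c) for c in frame.columns)
    rows_are_taxa = all(_looks_like_lineage(r) for r in frame.index)
    if rows_are_taxa and not cols_are_taxa:
        frame = frame.T  # taxa were rows: orient samples x taxa
    elif not cols_are_taxa and not rows_are_taxa:
        bad = [c for c in frame.columns if not _looks_like_lineage(c)][:3]
        raise FormatError(f"{path}: neither axis holds parseable lineages (e.g. {bad})")

    canonical = [TaxonLineage.parse(c).canonical_string for c in frame.columns]
    if len(set(canonical)) != len(canonical):
        seen: set[str] = set()
        dupes = sorted({c for c in canonical if c in seen or seen.add(c)})
        raise DuplicateTaxonError(f"{path}: duplicated lineages {dupes}")
    frame.columns = canonical
    frame.index = frame.index.astype(str)
    frame.index.name = None

    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise DataError(f"{path}: non-numeric or missing abundance cells")
    if (values < 0).any():
        raise DataError(f"{path}: negative abundance values")
    kind = "counts" if np.allclose(values, np.round(values)) else "relative"
    if kind == "relative":
        sums = values.sum(axis=1)
        nz = sums > 0
        frame.loc[nz] = frame.loc[nz].div(sums[nz], axis=0)  # tolerate percent-scaled input
    return TaxonomicProfile(frame.astype(float if kind == "relative" else np.int64), kind)


def write_profile(profile: TaxonomicProfile, path: str | Path) -> None:
    """Write a profile as a samples x taxa TSV (canonical lineage columns)."""
    profile.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a per-sample metadata TSV and derive the ``adult`` flag."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={"study_id": str, "subject_id": str})
    meta.index = meta.index.astype(str)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, derive ``adult`` (age >= 18; missing age -> NA)."""
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    if meta.index.duplicated().any():
        raise DuplicateSampleError("duplicate sample IDs in metadata")
    meta = meta.copy()
    meta["time_index"] = meta["time_index"].astype(int)
    if (meta["time_index"] < 0).any():
        raise DataError("negative time_index in metadata")
    age = pd.to_numeric(meta["age_years"], errors="coerce")
    if (age.dropna() < 0).any():
        raise DataError("negative age_years in metadata")
    meta["age_years"] = age
    meta["adult"] = age >= 18  # NaN age compares False -> treated as unknown/non-adult
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def _aligned(profile: TaxonomicProfile, metadata: pd.DataFrame) -> None:
    if set(profile.sample_ids) != set(metadata.index):
        only_p = sorted(set(profile.sample_ids) - set(metadata.index))[:3]
        only_m = sorted(set(metadata.index) - set(profile.sample_ids))[:3]
        raise DataError(
            f"profile and metadata sample sets differ (profile-only {only_p}, metadata-only {only_m})"
        )


def merge_studies(
    profiles: Sequence[TaxonomicProfile],
    metadata: Sequence[pd.DataFrame],
    prefix_study: bool = True,
) -> tuple[TaxonomicProfile, pd.DataFrame]:
    """Merge per-study profiles into one cohort matrix over the taxon union.

    Taxa absent from a study are filled with 0; sample order is the
    concatenation of the inputs. Sample IDs are prefixed ``"<study_id>:"``
    to guarantee global uniqueness (disable with ``prefix_study=False``).
    """
    if len(profiles) != len(metadata):
        raise DataError("one metadata table required per profile")
    if not profiles:
        raise EmptyProfileError("no profiles to merge")
    kinds = {p.value_kind for p in profiles}
    if len(kinds) > 1:
        raise IncompatibleProfilesError(f"cannot merge mixed value kinds {sorted(kinds)}")

    frames, metas = [], []
    for prof, meta in zip(profiles, metadata):
        meta = validate_metadata(meta)
        _aligned(prof, meta)
        frame = prof.data.copy()
        meta = meta.loc[frame.index].copy()
        if prefix_study:
            new_ids = meta["study_id"].astype(str) + ":" + frame.index.astype(str)
            frame.index = new_ids
            meta.index = new_ids
        frames.append(frame)
        metas.append(meta)

    merged = pd.concat(frames, axis=0, join="outer").fillna(0)
    # pd.concat preserves column union ordering poorly; fix to first-seen order
    ordered: list[str] = []
    seen: set[str] = set()
    for frame in frames:
        for c in frame.columns:
            if c not in seen:
                seen.add(c)
                ordered.append(c)
    merged = merged[ordered]
    if merged.index.duplicated().any():
        dupes = merged.index[merged.index.duplicated()].tolist()
        raise DuplicateSampleError(f"duplicate sample IDs after merge: {dupes}")
    kind = profiles[0].value_kind
    if kind == "counts":
        merged = merged.astype(np.int64)
    return TaxonomicProfile(merged, kind), pd.concat(metas, axis=0)


def select_first_timepoint(
    profile: TaxonomicProfile, metadata: pd.DataFrame
) -> tuple[TaxonomicProfile, pd.DataFrame]:
    """Keep one sample per (study, subject): minimum time_index, ties broken
    by lexicographic sample ID."""
    _aligned(profile, metadata)
    meta = metadata.loc[profile.sample_ids].copy()
    meta["_sid"] = meta.index
    first = (
        meta.sort_values(["study_id", "subject_id", "time_index", "_sid"])
        .groupby(["study_id", "subject_id"], sort=False)
        .head(1)
    )
    keep = [sid for sid in profile.sample_ids if sid in set(first.index)]
    logger.info("first-timepoint selection kept %d of %d samples", len(keep), profile.n_samples)
    return (
        TaxonomicProfile(profile.data.loc[keep], profile.value_kind),
        metadata.loc[keep],
    )


def rarefy(profile: TaxonomicProfile, depth: int, seed: int) -> TaxonomicProfile:
    """Rarefy every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and logged).
    Subsampling is multivariate hypergeometric, so each retained row sums to
    exactly ``depth``; the same seed reproduces the draw bit-for-bit.
    """
    if profile.value_kind != "counts":
        raise ConfigurationError("rarefy requires a counts profile")
    if depth <= 0:
        raise ConfigurationError(f"rarefaction depth must be positive, got {depth}")
    counts = profile.data.to_numpy(dtype=np.int64)
    sums = counts.sum(axis=1)
    keep = sums >= depth
    dropped = [sid for sid, k in zip(profile.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy(depth=%d) dropped %d samples: %s", depth, len(dropped), dropped)
    if not keep.any():
        raise EmptyProfileError(f"all samples below rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for i, row in enumerate(counts[keep]):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    frame = pd.DataFrame(
        out, index=[s for s, k in zip(profile.sample_ids, keep) if k], columns=profile.data.columns
    )
    return TaxonomicProfile(frame, "counts")


def collapse(profile: TaxonomicProfile, level: str) -> TaxonomicProfile:
    """Sum taxa sharing a lineage prefix at ``level`` ("genus" or "species").

    Taxa whose name at ``level`` is empty (e.g. ``g__``) or whose lineage
    stops above ``level`` are grouped under their deepest named ancestor, so
    the matrix grand total is conserved exactly.
    """
    letter = RANK_NAMES.get(level, level)
    if letter not in RANK_LETTERS:
        raise ConfigurationError(f"unknown collapse level {level!r}")
    groups: dict[str, list[str]] = {}
    for col in profile.data.columns:
        key = TaxonLineage.parse(col).truncate(letter).canonical_string
        groups.setdefault(key, []).append(col)
    collapsed = pd.DataFrame(
        {key: profile.data[cols].sum(axis=1) for key, cols in groups.items()},
        index=profile.data.index,
    )
    return TaxonomicProfile(collapsed, profile.value_kind)


def to_relative(profile: TaxonomicProfile) -> TaxonomicProfile:
    """Convert counts to per-sample relative abundances (rows sum to 1).

    All-zero samples stay zero and are logged.
    """
    if profile.value_kind != "counts":
        raise ConfigurationError("to_relative requires a counts profile")
    values = profile.data.to_numpy(dtype=float)
    sums = values.sum(axis=1)
    zero_rows = sums == 0
    if zero_rows.any():
        logger.warning(
            "to_relative: %d all-zero samples left as zero rows: %s",
            int(zero_rows.sum()),
            [s for s, z in zip(profile.sample_ids, zero_rows) if z],
        )
    safe = np.where(zero_rows, 1.0, sums)
    rel = values / safe[:, None]
    return TaxonomicProfile(
        pd.DataFrame(rel, index=profile.data.index, columns=profile.data.columns), "relative"
    )


def filter_cohort(
    profile: TaxonomicProfile,
    metadata: pd.DataFrame,
    diseases: Iterable[str],
    adults_only: bool = False,
    min_per_class: int = 2,
) -> tuple[TaxonomicProfile, pd.DataFrame]:
    """Subset to samples with a disease label in ``diseases`` (include
    ``"healthy"`` explicitly to keep controls); optionally keep adults only.

    Samples with missing age are excluded from adult-only cohorts.
    """
    _aligned(profile, metadata)
    wanted = set(diseases)
    meta = metadata.loc[profile.sample_ids]
    mask = meta["disease"].isin(wanted)
    if adults_only:
        mask &= meta["adult"].fillna(False).astype(bool)
    keep = meta.index[mask]
    kept_meta = metadata.loc[keep]
    class_sizes = kept_meta["disease"].value_counts()
    for label in sorted(wanted):
        if class_sizes.get(label, 0) < min_per_class:
            raise InsufficientDataError(
                f"class {label!r} has {class_sizes.get(label, 0)} samples "
                f"(< {min_per_class}) after filtering"
            )
    return TaxonomicProfile(profile.data.loc[keep], profile.value_kind), kept_meta


def balance_classes(
    profile: TaxonomicProfile, metadata: pd.DataFrame, seed: int
) -> tuple[TaxonomicProfile, pd.DataFrame]:
    """Subsample the majority class (without replacement) down to the
    minority-class size; requires exactly two disease labels."""
    _aligned(profile, metadata)
    meta = metadata.loc[profile.sample_ids]
    labels = meta["disease"]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise InsufficientDataError(f"balance_classes needs exactly 2 classes, got {classes}")
    sizes = labels.value_counts()
    n_target = int(sizes.min())
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for cls in classes:
        ids = list(labels.index[labels == cls])
        if len(ids) > n_target:
            ids = sorted(rng.choice(ids, size=n_target, replace=False))
            logger.info(
                "balance_classes(seed=%d): subsampled %s from %d to %d",
                seed, cls, int(sizes[cls]), n_target,
            )
        keep.extend(ids)
    keep = [sid for sid in profile.sample_ids if sid in set(keep)]  # preserve order
    return TaxonomicProfile(profile.data.loc[keep], profile.value_kind), metadata.loc[keep]
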