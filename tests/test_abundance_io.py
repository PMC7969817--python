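"""I/O and preprocessing contracts: parsing, merging, rarefaction, collapse."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from autosig import abundance_io as aio
from autosig.abundance_io import TaxonLineage, TaxonomicProfile
from autosig.errors import (
    ConfigurationError,
    DataError,
    DuplicateSampleError,
    DuplicateTaxonError,
    EmptyProfileError,
    FormatError,
    IncompatibleProfilesError,
    InsufficientDataError,
)
from conftest import make_metadata, make_profile, lineages


class TestLineage:
    @pytest.mark.parametrize(
        "text,canonical",
        [
            ("k__Bacteria|g__Roseburia", None),  # gap: g directly after k
            ("k__Bacteria;p__Firmicutes", "k__Bacteria;p__Firmicutes"),
            (
                "k__Bacteria|p__Firmicutes|c__Clostridia",
                "k__Bacteria;p__Firmicutes;c__Clostridia",
            ),
            ("k__Bacteria;p__;c__", "k__Bacteria;p__;c__"),  # empty names allowed
        ],
    )
    def test_parse_and_canonicalise(self, text, canonical):
        if canonical is None:
            with pytest.raises(FormatError):
                TaxonLineage.parse(text)
        else:
            assert TaxonLineage.parse(text).canonical_string == canonical

    def test_pipe_dialect_converts_to_semicolon(self):
        full = "k__Bacteria|p__Firmicutes|c__Clostridia|o__Clostridiales|f__Lachnospiraceae|g__Roseburia"
        assert (
            TaxonLineage.parse(full).canonical_string
            == "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Lachnospiraceae;g__Roseburia"
        )

    def test_strain_suffix_ignored(self):
        lin = TaxonLineage.parse("k__B|p__P|c__C|o__O|f__F|g__G|s__S|t__T1")
        assert lin.depth_letter == "s"

    @given(
        st.lists(
            st.text(alphabet="abcXYZ123", min_size=0, max_size=6),
            min_size=1,
            max_size=7,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_property(self, names):
        ranks = tuple((aio.RANK_LETTERS[i], n) for i, n in enumerate(names))
        lin = TaxonLineage(ranks)
        assert TaxonLineage.parse(lin.canonical_string) == lin

    def test_unparseable_token_rejected(self):
        with pytest.raises(FormatError):
            TaxonLineage.parse("not a lineage")


class TestReadProfile:
    def test_reads_pipe_dialect_and_orients(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text(
            "taxon\tsampleA\tsampleB\n"
            "k__Bacteria|p__Firmicutes\t3\t0\n"
            "k__Bacteria|p__Bacteroidetes\t1\t5\n"
        )
        prof = aio.read_profile(path, dialect="pipe-lineage")
        assert prof.sample_ids == ["sampleA", "sampleB"]
        assert list(prof.data.columns) == [
            "k__Bacteria;p__Firmicutes",
            "k__Bacteria;p__Bacteroidetes",
        ]
        assert prof.value_kind == "counts"

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(FormatError):
            aio.read_profile(path)

    def test_duplicate_lineages_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(
            "taxon\ts1\nk__B;p__F\t1\nk__B|p__F\t2\n"  # same taxon, two dialects
        )
        with pytest.raises(DuplicateTaxonError):
            aio.read_profile(path)

    def test_negative_values_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("taxon\ts1\nk__B;p__F\t-3\n")
        with pytest.raises(DataError):
            aio.read_profile(path)

    def test_write_read_roundtrip(self, tmp_path):
        prof = make_profile([[1, 2, 3], [4, 0, 6]])
        aio.write_profile(prof, tmp_path / "x.tsv")
        back = aio.read_profile(tmp_path / "x.tsv")
        pd.testing.assert_frame_equal(back.data, prof.data)


class TestMerge:
    def test_union_fill_with_zeros(self):
        p1 = make_profile([[5]], sample_ids=["a"], taxa=["k__B;p__X"])
        p2 = make_profile([[7]], sample_ids=["b"], taxa=["k__B;p__Y"])
        m1 = make_metadata(["a"], study="s1")
        m2 = make_metadata(["b"], study="s2")
        merged, meta = aio.merge_studies([p1, p2], [m1, m2])
        assert merged.data.shape == (2, 2)
        assert merged.data.loc["s1:a", "k__B;p__Y"] == 0
        assert merged.data.loc["s2:b", "k__B;p__X"] == 0
        assert list(meta.index) == ["s1:a", "s2:b"]

    def test_merging_profile_with_itself_rejected(self):
        p = make_profile([[1, 2]], sample_ids=["a"])
        m = make_metadata(["a"])
        with pytest.raises(DuplicateSampleError):
            aio.merge_studies([p, p], [m, m])

    def test_mixed_value_kinds_rejected(self):
        p1 = make_profile([[1, 1]], sample_ids=["a"])
        p2 = make_profile([[0.5, 0.5]], sample_ids=["b"], kind="relative")
        with pytest.raises(IncompatibleProfilesError):
            aio.merge_studies([p1, p2], [make_metadata(["a"]), make_metadata(["b"], study="s2")])

    def test_three_study_union_preserves_row_sums(self):
        rng = np.random.default_rng(4)
        taxa = lineages(12)
        profiles, metas = [], []
        for j, cols in enumerate([taxa[:6], taxa[3:9], taxa[6:]]):
            vals = rng.integers(0, 50, size=(4, len(cols)))
            p = make_profile(vals, sample_ids=[f"st{j}_s{i}" for i in range(4)], taxa=cols)
            profiles.append(p)
            metas.append(make_metadata(p.sample_ids, study=f"st{j}"))
        merged, _ = aio.merge_studies(profiles, metas)
        union = sorted(set(taxa[:6]) | set(taxa[3:9]) | set(taxa[6:]))
        assert sorted(merged.data.columns) == union
        expected_sums = np.concatenate([p.data.sum(axis=1).to_numpy() for p in profiles])
        np.testing.assert_array_equal(merged.data.sum(axis=1).to_numpy(), expected_sums)

    def test_split_and_remerge_is_identity(self):
        rng = np.random.default_rng(0)
        merged = make_profile(rng.integers(0, 9, (6, 5)))
        meta = make_metadata(merged.sample_ids, study=["s1"] * 3 + ["s2"] * 3)
        parts, part_meta = [], []
        for st_id in ("s1", "s2"):
            ids = meta.index[meta["study_id"] == st_id]
            parts.append(TaxonomicProfile(merged.data.loc[ids], "counts"))
            part_meta.append(meta.loc[ids])
        again, _ = aio.merge_studies(parts, part_meta, prefix_study=False)
        pd.testing.assert_frame_equal(again.data, merged.data)


class TestFirstTimepoint:
    def test_minimum_time_index_kept(self):
        p = make_profile(np.arange(12).reshape(3, 4), sample_ids=["t0", "t1", "t2"])
        meta = make_metadata(["t0", "t1", "t2"], subject=["u", "u", "u"], time=[0, 1, 2])
        out, _ = aio.select_first_timepoint(p, meta)
        assert out.sample_ids == ["t0"]

    def test_single_timepoint_cohort_unchanged(self):
        p = make_profile(np.eye(3, 4))
        meta = make_metadata(p.sample_ids)
        out, _ = aio.select_first_timepoint(p, meta)
        assert out.sample_ids == p.sample_ids

    def test_five_subjects_three_timepoints_gives_five(self):
        ids = [f"u{i}_t{t}" for i in range(5) for t in range(3)]
        p = make_profile(np.ones((15, 2)), sample_ids=ids)
        meta = make_metadata(
            ids,
            subject=[s.split("_")[0] for s in ids],
            time=[int(s.split("_t")[1]) for s in ids],
        )
        out, out_meta = aio.select_first_timepoint(p, meta)
        assert out.n_samples == 5
        assert (out_meta["time_index"] == 0).all()


class TestRarefy:
    def test_depth_contract_and_dropped_set(self):
        rng = np.random.default_rng(1)
        rows = [rng.multinomial(d, [0.25] * 4) for d in (6000, 5000, 4999)]
        p = make_profile(rows)
        out = aio.rarefy(p, depth=5000, seed=0)
        assert out.sample_ids == ["s0", "s1"]
        assert (out.data.sum(axis=1) == 5000).all()

    def test_sample_at_exact_depth_unchanged(self):
        p = make_profile([[3000, 2000, 0, 0]])
        out = aio.rarefy(p, 5000, seed=1)
        np.testing.assert_array_equal(out.data.to_numpy()[0], [3000, 2000, 0, 0])

    def test_hypergeometric_mean(self):
        # sample (4000, 2000) rarefied to 3000: E[first taxon] = 3000*4000/6000 = 2000
        p = make_profile(np.tile([4000, 2000], (10_000, 1)), taxa=lineages(2))
        out = aio.rarefy(p, 3000, seed=2)
        assert abs(out.data.iloc[:, 0].mean() - 2000) < 20

    def test_errors(self):
        p = make_profile([[10, 10]])
        with pytest.raises(ConfigurationError):
            aio.rarefy(p, 0, seed=0)
        with pytest.raises(EmptyProfileError):
            aio.rarefy(p, 5000, seed=0)

    def test_seed_reproducibility(self):
        p = make_profile([[4000, 2000, 1000]])
        a = aio.rarefy(p, 3000, seed=5)
        b = aio.rarefy(p, 3000, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestCollapse:
    def test_species_sum_to_genus(self):
        taxa = [
            "k__B;p__F;c__C;o__O;f__L;g__Clostridium;s__a",
            "k__B;p__F;c__C;o__O;f__L;g__Clostridium;s__b",
        ]
        p = make_profile([[3, 4]], taxa=taxa)
        out = aio.collapse(p, "genus")
        assert list(out.data.columns) == ["k__B;p__F;c__C;o__O;f__L;g__Clostridium"]
        assert out.data.iloc[0, 0] == 7

    def test_collapse_at_own_level_is_identity(self):
        taxa = ["k__B;p__F;c__C;o__O;f__L;g__G1;s__x", "k__B;p__F;c__C;o__O;f__L;g__G2;s__y"]
        p = make_profile([[1, 2]], taxa=taxa)
        out = aio.collapse(p, "species")
        pd.testing.assert_frame_equal(out.data, p.data)

    def test_unnamed_genus_groups_under_family_and_conserves_total(self):
        taxa = [
            "k__B;p__F;c__C;o__O;f__Mogibacteriaceae;g__",
            "k__B;p__F;c__C;o__O;f__Mogibacteriaceae;g__Named",
            "k__B;p__F;c__C;o__O;f__Other;g__X",
        ]
        p = make_profile([[5, 2, 1], [1, 1, 1]], taxa=taxa)
        out = aio.collapse(p, "genus")
        assert "k__B;p__F;c__C;o__O;f__Mogibacteriaceae" in out.data.columns
        assert out.data.to_numpy().sum() == p.data.to_numpy().sum()
        assert out.data.loc["s0", "k__B;p__F;c__C;o__O;f__Mogibacteriaceae"] == 5


class TestRelativeAndFilters:
    def test_to_relative_rows(self):
        p = make_profile([[2, 2, 0, 4], [0, 0, 0, 0]])
        out = aio.to_relative(p)
        np.testing.assert_allclose(out.data.iloc[0], [0.25, 0.25, 0, 0.5])
        np.testing.assert_allclose(out.data.iloc[1], 0)
        assert out.value_kind == "relative"

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_relative_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        p = make_profile(rng.integers(0, 30, (5, 8)))
        out = aio.to_relative(p)
        sums = out.data.sum(axis=1).to_numpy()
        keep = p.data.sum(axis=1).to_numpy() > 0
        np.testing.assert_allclose(sums[keep], 1.0, atol=1e-9)

    def test_adults_only_excludes_missing_age(self):
        p = make_profile(np.ones((6, 3)))
        meta = make_metadata(
            p.sample_ids,
            disease=["d"] * 3 + ["healthy"] * 3,
            age=[12.0, 30.0, np.nan, 45.0, 50.0, np.nan],
        )
        out, out_meta = aio.filter_cohort(p, meta, {"d", "healthy"}, adults_only=True, min_per_class=1)
        assert set(out.sample_ids) == {"s1", "s3", "s4"}

    def test_missing_disease_class_is_insufficient(self):
        p = make_profile(np.ones((4, 2)))
        meta = make_metadata(p.sample_ids, disease=["MS"] * 4)
        with pytest.raises(InsufficientDataError):
            aio.filter_cohort(p, meta, {"IBD", "healthy"})

    def test_filter_matches_brute_force(self):
        rng = np.random.default_rng(8)
        p = make_profile(rng.integers(0, 5, (30, 4)))
        diseases = rng.choice(["IBD", "MS", "healthy"], 30)
        ages = rng.choice([10.0, 25.0, 40.0], 30)
        meta = make_metadata(p.sample_ids, disease=list(diseases), age=list(ages))
        out, _ = aio.filter_cohort(p, meta, {"IBD", "healthy"}, adults_only=True)
        expected = [
            sid
            for sid, d, a in zip(p.sample_ids, diseases, ages)
            if d in {"IBD", "healthy"} and a >= 18
        ]
        assert out.sample_ids == expected


class TestBalance:
    def test_majority_subsampled(self):
        p = make_profile(np.ones((140, 2)))
        meta = make_metadata(p.sample_ids, disease=["healthy"] * 100 + ["IBD"] * 40)
        out, out_meta = aio.balance_classes(p, meta, seed=0)
        assert out_meta["disease"].value_counts().to_dict() == {"healthy": 40, "IBD": 40}

    def test_already_balanced_identity(self):
        p = make_profile(np.ones((8, 2)))
        meta = make_metadata(p.sample_ids, disease=["a"] * 4 + ["b"] * 4)
        out, _ = aio.balance_classes(p, meta, seed=3)
        assert out.sample_ids == p.sample_ids

    def test_seed_determinism(self):
        p = make_profile(np.ones((50, 2)))
        meta = make_metadata(p.sample_ids, disease=["a"] * 30 + ["b"] * 20)
        a, _ = aio.balance_classes(p, meta, seed=9)
        b, _ = aio.balance_classes(p, meta, seed=9)
        assert a.sample_ids == b.sample_ids
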