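"""Core containers, I/O and preprocessing filters."""

import numpy as np
import pandas as pd
import pytest

from cfmdna.tables import (
    AsvCountTable,
    StudyDesign,
    TaxonomyTable,
    ValidationError,
    filter_low_abundance,
    filter_nontarget_taxa,
    merge_technical_replicates,
    rarefy,
    read_count_table,
    read_design,
    read_taxonomy,
    transform,
    write_count_table,
    write_taxonomy,
)


class TestCountTableIO:
    def test_tsv_read_back(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("asv_id\ts1\ts2\na\t5\t0\nb\t1\t2\nc\t0\t7\n")
        table = read_count_table(path)
        assert list(table.counts.sum(axis=1)) == [5, 3, 7]
        assert table.sample_ids == ["s1", "s2"]

    @pytest.mark.parametrize("fmt", ["tsv", "biom"])
    def test_round_trip_bit_exact(self, tmp_path, small_table, fmt):
        path = tmp_path / f"c.{fmt}"
        write_count_table(small_table, path, fmt=fmt)
        back = read_count_table(path, fmt=fmt)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("asv_id\ts1\ts2\n")
        with pytest.raises(ValidationError, match="no ASVs"):
            read_count_table(path)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            AsvCountTable(pd.DataFrame({"s1": [-1, 2]}, index=["a", "b"]))
        with pytest.raises(ValidationError):
            AsvCountTable(pd.DataFrame({"s1": [1.5, 2.0]}, index=["a", "b"]))
        with pytest.raises(ValidationError, match="duplicate"):
            AsvCountTable(pd.DataFrame([[1], [2]], index=["a", "a"], columns=["s1"]))


class TestStudyDesign:
    def test_read_valid(self, tmp_path):
        path = tmp_path / "d.tsv"
        rows = ["sample_id\tsample_type\textraction_batch"]
        rows += [f"p{i}\tplasma\tA" for i in range(4)]
        rows += [f"n{i}\tplasma_denc\tA" for i in range(2)]
        path.write_text("\n".join(rows) + "\n")
        design = read_design(path)
        assert len(design.samples_of_type("plasma_denc")) == 2

    def test_unknown_sample_type(self):
        with pytest.raises(ValidationError, match="sample_type"):
            StudyDesign(pd.DataFrame({"sample_id": ["s1"], "sample_type": ["serum"]}))

    def test_day_in_two_batches_is_nesting_error(self):
        with pytest.raises(ValidationError, match="nesting"):
            StudyDesign(
                pd.DataFrame(
                    {
                        "sample_id": ["s1", "s2"],
                        "sample_type": ["plasma", "plasma"],
                        "extraction_batch": ["A", "B"],
                        "extraction_day": ["d1", "d1"],
                    }
                )
            )

    def test_replicate_group_spanning_patients_rejected(self):
        with pytest.raises(ValidationError, match="patients"):
            StudyDesign(
                pd.DataFrame(
                    {
                        "sample_id": ["s1", "s2"],
                        "sample_type": ["plasma", "plasma"],
                        "patient_id": ["p1", "p2"],
                        "extraction_batch": ["A", "B"],
                        "replicate_group": ["rg1", "rg1"],
                    }
                )
            )


class TestTaxonomy:
    def test_qiime_style_round_trip(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "Feature ID\tTaxon\tConfidence\n"
            "a\td__Bacteria;p__Firmicutes;c__Clostridia;o__Oscillospirales;"
            "f__Ruminococcaceae;g__Faecalibacterium\t0.99\n"
            "b\td__Bacteria;p__Proteobacteria\t0.80\n"
        )
        tax = read_taxonomy(path)
        assert tax.lineage("a")[-1] == "Faecalibacterium"
        assert tax.lineage("b") == ("Bacteria", "Proteobacteria")
        out = tmp_path / "t2.tsv"
        write_taxonomy(tax, out)
        back = read_taxonomy(out)
        assert back.lineage("a") == tax.lineage("a")

    def test_internal_gap_rejected(self):
        with pytest.raises(ValidationError, match="gap"):
            TaxonomyTable(
                pd.DataFrame(
                    {"asv_id": ["a"], "domain": ["Bacteria"], "phylum": [""],
                     "class": ["Clostridia"]}
                )
            )


class TestNontargetFilter:
    def _tax(self, families):
        return TaxonomyTable(
            pd.DataFrame(
                {
                    "asv_id": [f"a{i}" for i in range(len(families))],
                    "domain": "Bacteria",
                    "phylum": "Proteobacteria",
                    "class": "c",
                    "order": "o",
                    "family": families,
                }
            )
        )

    def test_mitochondria_removed(self):
        table = AsvCountTable(
            pd.DataFrame(np.ones((5, 2), int), index=[f"a{i}" for i in range(5)],
                         columns=["s1", "s2"])
        )
        tax = self._tax(["F1", "Mitochondria", "F2", "F3", "F4"])
        out = filter_nontarget_taxa(table, tax)
        assert len(out.asv_ids) == 4 and "a1" not in out.asv_ids

    def test_no_match_is_identity(self, small_table):
        tax = self._tax(["F1", "F2", "F3"])
        tax.frame.index = small_table.asv_ids
        out = filter_nontarget_taxa(small_table, tax)
        pd.testing.assert_frame_equal(out.counts, small_table.counts)

    def test_all_match_empty_with_warning(self):
        table = AsvCountTable(pd.DataFrame({"s1": [1, 2]}, index=["a0", "a1"]))
        tax = self._tax(["Mitochondria", "Chloroplast"])
        with pytest.warns(UserWarning, match="non-target"):
            out = filter_nontarget_taxa(table, tax)
        assert out.counts.shape[0] == 0

    def test_missing_taxonomy_is_error(self, small_table):
        tax = self._tax(["F1"])
        with pytest.raises(ValidationError, match="missing"):
            filter_nontarget_taxa(small_table, tax)


class TestMergeReplicates:
    def test_counts_sum(self):
        table = AsvCountTable(
            pd.DataFrame({"r1": [3, 0], "r2": [2, 5]}, index=["a", "b"])
        )
        design = StudyDesign(
            pd.DataFrame(
                {
                    "sample_id": ["r1", "r2"],
                    "sample_type": ["plasma", "plasma"],
                    "pcr_group": ["g1", "g1"],
                }
            )
        )
        merged, mdes = merge_technical_replicates(table, design, "pcr_group")
        assert list(merged.counts["g1"]) == [5, 5]
        assert merged.counts.to_numpy().sum() == table.counts.to_numpy().sum()

    def test_singletons_unchanged(self, small_table, small_design):
        merged, _ = merge_technical_replicates(small_table, small_design, "pcr_group")
        assert sorted(merged.sample_ids) == sorted(small_table.sample_ids)
        total_before = small_table.counts.to_numpy().sum()
        assert merged.counts.to_numpy().sum() == total_before

    def test_mixed_sample_types_rejected(self):
        table = AsvCountTable(pd.DataFrame({"r1": [1], "r2": [1]}, index=["a"]))
        design = StudyDesign(
            pd.DataFrame(
                {
                    "sample_id": ["r1", "r2"],
                    "sample_type": ["plasma", "plasma_denc"],
                    "pcr_group": ["g1", "g1"],
                }
            )
        )
        with pytest.raises(ValidationError, match="mixes"):
            merge_technical_replicates(table, design, "pcr_group")


class TestLowAbundanceFilter:
    def _fixture(self):
        # plasma stratum totals 100000 reads; asv_rare holds 1 read (0.001%)
        counts = pd.DataFrame(
            {
                "p1": [50000, 1, 10],
                "p2": [49979, 0, 10],
            },
            index=["asv_big", "asv_rare", "asv_edge"],
        )
        design = StudyDesign(
            pd.DataFrame({"sample_id": ["p1", "p2"], "sample_type": ["plasma"] * 2})
        )
        return AsvCountTable(counts), design

    def test_below_floor_removed(self):
        table, design = self._fixture()
        out = filter_low_abundance(table, design, 0.01)
        assert "asv_rare" not in out.asv_ids

    def test_exactly_at_floor_retained(self):
        # asv_edge has 20/100000 = exactly 0.02%; floor 0.02 keeps it
        table, design = self._fixture()
        out = filter_low_abundance(table, design, 0.02)
        assert "asv_edge" in out.asv_ids

    def test_zero_floor_identity(self):
        table, design = self._fixture()
        out = filter_low_abundance(table, design, 0.0)
        pd.testing.assert_frame_equal(out.counts, table.counts)

    def test_idempotent(self, default_cohort):
        table, design, _, _ = default_cohort
        once = filter_low_abundance(table, design, 0.01)
        twice = filter_low_abundance(once, design, 0.01)
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_per_stratum_removal(self):
        # rare in plasma but abundant in the DENC stratum: kept only there
        counts = pd.DataFrame(
            {"p1": [99999, 1], "n1": [50, 50]}, index=["big", "mixed"]
        )
        design = StudyDesign(
            pd.DataFrame(
                {"sample_id": ["p1", "n1"], "sample_type": ["plasma", "plasma_denc"]}
            )
        )
        out = filter_low_abundance(AsvCountTable(counts), design, 0.01)
        assert out.counts.loc["mixed", "p1"] == 0
        assert out.counts.loc["mixed", "n1"] == 50


class TestRarefy:
    def test_depth_equal_to_column_sum_is_identity(self, small_table):
        depth = int(small_table.library_sizes().min())
        out = rarefy(small_table, depth, seed=0)
        kept = out.sample_ids
        assert all(out.counts[s].sum() == depth for s in kept)

    def test_column_sums_equal_depth(self, default_cohort):
        table, *_ = default_cohort
        depth = int(table.library_sizes().min())
        out = rarefy(table, depth, seed=3)
        assert (out.counts.sum(axis=0) == depth).all()

    def test_deterministic_and_seed_sensitive(self, default_cohort):
        table, *_ = default_cohort
        depth = int(table.library_sizes().min() // 2)
        a = rarefy(table, depth, seed=5)
        b = rarefy(table, depth, seed=5)
        c = rarefy(table, depth, seed=6)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert not a.counts.equals(c.counts)

    def test_subsample_never_exceeds_input(self, small_table):
        out = rarefy(small_table, 3, seed=1)
        for s in out.sample_ids:
            assert (out.counts[s] <= small_table.counts[s]).all()

    def test_bad_depth(self, small_table):
        with pytest.raises(ValueError):
            rarefy(small_table, 0, seed=0)


class TestTransform:
    def test_relative(self):
        table = AsvCountTable(pd.DataFrame({"s": [2, 2, 4]}, index=list("abc")))
        rel = transform(table, "relative")
        assert np.allclose(rel["s"], [0.25, 0.25, 0.5])

    def test_sqrt_is_sqrt_of_relative(self, small_table):
        rel = transform(small_table, "relative")
        sq = transform(small_table, "sqrt")
        assert np.allclose(sq.to_numpy(), np.sqrt(rel.to_numpy()))

    def test_clr_constant_column_is_zero(self):
        table = AsvCountTable(pd.DataFrame({"s": [7, 7, 7]}, index=list("abc")))
        clr = transform(table, "clr")
        assert np.allclose(clr["s"], 0.0)

    def test_clr_closure(self, default_cohort):
        table, *_ = default_cohort
        clr = transform(table, "clr")
        assert np.abs(clr.sum(axis=0)).max() < 1e-9

    def test_log_cpm_formula(self):
        table = AsvCountTable(pd.DataFrame({"s": [10, 90]}, index=["a", "b"]))
        out = transform(table, "log_cpm", prior_cpm=0.5)
        expect = np.log2(1e6 * (np.array([10, 90]) + 0.5) / (100 + 1.0))
        assert np.allclose(out["s"], expect)

    def test_clr_requires_positive_offset(self, small_table):
        with pytest.raises(ValueError):
            transform(small_table, "clr", offset=0.0)
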