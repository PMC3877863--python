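"""Base-coverage quantification: SAM ingestion, read filter, counting, normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fungiflow as ff
from fungiflow.quantify import (
    CoverageTable,
    SamFormatError,
    UnknownLocusError,
    read_expression_tsv,
    write_expression_table,
)

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:locusA\tLN:300\n@SQ\tSN:locusB\tLN:200\n"


def _sam(tmp_path, body: str):
    path = tmp_path / "test.sam"
    path.write_text(SAM_HEADER + body)
    return path


def _line(qname, flag, rname, pos, cigar, seq_len):
    return (
        f"{qname}\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0\t"
        f"{'A' * seq_len}\t{'I' * seq_len}\n"
    )


ANNOT = {"locusA": 300, "locusB": 200}


class TestReadAlignments:
    def test_full_length_single_locus_record(self, tmp_path):
        path = _sam(tmp_path, _line("r1", 0, "locusA", 10, "50M", 50))
        (rec,) = ff.read_alignments(path, ANNOT)
        assert rec.read_length == 50
        assert rec.aligned_span == 50
        assert not rec.is_clipped
        assert rec.n_loci_hit == 1

    def test_multi_locus_read_counts_distinct_loci(self, tmp_path):
        body = _line("r1", 0, "locusA", 10, "50M", 50) + _line("r1", 256, "locusB", 5, "50M", 50)
        path = _sam(tmp_path, body)
        recs = ff.read_alignments(path, ANNOT)
        assert len(recs) == 2
        assert all(r.n_loci_hit == 2 for r in recs)

    def test_repeat_alignment_same_locus_is_one_locus_hit(self, tmp_path):
        body = _line("r1", 0, "locusA", 10, "50M", 50) + _line("r1", 256, "locusA", 80, "50M", 50)
        recs = ff.read_alignments(_sam(tmp_path, body), ANNOT)
        assert all(r.n_loci_hit == 1 for r in recs)

    def test_soft_clip_flags(self, tmp_path):
        path = _sam(tmp_path, _line("r1", 0, "locusA", 10, "45M5S", 50))
        (rec,) = ff.read_alignments(path, ANNOT)
        assert rec.read_length == 50
        assert rec.aligned_span == 45
        assert rec.is_clipped

    def test_unmapped_reads_dropped(self, tmp_path):
        path = _sam(tmp_path, _line("r1", 4, "*", 0, "*", 50))
        assert ff.read_alignments(path) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.sam"
        path.write_text(SAM_HEADER + "r1\t0\tlocusA\n")
        with pytest.raises(SamFormatError, match="line 4"):
            ff.read_alignments(path)

    def test_unknown_reference_is_hard_error(self, tmp_path):
        body = SAM_HEADER + "@SQ\tSN:ghost\tLN:100\n" + _line("r1", 0, "ghost", 1, "50M", 50)
        path = tmp_path / "ghost.sam"
        path.write_text(body)
        with pytest.raises(UnknownLocusError, match="ghost"):
            ff.read_alignments(path, ANNOT)

    def test_fixture_records_match_manifest(self, sam_fixture_on_disk):
        fixture, fasta, sam = sam_fixture_on_disk
        annotation = ff.read_annotation_fasta(fasta)
        records = ff.read_alignments(sam, annotation)
        by_read = {}
        for rec in records:
            by_read.setdefault(rec.read_id, []).append(rec)
        for entry in fixture.manifest["reads"]:
            recs = by_read[entry["read_id"]]
            assert len(recs) == len(entry["targets"])
            assert all(r.read_length == entry["read_length"] for r in recs)
            assert all(r.n_loci_hit == len(set(entry["targets"])) for r in recs)


class TestFilter:
    @pytest.mark.parametrize(
        "cigar,n_loci,kept",
        [
            ("50M", 1, True),
            ("45M5S", 1, False),  # not mapped in its entire length
            ("50M", 2, False),  # hits more than one locus
            ("20M1I29M", 1, False),  # insertion: not a complete match
            ("25M5D25M", 1, False),  # deletion: not a complete match
        ],
    )
    def test_full_single_locus_rule(self, tmp_path, cigar, n_loci, kept):
        body = _line("r1", 0, "locusA", 10, cigar, 50)
        if n_loci == 2:
            body += _line("r1", 256, "locusB", 5, cigar, 50)
        recs = ff.read_alignments(_sam(tmp_path, body), ANNOT)
        assert bool(ff.filter_full_single_locus(recs)) is kept

    def test_fixture_retains_three_of_six(self, sam_fixture_on_disk):
        fixture, fasta, sam = sam_fixture_on_disk
        records = ff.read_alignments(sam, ff.read_annotation_fasta(fasta))
        retained = ff.filter_full_single_locus(records)
        assert {r.read_id for r in retained} == {
            e["read_id"] for e in fixture.manifest["reads"] if e["retained"]
        }
        assert len({r.read_id for r in retained}) == 3

    def test_filter_is_idempotent(self, sam_fixture_on_disk):
        _, fasta, sam = sam_fixture_on_disk
        records = ff.read_alignments(sam, ff.read_annotation_fasta(fasta))
        once = ff.filter_full_single_locus(records)
        assert ff.filter_full_single_locus(once) == once


class TestCounting:
    def test_two_reads_give_hundred_bases(self, tmp_path):
        body = _line("r1", 0, "locusA", 10, "50M", 50) + _line("r2", 0, "locusA", 60, "50M", 50)
        recs = ff.read_alignments(_sam(tmp_path, body), ANNOT)
        table = ff.count_base_coverage(ff.filter_full_single_locus(recs), ANNOT)
        assert table.raw_bases["locusA"] == 100
        assert table.raw_bases["locusB"] == 0  # annotated but uncovered locus kept
        assert table.total_bases == 100

    def test_fixture_coverage_matches_manifest_exactly(self, sam_fixture_on_disk):
        fixture, fasta, sam = sam_fixture_on_disk
        annotation = ff.read_annotation_fasta(fasta)
        records = ff.read_alignments(sam, annotation)
        table = ff.count_base_coverage(ff.filter_full_single_locus(records), annotation)
        assert table.raw_bases.to_dict() == fixture.manifest["expected_raw_bases"]
        assert table.n_reads.to_dict() == fixture.manifest["expected_n_reads"]


def _table(raw: dict, lengths: dict) -> CoverageTable:
    frame = pd.DataFrame(
        {
            "raw_bases": pd.Series(raw, dtype=int),
            "n_reads": pd.Series(0, index=list(raw), dtype=int),
            "length": pd.Series(lengths, dtype=int),
        }
    )
    frame.index.name = "locus_tag"
    return CoverageTable(frame)


class TestNormalization:
    def test_worked_two_locus_example(self):
        table = _table({"a": 5000, "b": 5000}, {"a": 1000, "b": 500})
        norm = ff.normalize_coverage(table, 1e9)
        assert norm["a"] == pytest.approx(5.0e5)
        assert norm["b"] == pytest.approx(1.0e6)

    def test_single_locus_collapses_to_scale_over_length(self):
        table = _table({"a": 777}, {"a": 250})
        norm = ff.normalize_coverage(table, 1e9)
        assert norm["a"] == pytest.approx(1e9 / 250)

    def test_scale_invariance_under_doubling(self):
        t1 = _table({"a": 5000, "b": 3000}, {"a": 1000, "b": 500})
        t2 = _table({"a": 10000, "b": 6000}, {"a": 1000, "b": 500})
        assert np.allclose(ff.normalize_coverage(t1), ff.normalize_coverage(t2))

    def test_empty_experiment_is_hard_error(self):
        table = _table({"a": 0, "b": 0}, {"a": 100, "b": 100})
        with pytest.raises(ValueError, match="empty experiment"):
            ff.normalize_coverage(table)

    @given(
        st.lists(
            st.tuples(st.integers(0, 10**6), st.integers(1, 10**5)),
            min_size=1,
            max_size=20,
        ).filter(lambda rows: any(b > 0 for b, _ in rows))
    )
    def test_conservation_sum_norm_times_length(self, rows):
        raw = {f"g{i}": b for i, (b, _) in enumerate(rows)}
        lengths = {f"g{i}": ln for i, (_, ln) in enumerate(rows)}
        norm = ff.normalize_coverage(_table(raw, lengths), 1e9)
        total = float((norm * pd.Series(lengths)).sum())
        assert total == pytest.approx(1e9, rel=1e-9)


class TestExpressionVector:
    def test_log2_of_million(self):
        vec = ff.to_expression_vector(pd.Series({"a": 1.0e6, "b": 0.0}))
        assert vec.values["a"] == pytest.approx(19.9316, abs=1e-4)

    def test_zero_coverage_loci_excluded(self):
        vec = ff.to_expression_vector(pd.Series({"a": 4.0, "b": 0.0}))
        assert list(vec.values.index) == ["a"]

    def test_all_zero_gives_empty_vector(self):
        vec = ff.to_expression_vector(pd.Series({"a": 0.0, "b": 0.0}))
        assert vec.n_genes == 0

    def test_expression_table_roundtrip(self, tmp_path, sam_fixture_on_disk):
        fixture, fasta, sam = sam_fixture_on_disk
        annotation = ff.read_annotation_fasta(fasta)
        records = ff.read_alignments(sam, annotation)
        table = ff.count_base_coverage(ff.filter_full_single_locus(records), annotation)
        out = tmp_path / "expr.tsv"
        write_expression_table(out, table)
        vec = read_expression_tsv(out)
        norm = ff.normalize_coverage(table)
        expected = np.log2(norm[norm > 0])
        assert np.allclose(vec.values.sort_index(), expected.sort_index())


class TestRpkm:
    def test_standard_formula(self):
        rpkm = ff.compute_rpkm(pd.Series({"a": 100}), {"a": 1000}, total_reads=10**6)
        assert rpkm["a"] == pytest.approx(100.0)

    def test_zero_reads_zero_rpkm(self):
        rpkm = ff.compute_rpkm(pd.Series({"a": 0, "b": 10}), {"a": 500, "b": 500})
        assert rpkm["a"] == 0.0

    def test_zero_total_reads_is_error(self):
        with pytest.raises(ValueError, match="zero mapped reads"):
            ff.compute_rpkm(pd.Series({"a": 0}), {"a": 500})


class TestAnnotationLoaders:
    def test_tsv_with_and_without_header(self, tmp_path):
        p1 = tmp_path / "a.tsv"
        p1.write_text("locus_tag\tlength\ng1\t100\ng2\t250\n")
        p2 = tmp_path / "b.tsv"
        p2.write_text("g1\t100\ng2\t250\n")
        expected = {"g1": 100, "g2": 250}
        assert ff.read_annotation_tsv(p1) == expected
        assert ff.read_annotation_tsv(p2) == expected

    def test_duplicate_tag_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("g1\t100\ng1\t250\n")
        with pytest.raises(ValueError, match="duplicate"):
            ff.read_annotation_tsv(p)

    def test_fasta_lengths(self, tmp_path):
        p = tmp_path / "ref.fa"
        p.write_text(">g1\nACGTACGT\n>g2\nACG\n")
        assert ff.read_annotation_fasta(p) == {"g1": 8, "g2": 3}
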