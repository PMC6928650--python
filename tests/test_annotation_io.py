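"""Annotation readers/writers: format parsing, split-read merging, round trips."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from svadist.annotation_io import (
    ParseError,
    merge_split_elements,
    parse_pvalue_log10,
    read_elements,
    read_transcripts,
    read_zfp_table,
    write_elements_tsv,
    write_transcripts_tsv,
)
from svadist.core import GenomicInterval, Strand, SvaElement


class TestReadElementsBed:
    def test_single_bed_line(self, tmp_path):
        p = tmp_path / "one.bed"
        p.write_text("chr19\t23000000\t23002000\tSVA_D\t0\t+\n")
        elements, skipped = read_elements(p, format="bed6")
        assert skipped == 0
        (el,) = elements
        assert el.interval == GenomicInterval("chr19", 23_000_000, 23_002_000, Strand.PLUS)
        assert el.subfamily == "D"
        assert el.source == "reference"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        elements, skipped = read_elements(p, format="bed6")
        assert elements == [] and skipped == 0

    def test_unmappable_names_skipped_with_tally(self, tmp_path):
        # 50 records: 47 SVA labels cycling A..F1 and 3 other repeat classes
        subfams = ["SVA_A", "SVA_B", "SVA_C", "SVA_D", "SVA_E", "SVA_F", "SVA_F1"]
        lines = []
        for i in range(47):
            lines.append(f"chr1\t{i * 10000}\t{i * 10000 + 2000}\t{subfams[i % 7]}\t0\t+")
        for i, name in enumerate(["AluY", "L1HS", "HERVK"]):
            lines.append(f"chr2\t{i * 10000}\t{i * 10000 + 300}\t{name}\t0\t-")
        p = tmp_path / "mixed.bed"
        p.write_text("\n".join(lines) + "\n")
        elements, skipped = read_elements(p, format="bed6")
        assert len(elements) == 47
        assert skipped == 3

    def test_malformed_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\tSVA_A\t0\t+\nchr1\tnope\t400\tSVA_B\t0\t+\n")
        with pytest.raises(ParseError, match=":2"):
            read_elements(p, format="bed6")

    def test_inverted_span_is_validation_error(self, tmp_path):
        p = tmp_path / "inv.bed"
        p.write_text("chr1\t500\t400\tSVA_A\t0\t+\n")
        with pytest.raises(ParseError, match="0 <= start < end"):
            read_elements(p, format="bed6")


class TestReadElementsRepeatMasker:
    def test_ucsc_table_dump(self, tmp_path):
        p = tmp_path / "rmsk.tsv"
        p.write_text(
            "#genoName\tgenoStart\tgenoEnd\tstrand\trepName\tid\n"
            "chr19\t23000000\t23002000\t+\tSVA_D\t101\n"
            "chr19\t23100000\t23100500\t-\tAluY\t102\n"
        )
        elements, skipped = read_elements(p, format="repeatmasker_out")
        assert skipped == 1
        assert elements[0].interval.start == 23_000_000
        assert elements[0].raw_id == "101"

    def test_native_out_is_one_based(self, tmp_path):
        p = tmp_path / "native.out"
        p.write_text(
            "   SW   perc perc perc  query     position in query    matching repeat\n"
            "score   div. del. ins.  sequence  begin  end   (left)  repeat   class/family\n"
            "\n"
            "  463   11.5  0.1  0.2  chr19   23000001 23002000 (35000) + SVA_D Retroposon/SVA 1 2000 (0) 7\n"
        )
        elements, skipped = read_elements(p, format="repeatmasker_out")
        (el,) = elements
        # native .out begin is 1-based inclusive -> 0-based half-open
        assert (el.interval.start, el.interval.end) == (23_000_000, 23_002_000)
        assert el.raw_id == "7"


class TestMergeSplitElements:
    def test_single_element_unchanged(self):
        el = SvaElement(GenomicInterval("chr1", 100, 500), "D", raw_id="x")
        assert merge_split_elements([el]) == [el]

    def test_shared_raw_id_merges_across_gap(self):
        a = SvaElement(GenomicInterval("chr1", 100, 500), "D", raw_id="42")
        b = SvaElement(GenomicInterval("chr1", 900, 1400), "D", raw_id="42")
        (merged,) = merge_split_elements([a, b])
        assert (merged.interval.start, merged.interval.end) == (100, 1400)
        assert merged.raw_id == "42"

    def test_anonymous_overlap_merges(self):
        a = SvaElement(GenomicInterval("chr1", 100, 500), "D")
        b = SvaElement(GenomicInterval("chr1", 400, 800), "D")
        (merged,) = merge_split_elements([a, b])
        assert (merged.interval.start, merged.interval.end) == (100, 800)

    def test_different_subfamilies_never_merge(self):
        a = SvaElement(GenomicInterval("chr1", 100, 500), "D")
        b = SvaElement(GenomicInterval("chr1", 400, 800), "E")
        assert len(merge_split_elements([a, b])) == 2

    def test_distinct_raw_ids_never_proximity_merge(self):
        a = SvaElement(GenomicInterval("chr1", 100, 500), "D", raw_id="1")
        b = SvaElement(GenomicInterval("chr1", 400, 800), "D", raw_id="2")
        assert len(merge_split_elements([a, b])) == 2

    def test_gap_beyond_max_gap_keeps_separate(self):
        a = SvaElement(GenomicInterval("chr1", 100, 500), "D")
        b = SvaElement(GenomicInterval("chr1", 6000, 6400), "D")
        assert len(merge_split_elements([a, b], max_gap=5000)) == 2
        assert len(merge_split_elements([a, b], max_gap=6000)) == 1

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=50_000),
                st.integers(min_value=1, max_value=5_000),
                st.sampled_from(["D", "E"]),
                st.sampled_from(["", "id1", "id2"]),
            ),
            max_size=15,
        )
    )
    def test_idempotent_and_coverage_preserving(self, rows):
        elements = [
            SvaElement(GenomicInterval("chr1", s, s + w), f, raw_id=r)
            for s, w, f, r in rows
        ]
        once = merge_split_elements(elements)
        twice = merge_split_elements(once)
        assert once == twice
        assert len(once) <= len(elements)

        def covered(els):
            pts = set()
            for e in els:
                pts.update(range(e.interval.start, e.interval.end))
            return pts

        assert covered(elements) <= covered(once)


class TestTranscripts:
    def test_flat_tsv(self, tmp_path):
        p = tmp_path / "tx.tsv"
        p.write_text(
            "chrom\tstart\tend\tstrand\ttranscript_id\tgene_id\tgene_symbol\n"
            "chr19\t100\t5000\t+\tt1\tg1\tZNF91\n"
            "chr19\t200\t6000\t-\tt2\tg1\tZNF91\n"
            "chr19\t9000\t12000\t+\tt3\tg2\tGAK\n"
        )
        txs = read_transcripts(p, format="tsv")
        assert len(txs) == 3
        assert txs[0].interval == GenomicInterval("chr19", 100, 5000, Strand.PLUS)
        assert len({t.gene_id for t in txs}) == 2

    def test_bed12_span_ignores_blocks(self, tmp_path):
        p = tmp_path / "tx.bed"
        p.write_text(
            "chr1\t1000\t9000\ttxA\t0\t+\t1200\t8800\t0\t2\t100,200\t0,7800\n"
        )
        (t,) = read_transcripts(p, format="bed12")
        assert (t.interval.start, t.interval.end) == (1000, 9000)
        assert t.gene_id == "txA"

    def test_duplicate_transcript_ids_listed(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "chrom\tstart\tend\ttranscript_id\tgene_id\n"
            "chr1\t1\t10\tt1\tg1\nchr1\t5\t20\tt1\tg1\n"
        )
        with pytest.raises(ParseError, match="t1"):
            read_transcripts(p, format="tsv")

    def test_missing_symbol_falls_back_to_gene_id(self, tmp_path):
        p = tmp_path / "tx.tsv"
        p.write_text("chrom\tstart\tend\ttranscript_id\tgene_id\nchr1\t1\t10\tt1\tg1\n")
        (t,) = read_transcripts(p, format="tsv")
        assert t.symbol == "g1"


class TestPvalueParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("4.53 × 10^−89", math.log10(4.53) - 89),  # approx -88.34
            ("4.53e-89", math.log10(4.53) - 89),
            ("1.00", 0.0),
            ("0.13", math.log10(0.13)),
            ("1.14 × 10^−320", math.log10(1.14) - 320),  # approx -319.94, not -inf
        ],
    )
    def test_log10_extraction(self, text, expected):
        got = parse_pvalue_log10(text)
        assert got == pytest.approx(expected, abs=1e-9)
        assert math.isfinite(got)

    def test_sub_underflow_value_not_zero_or_inf(self):
        v = parse_pvalue_log10("1.14 × 10^−320")
        assert v == pytest.approx(-319.94, abs=0.01)

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_pvalue_log10("n/a")
        with pytest.raises(ValueError):
            parse_pvalue_log10("2.0")


class TestZfpTable:
    def test_missing_pvalue_column_is_format_error(self, tmp_path):
        p = tmp_path / "zfp.tsv"
        p.write_text(
            "protein\tposition\tsva_a\tsva_b\tsva_c\tsva_d\tsva_e\n"
            "ZNF1\tchr1:100-200\t1.0\t1.0\t1.0\t1.0\t1.0\n"
        )
        with pytest.raises(ParseError, match="sva_f"):
            read_zfp_table(p)

    def test_position_with_thousands_separators(self, tmp_path):
        p = tmp_path / "zfp.tsv"
        p.write_text(
            "protein\tposition\tsva_a\tsva_b\tsva_c\tsva_d\tsva_e\tsva_f\n"
            "ZNF141\tchr4:331,596-367,691\t7.76e-6\t4.53e-89\t1.04e-62\t5.07e-5\t0.13\t0.40\n"
        )
        (rec,) = read_zfp_table(p)
        assert (rec.interval.start, rec.interval.end) == (331_595, 367_691)
        assert rec.log10_pvalues["B"] == pytest.approx(math.log10(4.53) - 89)


class TestRoundTrips:
    def test_element_tsv_round_trip(self, tmp_path):
        elements = [
            SvaElement(GenomicInterval("chr1", 100, 2100, Strand.PLUS), "D", raw_id="a"),
            SvaElement(GenomicInterval("chr2", 5, 2005, Strand.MINUS), "F1", source="rip"),
        ]
        p = tmp_path / "els.tsv"
        write_elements_tsv(elements, p)
        back, skipped = read_elements(p, format="tsv")
        assert skipped == 0
        assert back == elements

    def test_transcript_tsv_round_trip(self, tmp_path):
        from conftest import make_transcript

        txs = [
            make_transcript("chr1", 10, 500, "t1", "g1", "ZNF91"),
            make_transcript("chr1", 600, 900, "t2", "g1", "ZNF91", strand=Strand.MINUS),
        ]
        p = tmp_path / "tx.tsv"
        write_transcripts_tsv(txs, p)
        assert read_transcripts(p, format="tsv") == txs
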