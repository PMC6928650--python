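"""Locus characterisation, subfamily composition fold changes, proximity."""

import math

import pytest

from conftest import make_element, make_transcript
from svadist.core import GenomicInterval, Strand, SvaElement
from svadist.locus import (
    ZnfPatterns,
    annotate_proximity,
    classify_znf,
    composition_fold_change,
    fold_change_from_counts,
    fold_change_from_shares,
    summarize_locus,
)
from svadist.resources import load_genome_subfamily_shares, load_znf_loci_subfamily_counts


class TestClassifyZnf:
    @pytest.mark.parametrize(
        "symbol,expected",
        [("ZNF91", True), ("GAK", False), ("ZKSCAN5", True), ("znf611", True),
         ("ZSCAN22", True), ("ZIK1", True), ("ZFP28", True), ("DGKQ", False),
         ("TAF1", False)],
    )
    def test_default_patterns(self, symbol, expected):
        assert classify_znf(symbol) is expected

    def test_exclude_overrides_include(self):
        patterns = ZnfPatterns(exclude=(r"^ZNF91$",))
        assert classify_znf("ZNF91", patterns) is False
        assert classify_znf("ZNF92", patterns) is True


class TestSummarizeLocus:
    def test_synthetic_fixture_counts(self):
        """3 genes (2 zinc-finger), 6 transcripts, 2 SVAs in one megabase."""
        iv = GenomicInterval("chr19", 0, 1_000_000)
        txs = []
        genes = [("g1", "ZNF10"), ("g2", "ZKSCAN3"), ("g3", "GAK")]
        k = 0
        for gid, sym in genes:
            for _ in range(2):
                txs.append(make_transcript("chr19", 1000 * (k + 1), 1000 * (k + 1) + 500,
                                           f"t{k}", gid, sym))
                k += 1
        elements = [make_element("chr19", 50_000, "D"), make_element("chr19", 60_000, "E")]
        s = summarize_locus(iv, txs, elements)
        assert (s.n_genes, s.n_transcripts, s.n_znf_genes) == (3, 6, 2)
        assert s.pct_znf == 66.67
        assert s.transcripts_per_sva == 3.00
        assert s.genes_per_sva == 1.50
        assert s.n_krab_znf is None

    def test_krab_count_with_supplied_list(self):
        iv = GenomicInterval("chr19", 0, 1_000_000)
        txs = [make_transcript("chr19", 1000, 2000, "t1", "g1", "ZNF91"),
               make_transcript("chr19", 3000, 4000, "t2", "g2", "ZNF92")]
        s = summarize_locus(iv, txs, [], krab_list=["ZNF91"])
        assert s.n_krab_znf == 1

    def test_empty_region_has_undefined_ratios(self):
        s = summarize_locus(GenomicInterval("chr1", 0, 1_000_000), [], [])
        assert s.n_genes == 0 and s.n_sva_total == 0
        assert math.isnan(s.pct_znf)
        assert math.isnan(s.transcripts_per_sva)

    def test_membership_by_start_rule(self):
        iv = GenomicInterval("chr1", 1_000_000, 2_000_000)
        inside = make_transcript("chr1", 1_999_999, 2_500_000, "t1", "g1", "ZNF1")
        outside = make_transcript("chr1", 999_000, 1_500_000, "t2", "g2", "ZNF2")
        s = summarize_locus(iv, [inside, outside], [])
        assert s.n_transcripts == 1 and s.n_genes == 1

    def test_additive_over_disjoint_intervals(self):
        txs = [make_transcript("chr1", 100, 200, f"t{i}", f"g{i}") for i in range(4)]
        txs += [make_transcript("chr1", 1_000_100, 1_000_200, f"u{i}", f"h{i}") for i in range(3)]
        els = [make_element("chr1", 500, "D"), make_element("chr1", 1_000_500, "E")]
        a = summarize_locus(GenomicInterval("chr1", 0, 1_000_000), txs, els)
        b = summarize_locus(GenomicInterval("chr1", 1_000_000, 2_000_000), txs, els)
        union = summarize_locus(GenomicInterval("chr1", 0, 2_000_000), txs, els)
        assert union.n_transcripts == a.n_transcripts + b.n_transcripts
        assert union.n_genes == a.n_genes + b.n_genes
        assert union.n_sva_total == a.n_sva_total + b.n_sva_total


class TestCompositionFoldChange:
    def test_published_locus_counts_reproduce_printed_folds(self):
        """Pooled counts at the three 1 Mb zinc-finger loci vs hg19 shares."""
        loci = load_znf_loci_subfamily_counts()
        pooled: dict[str, int] = {}
        for counts in loci.values():
            for s, n in counts.items():
                pooled[s] = pooled.get(s, 0) + n
        pooled = {s: pooled.get(s, 0) for s in ("A", "B", "C", "D", "E", "F", "F1")}
        assert sum(pooled.values()) == 25
        comp = fold_change_from_shares(pooled, load_genome_subfamily_shares())
        assert comp.fold_change["B"] == 0.24
        assert comp.fold_change["A"] == 0.51
        assert comp.fold_change["D"] == 1.08
        assert comp.fold_change["F"] == 0.89
        assert comp.fold_change["E"] == 4.86
        assert comp.fold_change["old"] == 0.46
        assert comp.locus_share["old"] == 16.00
        # F1 absent from these loci: defined convention is fold 0.00
        assert comp.fold_change["F1"] == 0.00

    def test_identity_composition_gives_unit_folds(self):
        elements = [make_element("chr1", i * 10_000, s)
                    for i, s in enumerate(["A", "A", "D", "D", "D", "E", "F1"])]
        comp = composition_fold_change(elements, elements)
        for s in ("A", "D", "E", "F1", "old", "young"):
            assert comp.fold_change[s] == 1.00

    def test_shares_sum_to_100(self):
        elements = [make_element("chr1", i * 10_000, s)
                    for i, s in enumerate(["A", "B", "C", "D", "E", "F", "F1", "D", "D"])]
        comp = composition_fold_change(elements[:4], elements)
        subfam = ("A", "B", "C", "D", "E", "F", "F1")
        assert sum(comp.genome_share[s] for s in subfam) == pytest.approx(100.0, abs=0.05)
        assert sum(comp.locus_share[s] for s in subfam) == pytest.approx(100.0, abs=0.05)

    def test_empty_genome_set_errors(self):
        with pytest.raises(ValueError):
            composition_fold_change([make_element("chr1", 0, "A")], [])

    def test_absent_subfamily_conventions(self):
        comp = fold_change_from_counts({"A": 1, "D": 1, "E": 1}, {"A": 5, "D": 5})
        # absent from the genome set -> undefined sentinel
        assert math.isnan(comp.fold_change["E"])
        # present in genome, absent from locus -> 0.00
        comp2 = fold_change_from_counts({"A": 1}, {"A": 5, "D": 5})
        assert comp2.fold_change["D"] == 0.00


class TestProximity:
    def test_element_inside_transcript(self):
        txs = [make_transcript("chr1", 10_000, 50_000, "t1", "g1")]
        els = [make_element("chr1", 20_000, "D")]
        (ann,), frac = annotate_proximity(els, txs)
        assert ann.relation == "within_gene"
        assert ann.distance_bp == 0
        assert ann.nearest_gene == "g1"
        assert frac == 1.0

    def test_upstream_of_plus_strand_within_window(self):
        txs = [make_transcript("chr1", 100_000, 150_000, "t1", "g1")]
        els = [SvaElement(GenomicInterval("chr1", 93_000, 95_000), "D")]
        (ann,), frac = annotate_proximity(els, txs, upstream_window=10_000)
        assert ann.relation == "upstream"
        assert ann.distance_bp == 5_000
        assert frac == 1.0

    def test_downstream_not_counted_in_genic_fraction(self):
        txs = [make_transcript("chr1", 100_000, 150_000, "t1", "g1")]
        els = [SvaElement(GenomicInterval("chr1", 153_000, 155_000), "D")]
        (ann,), frac = annotate_proximity(els, txs, upstream_window=10_000)
        assert ann.relation == "downstream"
        assert ann.distance_bp == 3_000
        assert frac == 0.0

    def test_minus_strand_flips_orientation(self):
        txs = [make_transcript("chr1", 100_000, 150_000, "t1", "g1", strand=Strand.MINUS)]
        before = [SvaElement(GenomicInterval("chr1", 93_000, 95_000), "D")]
        after = [SvaElement(GenomicInterval("chr1", 153_000, 155_000), "D")]
        (ann_b,), _ = annotate_proximity(before, txs)
        (ann_a,), _ = annotate_proximity(after, txs)
        assert ann_b.relation == "downstream"
        assert ann_a.relation == "upstream"

    def test_far_element_is_intergenic(self):
        txs = [make_transcript("chr1", 100_000, 150_000, "t1", "g1")]
        els = [SvaElement(GenomicInterval("chr1", 200_000, 202_000), "D")]
        (ann,), frac = annotate_proximity(els, txs, upstream_window=10_000)
        assert ann.relation == "intergenic"
        assert frac == 0.0

    def test_genic_fraction_monotone_in_upstream_window(self):
        txs = [make_transcript("chr1", 100_000, 150_000, "t1", "g1"),
               make_transcript("chr1", 400_000, 420_000, "t2", "g2", strand=Strand.MINUS)]
        els = [
            make_element("chr1", 110_000, "D"),            # within
            SvaElement(GenomicInterval("chr1", 97_000, 99_000), "E"),   # 1 kb upstream t1
            SvaElement(GenomicInterval("chr1", 85_000, 87_000), "F"),   # 13 kb upstream t1
            SvaElement(GenomicInterval("chr1", 425_000, 427_000), "D"), # 5 kb upstream t2 (-)
            SvaElement(GenomicInterval("chr1", 700_000, 702_000), "A"), # far
        ]
        fracs = [annotate_proximity(els, txs, upstream_window=w)[1]
                 for w in (0, 2_000, 6_000, 15_000, 300_000)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] == pytest.approx(1 / 5)
        assert fracs[2] == pytest.approx(3 / 5)
        assert fracs[3] == pytest.approx(4 / 5)

    def test_unknown_strand_gives_unoriented_relation(self):
        txs = [make_transcript("chr1", 100_000, 150_000, "t1", "g1", strand=Strand.UNKNOWN)]
        els = [SvaElement(GenomicInterval("chr1", 93_000, 95_000), "D")]
        (ann,), _ = annotate_proximity(els, txs)
        assert ann.relation == "intergenic_unoriented"
        assert ann.distance_bp == 5_000
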