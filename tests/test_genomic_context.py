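import numpy as np
import pytest

from crown_ocr.genome_model import GenomicInterval, promoter_gene_interval
from crown_ocr.genomic_context import (
    OcrGeneHit,
    build_profiles,
    classify_location,
    coverage_pct,
    gene_class,
    intersect_ocrs_genes,
    tss_relative_positions,
)
from crown_ocr.ocr_construction import OCR, OCRSet

from conftest import CHROM_LEN, make_annotation, make_gene
from _oracles import bitmap_coverage_pct, brute_intersect


def ocr(chrom, start, end, ocr_id="OCR_1", support=1):
    return OCR(GenomicInterval(chrom, start, end), support=support, sources=frozenset(), id=ocr_id)


def ocr_set(*triples):
    return OCRSet([ocr(c, s, e, f"OCR_{i}") for i, (c, s, e) in enumerate(triples, 1)])


PLUS = make_gene("gp", start=10_000, end=12_000, strand="+")   # TSS 10000
MINUS = make_gene("gm", start=10_000, end=12_000, strand="-")  # TSS 11999


class TestClassifyLocation:
    @pytest.mark.parametrize(
        "interval,expected",
        [((9_800, 10_400), "over_TSS"),   # covers the TSS base
         ((6_000, 7_000), "promoter"),    # wholly upstream
         ((10_500, 11_000), "gene_body"), # wholly downstream of TSS
         ((10_001, 12_500), "gene_body")],
    )
    def test_plus_strand(self, interval, expected):
        assert classify_location(GenomicInterval("chr1H", *interval), PLUS, CHROM_LEN) == expected

    @pytest.mark.parametrize(
        "interval,expected",
        [((11_800, 12_300), "over_TSS"),
         ((12_500, 13_000), "promoter"),   # upstream = higher coordinates
         ((10_500, 11_000), "gene_body")],
    )
    def test_minus_strand_mirrored(self, interval, expected):
        assert classify_location(GenomicInterval("chr1H", *interval), MINUS, CHROM_LEN) == expected

    def test_non_overlapping_ocr_rejected(self):
        with pytest.raises(ValueError, match="does not overlap"):
            classify_location(GenomicInterval("chr1H", 20_000, 21_000), PLUS, CHROM_LEN)


class TestGeneClass:
    def _hit(self, cls):
        return OcrGeneHit("o", "g", cls, -100, 100, 10)

    @pytest.mark.parametrize(
        "classes,expected",
        [(("promoter", "over_TSS"), "over_TSS"),
         (("gene_body",), "gene_body"),
         (("promoter", "gene_body"), "promoter"),
         (("gene_body", "over_TSS", "promoter"), "over_TSS")],
    )
    def test_precedence(self, classes, expected):
        assert gene_class([self._hit(c) for c in classes]) == expected

    def test_no_hits_rejected(self):
        with pytest.raises(ValueError):
            gene_class([])


class TestIntersect:
    def test_single_hit_with_overlap_len(self):
        ann = make_annotation([PLUS])
        hits = intersect_ocrs_genes(ocr_set(("chr1H", 6_000, 7_000)), ann)
        assert len(hits) == 1
        assert hits[0].gene_id == "gp" and hits[0].overlap_len == 1_000

    def test_ocr_outside_window_no_hit(self):
        ann = make_annotation([PLUS])
        assert intersect_ocrs_genes(ocr_set(("chr1H", 20_000, 21_000)), ann) == []

    def test_matches_all_pairs_oracle_on_random_fixture(self, rng):
        genes = []
        for i in range(30):
            start = int(rng.integers(6_000, CHROM_LEN - 20_000))
            genes.append(
                make_gene(f"g{i}", start=start, end=start + int(rng.integers(500, 5_000)),
                          strand="+" if rng.random() < 0.5 else "-")
            )
        ann = make_annotation(genes)
        triples = []
        for _ in range(80):
            s = int(rng.integers(0, CHROM_LEN - 2_000))
            triples.append(("chr1H", s, s + int(rng.integers(100, 2_000))))
        oset = ocr_set(*triples)
        got = {(h.ocr_id, h.gene_id) for h in intersect_ocrs_genes(oset, ann)}
        windows = [
            (g.id, ("chr1H", promoter_gene_interval(g, CHROM_LEN).start,
                    promoter_gene_interval(g, CHROM_LEN).end))
            for g in genes
        ]
        ocr_tuples = [(o.id, (o.interval.chrom, o.interval.start, o.interval.end)) for o in oset]
        assert got == brute_intersect(ocr_tuples, windows)


class TestCoverage:
    def test_simple_fraction(self):
        # promoter-gene interval [5000,13000) = 8000 nt; OCR covers 2000 of it
        assert coverage_pct(PLUS, ocr_set(("chr1H", 5_000, 7_000)), CHROM_LEN) == 25.0

    def test_no_overlap_zero(self):
        assert coverage_pct(PLUS, ocr_set(("chr1H", 100_000, 101_000)), CHROM_LEN) == 0.0

    def test_overlapping_inputs_union_counted_once(self, rng):
        triples = []
        for _ in range(15):
            s = int(rng.integers(4_000, 14_000))
            triples.append(("chr1H", s, s + int(rng.integers(50, 1_500))))
        oset = ocr_set(*triples)
        got = coverage_pct(PLUS, oset, CHROM_LEN)
        expected = bitmap_coverage_pct((5_000, 13_000), [(s, e) for _, s, e in triples])
        assert got == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_ocr_splitting(self):
        split = ocr_set(("chr1H", 6_000, 6_500), ("chr1H", 6_500, 7_000))
        merged = ocr_set(("chr1H", 6_000, 7_000))
        assert coverage_pct(PLUS, split, CHROM_LEN) == coverage_pct(PLUS, merged, CHROM_LEN)


class TestTssOffsets:
    def test_plus_strand_offsets(self):
        ann = make_annotation([PLUS])
        hits = intersect_ocrs_genes(ocr_set(("chr1H", 9_800, 10_400)), ann)
        assert (hits[0].tss_offset_start, hits[0].tss_offset_end) == (-200, 400)

    def test_minus_strand_transcription_direction(self):
        ann = make_annotation([MINUS])
        hits = intersect_ocrs_genes(ocr_set(("chr1H", 11_800, 12_300)), ann)
        assert hits[0].tss_offset_start == -300

    def test_ocr_starting_at_tss_offset_zero(self):
        ann = make_annotation([PLUS])
        hits = intersect_ocrs_genes(ocr_set(("chr1H", 10_000, 10_300)), ann)
        assert hits[0].tss_offset_start == 0

    def test_table_shape(self):
        ann = make_annotation([PLUS, make_gene("g2", start=50_000, end=52_000)])
        hits = intersect_ocrs_genes(ocr_set(("chr1H", 9_900, 10_100), ("chr1H", 49_000, 49_500)), ann)
        df = tss_relative_positions(hits)
        assert list(df.columns) == ["ocr_id", "gene_id", "tss_offset_start", "tss_offset_end"]
        assert len(df) == 2


class TestProfilesPartition:
    def test_each_accessible_gene_gets_exactly_one_class(self, small_study):
        from crown_ocr.ocr_construction import merge_peaks

        all_set = merge_peaks(small_study["peaks"])
        profiles = build_profiles(all_set, small_study["annotation"])
        acc = profiles[profiles["accessible"]]
        assert acc["gene_class"].isin(["promoter", "over_TSS", "gene_body"]).all()
        assert profiles.loc[~profiles["accessible"], "gene_class"].isna().all()
        counts = acc["gene_class"].value_counts()
        assert counts.sum() == len(acc)

    def test_strand_symmetry_of_promoter_hits(self):
        """Reflecting gene and OCR about the chromosome midpoint preserves the class."""
        for cls_interval in [(6_000, 7_000), (9_800, 10_400), (10_500, 11_000)]:
            fwd = classify_location(GenomicInterval("chr1H", *cls_interval), PLUS, CHROM_LEN)
            lo, hi = CHROM_LEN - cls_interval[1], CHROM_LEN - cls_interval[0]
            mirrored_gene = make_gene(
                "gm2", start=CHROM_LEN - 12_000, end=CHROM_LEN - 10_000, strand="-"
            )
            rev = classify_location(GenomicInterval("chr1H", lo, hi), mirrored_gene, CHROM_LEN)
            assert fwd == rev
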