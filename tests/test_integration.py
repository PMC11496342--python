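import numpy as np
import pandas as pd
import pytest

from crown_ocr.genome_model import GenomicInterval
from crown_ocr.genomic_context import build_profiles, intersect_ocrs_genes
from crown_ocr.integration import (
    accessibility_change,
    accessible_genes,
    change_expression_crosstab,
    change_summary,
    expression_by_coverage,
)
from crown_ocr.ocr_construction import OCR, OCRSet, merge_peaks

from conftest import CHROM_LEN, make_annotation, make_gene
from _oracles import exact_fisher_two_sided


def ocr_set(*triples):
    return OCRSet(
        [OCR(GenomicInterval(c, s, e), support=1, sources=frozenset(), id=f"OCR_{i}")
         for i, (c, s, e) in enumerate(triples, 1)]
    )


def de_frame(rows):
    """rows: (gene_id, log2fc, is_deg)"""
    return pd.DataFrame(
        {
            "gene_id": [r[0] for r in rows],
            "base_mean": 10.0,
            "log2fc": [r[1] for r in rows],
            "p": 0.01,
            "padj": 0.01,
            "is_deg": [r[2] for r in rows],
        }
    )


class TestAccessibleGenes:
    def test_single_overlap_counted(self):
        ann = make_annotation([make_gene("g1")])
        assert accessible_genes(ocr_set(("chr1H", 6_000, 7_000)), ann) == {"g1": 1}

    def test_ocr_outside_all_windows_empty(self):
        ann = make_annotation([make_gene("g1")])
        assert accessible_genes(ocr_set(("chr1H", 100_000, 101_000)), ann) == {}

    def test_multiple_ocrs_counted(self):
        ann = make_annotation([make_gene("g1")])
        got = accessible_genes(ocr_set(("chr1H", 6_000, 7_000), ("chr1H", 11_000, 11_500)), ann)
        assert got == {"g1": 2}

    def test_agrees_with_interval_tree_route(self, small_study):
        """Binary-search counting must match intersect_ocrs_genes grouped by gene."""
        all_set = merge_peaks(small_study["peaks"])
        ann = small_study["annotation"]
        got = accessible_genes(all_set, ann)
        hits = intersect_ocrs_genes(all_set, ann)
        expected = {}
        for h in hits:
            expected[h.gene_id] = expected.get(h.gene_id, 0) + 1
        assert got == expected


class TestAccessibilityChange:
    def test_lose_gain_stable(self):
        changes = accessibility_change(
            {"a": 2, "c": 1, "d": 1}, {"b": 1, "c": 3}, ["a", "b", "c", "d", "e"]
        )
        by_gene = {c.gene_id: c.change for c in changes}
        assert by_gene == {
            "a": "lose", "b": "gain", "c": "stable_accessible",
            "d": "lose", "e": "stable_inaccessible",
        }

    def test_partition_totals(self, rng):
        genes = [f"g{i}" for i in range(300)]
        a = {g: 1 for g in genes if rng.random() < 0.4}
        b = {g: 1 for g in genes if rng.random() < 0.4}
        summary = change_summary(accessibility_change(a, b, genes))
        assert sum(summary.values()) == len(genes)

    def test_swapping_variants_swaps_lose_and_gain(self, rng):
        genes = [f"g{i}" for i in range(300)]
        a = {g: int(rng.integers(1, 4)) for g in genes if rng.random() < 0.4}
        b = {g: int(rng.integers(1, 4)) for g in genes if rng.random() < 0.4}
        fwd = change_summary(accessibility_change(a, b, genes))
        rev = change_summary(accessibility_change(b, a, genes))
        assert fwd["lose"] == rev["gain"] and fwd["gain"] == rev["lose"]
        assert fwd["stable_accessible"] == rev["stable_accessible"]


class TestCrossTab:
    def _changes(self, lose_ids, other_ids):
        return accessibility_change(
            {g: 1 for g in lose_ids + other_ids}, {g: 1 for g in other_ids},
            lose_ids + other_ids,
        )

    def test_or_nine_and_exact_p(self):
        # lose: 3 down + 1 up; not-lose: 1 down + 3 up
        lose = [f"l{i}" for i in range(4)]
        other = [f"o{i}" for i in range(4)]
        changes = self._changes(lose, other)
        de = de_frame(
            [(g, -3.0, True) for g in lose[:3]] + [(lose[3], 3.0, True)]
            + [(other[0], -3.0, True)] + [(g, 3.0, True) for g in other[1:]]
        )
        lose_tab, _ = change_expression_crosstab(changes, de)
        assert lose_tab.table.tolist() == [[3, 1], [1, 3]]
        assert lose_tab.odds_ratio == pytest.approx(9.0)
        assert lose_tab.p_value == pytest.approx(float(exact_fisher_two_sided([[3, 1], [1, 3]])))

    def test_balanced_table_or_one(self):
        lose = [f"l{i}" for i in range(10)]
        other = [f"o{i}" for i in range(10)]
        changes = self._changes(lose, other)
        de = de_frame(
            [(g, -3.0, True) for g in lose[:5]] + [(g, 3.0, True) for g in lose[5:]]
            + [(g, -3.0, True) for g in other[:5]] + [(g, 3.0, True) for g in other[5:]]
        )
        lose_tab, _ = change_expression_crosstab(changes, de)
        assert lose_tab.table.tolist() == [[5, 5], [5, 5]]
        assert lose_tab.odds_ratio == pytest.approx(1.0)

    def test_zero_degs_warns_without_test(self):
        changes = self._changes(["l1"], ["o1"])
        de = de_frame([("l1", -3.0, False), ("o1", 3.0, False)])
        with pytest.warns(UserWarning, match="no DEGs"):
            lose_tab, _ = change_expression_crosstab(changes, de)
        assert lose_tab.p_value is None

    def test_requires_is_deg_column(self):
        changes = self._changes(["l1"], ["o1"])
        with pytest.raises(ValueError, match="is_deg"):
            change_expression_crosstab(changes, de_frame([]).drop(columns=["is_deg"]))


class TestExpressedVsAccessible:
    def test_accessible_genes_more_often_expressed_under_positive_coupling(self):
        """With planted accessibility->expression coupling and a low expression
        baseline, the expressed fraction is higher among accessible genes."""
        import pandas as pd
        from crown_ocr.expression import ExpressionMatrix, expressed_flags, fpkm
        from crown_ocr.synthetic_data import (
            StudyConfig, simulate_annotation, simulate_counts, simulate_truth)

        cfg = StudyConfig(n_genes=600, n_chroms=1, chrom_len=15_000_000,
                          base_meanlog=-1.0, base_sdlog=1.0,
                          accessibility_meanlog_shift=2.5, seed=17)
        ann = simulate_annotation(cfg)
        truth = simulate_truth(cfg, ann)
        counts = simulate_counts(cfg, truth)
        design = pd.DataFrame(
            [{"sample_id": l.sample_id, "genotype": l.genotype, "time": l.time,
              "temperature": l.temperature, "replicate": l.replicate, "assay": l.assay}
             for l in cfg.rna_labels()]
        )
        lengths = pd.Series({g.id: g.span.length for g in ann.genes}).reindex(counts.index)
        expressed = expressed_flags(fpkm(ExpressionMatrix(counts, lengths, design)))
        ever_accessible = (truth.genes["accessible_C"] | truth.genes["gains_HT"]).to_numpy()
        frac_acc = expressed.to_numpy()[ever_accessible].mean()
        frac_inacc = expressed.to_numpy()[~ever_accessible].mean()
        assert frac_inacc < 1.0  # the contrast is informative, not vacuous
        assert frac_acc > frac_inacc


class TestExpressionByCoverage:
    def _profiles(self, coverages, classes=None):
        n = len(coverages)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "accessible": [c > 0 for c in coverages],
                "gene_class": classes or ["over_TSS" if c > 0 else None for c in coverages],
                "coverage_pct": coverages,
                "n_ocrs": [1 if c > 0 else 0 for c in coverages],
            }
        )

    def test_positive_trend(self):
        profiles = self._profiles([5.0] * 10 + [55.0] * 10)
        fpkm_mean = pd.Series([1.0] * 10 + [5.0] * 10, index=[f"g{i}" for i in range(20)])
        _, _, trend = expression_by_coverage(profiles, fpkm_mean)
        assert trend > 0

    def test_constant_fpkm_zero_trend(self):
        profiles = self._profiles([5.0] * 10 + [55.0] * 10)
        fpkm_mean = pd.Series(2.0, index=[f"g{i}" for i in range(20)])
        _, _, trend = expression_by_coverage(profiles, fpkm_mean)
        assert trend == 0.0

    def test_per_class_table(self):
        profiles = self._profiles(
            [10.0, 20.0, 0.0], classes=["promoter", "over_TSS", None]
        )
        fpkm_mean = pd.Series([1.0, 8.0, 0.1], index=["g0", "g1", "g2"])
        _, per_class, _ = expression_by_coverage(profiles, fpkm_mean)
        got = dict(zip(per_class["gene_class"], per_class["median_fpkm"]))
        assert got == {"promoter": 1.0, "over_TSS": 8.0}
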