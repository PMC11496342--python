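import numpy as np
import pytest

from crown_ocr.genome_model import GeneModel, GenomeAnnotation, GenomicInterval
from crown_ocr.io_formats import PeakSet, SampleLabel
from crown_ocr.synthetic_data import (
    StudyConfig,
    simulate_annotation,
    simulate_counts,
    simulate_peaks,
    simulate_truth,
)

CHROM_LEN = 1_000_000


def make_gene(gene_id="g1", chrom="chr1H", start=10_000, end=12_000, strand="+"):
    return GeneModel(id=gene_id, span=GenomicInterval(chrom, start, end), strand=strand)


def make_annotation(genes, chrom_len=CHROM_LEN):
    sizes = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), chrom_len)
    return GenomeAnnotation(genes=list(genes), chrom_sizes=sizes)


def make_peakset(intervals, genotype="Bn", time="1d", temperature="C", replicate=1):
    label = SampleLabel(genotype, time, temperature, replicate, "ATAC")
    return PeakSet(label=label, peaks=[GenomicInterval(c, s, e) for c, s, e in intervals])


@pytest.fixture(scope="session")
def small_config():
    return StudyConfig(n_genes=200, n_chroms=2, chrom_len=3_000_000, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    """An in-memory synthetic study shared across tests (read-only)."""
    annotation = simulate_annotation(small_config)
    truth = simulate_truth(small_config, annotation)
    peaks = simulate_peaks(small_config, annotation, truth)
    counts = simulate_counts(small_config, truth)
    return {
        "config": small_config,
        "annotation": annotation,
        "truth": truth,
        "peaks": peaks,
        "counts": counts,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
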