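"""Synthetic factorial ATAC + RNA study generator with known ground truth.

Emulates the study design this pipeline targets: 3 genotypes x 2 time points
x 2 temperature regimes, with 2 ATAC-seq and 3 RNA-seq replicates (24 peak
files, 36 count columns).  Per gene the generator draws a true accessibility
state, an OCR placement (promoter / over TSS / gene body), temperature-driven
accessibility loss/gain, and negative-binomial expression with a planted
odds-ratio coupling between accessibility loss under heat and
down-regulation — so every pipeline stage can be scored against truth with
no external data.

Genes are spaced so promoter-gene intervals never overlap, which makes the
gene-level truth unambiguous; overlapping genes are exercised separately by
hand-built micro-fixtures in the test suite.  All randomness flows from one
master seed through named ``numpy`` SeedSequence spawns (annotation, truth,
peaks, counts, terms), so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .genome_model import GeneModel, GenomeAnnotation, GenomicInterval, promoter_gene_interval
from .io_formats import (
    PeakSet,
    SampleLabel,
    write_design,
    write_gff3,
    write_peaks_narrowpeak,
    write_term_map,
)

__all__ = ["StudyConfig", "TruthTable", "simulate_annotation", "simulate_truth",
           "simulate_peaks", "simulate_counts", "generate_study"]

_STREAMS = ("annotation", "truth", "peaks", "counts", "terms")


@dataclass
class StudyConfig:
    """Parameters of one synthetic study; defaults are the study conditions.

    Accessibility rates approximate the real study's marginal proportions
    (roughly a third of genes accessible under control, more under heat);
    placement probabilities follow the observed gene-class split (promoter /
    over TSS / gene body ~ 0.37 / 0.48 / 0.15); NB dispersion 0.05 is a
    typical well-replicated bulk RNA-seq value.  The planted loss and
    regulation rates (p_lose_under_HT, p_down_base, p_up at 0.2) are denser
    than a full-genome study would show: at the desk-scale default of 2000
    genes they keep every cell of the loss x regulation cross-table large
    enough that the generator's odds-ratio recovery contract (estimate within
    [2, 8] when coupling_or = 4) holds run by run.
    """

    n_genes: int = 2000
    n_chroms: int = 2
    chrom_len: int = 20_000_000
    genotypes: Tuple[str, ...] = ("Bn", "B7", "B8")
    times: Tuple[str, ...] = ("1d", "10d")
    temperatures: Tuple[str, ...] = ("C", "HT")
    n_atac_reps: int = 2
    n_rna_reps: int = 3
    # accessibility truth
    p_accessible: float = 0.35
    p_lose_under_HT: float = 0.20
    p_gain_under_HT: float = 0.25
    p_variant_dropout: float = 0.05
    placement_probs: Tuple[float, float, float] = (0.37, 0.48, 0.15)  # promoter, over_TSS, gene_body
    # peak emission
    peak_noise: float = 0.10
    peak_jitter: int = 100
    spurious_rate: float = 0.15  # spurious intergenic peaks per gene per sample
    # expression truth
    coupling_or: float = 4.0
    p_down_base: float = 0.20
    p_up: float = 0.20
    deg_log2fc: float = 3.0
    nb_dispersion: float = 0.05
    library_factor_range: Tuple[float, float] = (0.8, 1.25)
    base_meanlog: float = 3.3
    base_sdlog: float = 1.2
    accessibility_meanlog_shift: float = 1.2
    coverage_meanlog_slope: float = 8.0
    # term map
    n_terms: int = 50
    term_size_range: Tuple[int, int] = (20, 200)
    plant_enriched_term: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_accessible", "p_lose_under_HT", "p_gain_under_HT",
                     "p_variant_dropout", "peak_noise", "p_down_base", "p_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coupling_or <= 0:
            raise ValueError("coupling_or must be > 0")
        if self.n_atac_reps < 2 or self.n_rna_reps < 2:
            raise ValueError("replicate counts must be >= 2")
        if abs(sum(self.placement_probs) - 1.0) > 1e-9:
            raise ValueError("placement_probs must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        """A named, independent random stream derived from the master seed."""
        if stream not in _STREAMS:
            raise ValueError(f"unknown stream {stream!r}")
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))
        )

    @property
    def variants(self) -> List[Tuple[str, str, str]]:
        return [
            (g, t, temp)
            for g in self.genotypes
            for t in self.times
            for temp in self.temperatures
        ]

    def atac_labels(self) -> List[SampleLabel]:
        return [
            SampleLabel(g, t, temp, r, "ATAC")
            for (g, t, temp) in self.variants
            for r in range(1, self.n_atac_reps + 1)
        ]

    def rna_labels(self) -> List[SampleLabel]:
        return [
            SampleLabel(g, t, temp, r, "RNA")
            for (g, t, temp) in self.variants
            for r in range(1, self.n_rna_reps + 1)
        ]


@dataclass
class TruthTable:
    """Ground truth of one synthetic study.

    ``genes``: per-gene frame (placement, OCR interval, loses/gains under HT,
    DE label and planted log2fc, expression mean).  ``variant_accessibility``:
    genes x variants boolean frame of true accessibility states, variant
    columns named genotype_time_temperature.
    """

    genes: pd.DataFrame
    variant_accessibility: pd.DataFrame


_GENE_MARGIN = 6000      # keeps promoter-gene intervals inside the chromosome
_GENE_SPACING = 12000    # minimum gap between spans: intervals can never touch


def simulate_annotation(config: StudyConfig) -> GenomeAnnotation:
    """Place genes with random strand, lengths 1-5 kb, spacing >= 12 kb.

    Deterministic for a given seed.  Raises when ``n_genes`` cannot be packed
    into the configured chromosomes.
    """
    rng = config.rng("annotation")
    per_gene_max = 5000 + _GENE_SPACING + 2000
    capacity = config.n_chroms * max(0, config.chrom_len - 2 * _GENE_MARGIN)
    if config.n_genes * per_gene_max > capacity:
        raise ValueError(
            f"cannot pack {config.n_genes} genes into "
            f"{config.n_chroms} x {config.chrom_len} nt chromosomes"
        )
    chroms = [f"chr{i + 1}H" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_len for c in chroms}
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes: List[GeneModel] = []
    gi = 0
    for chrom, n_here in zip(chroms, per_chrom):
        cursor = _GENE_MARGIN
        for _ in range(n_here):
            length = int(rng.integers(1000, 5001))
            strand = "+" if rng.random() < 0.5 else "-"
            start = cursor
            end = start + length
            if end + _GENE_MARGIN > config.chrom_len:
                raise ValueError(f"ran out of space on {chrom} at gene {gi}")
            gi += 1
            genes.append(GeneModel(id=f"gene_{gi:05d}", span=GenomicInterval(chrom, start, end), strand=strand))
            cursor = end + _GENE_SPACING + int(rng.integers(0, 2001))
    return GenomeAnnotation(genes=genes, chrom_sizes=sizes)


def _place_true_ocr(gene: GeneModel, placement: str, rng: np.random.Generator) -> Tuple[int, int]:
    """A true OCR interval for the gene, wholly inside its class region.

    Margins of >=150 nt to every class boundary guarantee the class survives
    the per-replicate +-100 nt jitter applied by :func:`simulate_peaks`.
    """
    tss = gene.tss
    width = int(rng.integers(250, 801))
    if placement == "over_TSS":
        width = max(width, 400)
        a = int(rng.integers(150, width - 149))  # tss sits >=150 nt inside
        lo_axis, hi_axis = -a, width - a
    elif placement == "promoter":
        u = int(rng.integers(150, 3001))  # downstream edge >=150 nt before TSS
        lo_axis, hi_axis = -(u + width), -u
    else:  # gene_body: wholly downstream of the TSS, inside the gene span
        body = gene.span.length
        w = min(width, max(200, body - 400))
        d = int(rng.integers(150, max(151, body - w - 100)))
        lo_axis, hi_axis = d, d + w
    if gene.strand == "+":
        return tss + lo_axis, tss + hi_axis
    return tss - hi_axis + 1, tss - lo_axis + 1


def simulate_truth(config: StudyConfig, annotation: GenomeAnnotation) -> TruthTable:
    """Draw the per-gene truth: accessibility, placement, DE label, expression mean."""
    rng = config.rng("truth")
    n = len(annotation)
    accessible_c = rng.random(n) < config.p_accessible
    loses = accessible_c & (rng.random(n) < config.p_lose_under_HT)
    gains = ~accessible_c & (rng.random(n) < config.p_gain_under_HT)

    placements = rng.choice(
        np.array(["promoter", "over_TSS", "gene_body"]),
        size=n,
        p=np.array(config.placement_probs),
    )
    ocr_bounds = [
        _place_true_ocr(g, placements[i], rng) for i, g in enumerate(annotation.genes)
    ]

    # Down-regulation under heat couples to accessibility loss via coupling_or
    # on the odds scale; up-regulation is independent of accessibility.
    o0 = config.p_down_base / (1.0 - config.p_down_base)
    o1 = config.coupling_or * o0
    p_down_lose = o1 / (1.0 + o1)
    p_down = np.where(loses, p_down_lose, config.p_down_base)
    u = rng.random(n)
    down = u < p_down
    up = ~down & (rng.random(n) < config.p_up)
    log2fc = np.zeros(n)
    log2fc[down] = -config.deg_log2fc
    log2fc[up] = config.deg_log2fc

    ever_accessible = accessible_c | gains
    coverage_frac = np.zeros(n)
    for i, g in enumerate(annotation.genes):
        pg = promoter_gene_interval(g, annotation.chrom_len(g.chrom))
        coverage_frac[i] = (ocr_bounds[i][1] - ocr_bounds[i][0]) / pg.length
    meanlog = (
        config.base_meanlog
        + rng.normal(0.0, config.base_sdlog, size=n)
        + config.accessibility_meanlog_shift * ever_accessible
        + config.coverage_meanlog_slope * coverage_frac * ever_accessible
    )

    genes_df = pd.DataFrame(
        {
            "gene_id": annotation.gene_ids,
            "accessible_C": accessible_c,
            "loses_HT": loses,
            "gains_HT": gains,
            "placement": placements,
            "ocr_start": [b[0] for b in ocr_bounds],
            "ocr_end": [b[1] for b in ocr_bounds],
            "de_label": np.where(down, "down", np.where(up, "up", "none")),
            "log2fc": log2fc,
            "meanlog": meanlog,
        }
    )

    # Variant-level states: baseline holds across genotypes and times; a small
    # per-(gene, genotype, time) dropout silences both temperatures of a cell.
    acc = {}
    for g in config.genotypes:
        for t in config.times:
            dropout = rng.random(n) < config.p_variant_dropout
            acc[f"{g}_{t}_C"] = accessible_c & ~dropout
            acc[f"{g}_{t}_HT"] = ((accessible_c & ~loses) | gains) & ~dropout
    va = pd.DataFrame(acc, index=annotation.gene_ids)
    return TruthTable(genes=genes_df, variant_accessibility=va)


def _intergenic_slots(annotation: GenomeAnnotation) -> Dict[str, List[Tuple[int, int]]]:
    """Per chromosome, regions safely outside every promoter-gene interval."""
    slots: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, genes in annotation.genes_by_chrom().items():
        pgs = sorted(
            (promoter_gene_interval(g, annotation.chrom_len(chrom)).start,
             promoter_gene_interval(g, annotation.chrom_len(chrom)).end)
            for g in genes
        )
        out = []
        prev_end = 0
        for s, e in pgs:
            if s - prev_end >= 2500:
                out.append((prev_end + 1000, s - 1000))
            prev_end = max(prev_end, e)
        if annotation.chrom_len(chrom) - prev_end >= 2500:
            out.append((prev_end + 1000, annotation.chrom_len(chrom) - 1000))
        slots[chrom] = out
    return slots


def simulate_peaks(
    config: StudyConfig, annotation: GenomeAnnotation, truth: TruthTable
) -> List[PeakSet]:
    """One PeakSet per ATAC sample (24 with the default design).

    Every gene truly accessible in a variant emits a peak per replicate with
    probability 1 - peak_noise, at its true placement jittered +-100 nt;
    spurious peaks land in intergenic slots that cannot touch any
    promoter-gene interval.  Deterministic per seed.
    """
    rng = config.rng("peaks")
    genes = annotation.genes
    slots = _intergenic_slots(annotation)
    chrom_slots = {c: s for c, s in slots.items() if s}
    peak_sets: List[PeakSet] = []
    for label in config.atac_labels():
        variant = label.variant
        acc = truth.variant_accessibility[variant].to_numpy()
        emit = acc & (rng.random(len(genes)) >= config.peak_noise)
        intervals: List[GenomicInterval] = []
        idx = np.flatnonzero(emit)
        j = rng.integers(-config.peak_jitter, config.peak_jitter + 1, size=(idx.size, 2))
        for row, i in enumerate(idx):
            g = genes[i]
            s = int(truth.genes["ocr_start"].iat[i] + j[row, 0])
            e = int(truth.genes["ocr_end"].iat[i] + j[row, 1])
            if e - s < 50:
                e = s + 50
            intervals.append(GenomicInterval(g.chrom, max(0, s), e))
        n_spurious = rng.poisson(config.spurious_rate * len(genes))
        chroms = list(chrom_slots)
        for _ in range(n_spurious):
            chrom = chroms[int(rng.integers(len(chroms)))]
            lo, hi = chrom_slots[chrom][int(rng.integers(len(chrom_slots[chrom])))]
            w = int(rng.integers(200, 501))
            if hi - lo <= w:
                continue
            s = int(rng.integers(lo, hi - w))
            intervals.append(GenomicInterval(chrom, s, s + w))
        peak_sets.append(PeakSet(label=label, peaks=intervals))
    return peak_sets


def simulate_counts(config: StudyConfig, truth: TruthTable) -> pd.DataFrame:
    """Negative-binomial RNA counts (genes x 36 samples with the default design).

    HT samples of down-/up-labelled genes have their mean scaled by
    2**(+-deg_log2fc); library scaling factors are drawn per sample.  As
    ``nb_dispersion`` approaches 0 the counts approach Poisson.
    """
    rng = config.rng("counts")
    labels = config.rna_labels()
    mu_base = np.exp(truth.genes["meanlog"].to_numpy())
    lfc = truth.genes["log2fc"].to_numpy()
    n = mu_base.size
    lib = rng.uniform(*config.library_factor_range, size=len(labels))
    cols = {}
    for si, label in enumerate(labels):
        mu = mu_base * lib[si]
        if label.temperature == "HT":
            mu = mu * np.power(2.0, lfc)
        mu = np.maximum(mu, 1e-8)
        if config.nb_dispersion > 1e-12:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            cols[label.sample_id] = rng.negative_binomial(r, p)
        else:
            cols[label.sample_id] = rng.poisson(mu)
    return pd.DataFrame(cols, index=truth.genes["gene_id"]).rename_axis("gene_id")


def _simulate_terms(config: StudyConfig, truth: TruthTable) -> Dict[str, set]:
    """A flat term map over all genes; optionally one term planted in the down set."""
    rng = config.rng("terms")
    gene_ids = truth.genes["gene_id"].to_numpy()
    # term sizes are clamped so tiny studies stay samplable
    hi = min(config.term_size_range[1], max(2, gene_ids.size // 3))
    lo = min(config.term_size_range[0], hi)
    terms: Dict[str, set] = {}
    for i in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        terms[f"TERM:{i + 1:04d}"] = set(rng.choice(gene_ids, size=size, replace=False))
    if config.plant_enriched_term:
        down = gene_ids[(truth.genes["de_label"] == "down").to_numpy()]
        if down.size >= 5:
            take = down[rng.random(down.size) < 0.6]
            filler = rng.choice(gene_ids, size=min(20, gene_ids.size // 3), replace=False)
            terms["TERM:planted_down"] = set(take) | set(filler)
    return terms


def generate_study(config: StudyConfig, out_dir, force: bool = False) -> Path:
    """Write a complete, self-contained study fixture directory.

    Contents: peaks/<sample>.narrowPeak (one per ATAC sample), counts.tsv,
    design.tsv (ATAC + RNA rows), genes.gff3, terms.tsv, truth_genes.tsv,
    truth_variants.tsv, config.yaml.  Reruns with the same seed are
    byte-identical.  Refuses to write into an existing non-empty directory
    unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    (out / "peaks").mkdir(parents=True, exist_ok=True)

    annotation = simulate_annotation(config)
    truth = simulate_truth(config, annotation)
    peak_sets = simulate_peaks(config, annotation, truth)
    counts = simulate_counts(config, truth)
    terms = _simulate_terms(config, truth)

    write_gff3(annotation, out / "genes.gff3")
    for ps in peak_sets:
        write_peaks_narrowpeak(ps, out / "peaks" / f"{ps.label.sample_id}.narrowPeak")
    write_design(config.atac_labels() + config.rna_labels(), out / "design.tsv")
    counts.to_csv(out / "counts.tsv", sep="\t")
    write_term_map(terms, out / "terms.tsv")
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    truth.variant_accessibility.rename_axis("gene_id").to_csv(out / "truth_variants.tsv", sep="\t")
    cfg = asdict(config)
    for k, v in cfg.items():
        if isinstance(v, tuple):
            cfg[k] = list(v)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out
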