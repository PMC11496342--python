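"""Readers and writers for peak files, OCR sets, annotation, counts and design tables.

Formats handled: narrowPeak / BED3+ (peaks, OCRs), GFF3 or a minimal TSV gene
model (annotation), TSV count and design tables, a flat term->gene TSV for
enrichment, and a YAML run configuration.  All readers reject malformed input
with the offending line number rather than silently coercing it; every writer
round-trips losslessly through its paired reader.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
import yaml

from .genome_model import GeneModel, GenomeAnnotation, GenomicInterval

__all__ = [
    "SampleLabel",
    "PeakSet",
    "full_design",
    "read_peaks",
    "write_peaks_narrowpeak",
    "write_ocr_bed",
    "read_ocr_bed",
    "read_counts",
    "read_design",
    "write_design",
    "read_gff3",
    "write_gff3",
    "read_gene_table",
    "read_term_map",
    "write_term_map",
    "load_config",
    "DEFAULT_CONFIG",
]

GENOTYPES = ("Bn", "B7", "B8")
TIMES = ("1d", "10d")
TEMPERATURES = ("C", "HT")


@dataclass(frozen=True, order=True)
class SampleLabel:
    """Factor coordinates of one sample in the factorial design.

    The study crosses genotype (cv. Bowman and two sdw1 near-isogenic
    lines), time point (tillering, +10 days), and temperature regime
    (control vs. high), with 2 ATAC-seq and 3 RNA-seq replicates; the full
    design therefore enumerates 24 ATAC and 36 RNA samples.
    """

    genotype: str
    time: str
    temperature: str
    replicate: int
    assay: str = "ATAC"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")
        if self.assay not in ("ATAC", "RNA"):
            raise ValueError(f"assay must be ATAC or RNA, got {self.assay!r}")

    @property
    def sample_id(self) -> str:
        return f"{self.genotype}_{self.time}_{self.temperature}_r{self.replicate}_{self.assay}"

    @property
    def variant(self) -> str:
        """The experimental variant (genotype, time, temperature) without replicate."""
        return f"{self.genotype}_{self.time}_{self.temperature}"


def full_design(
    genotypes: Sequence[str] = GENOTYPES,
    times: Sequence[str] = TIMES,
    temperatures: Sequence[str] = TEMPERATURES,
    n_atac_reps: int = 2,
    n_rna_reps: int = 3,
) -> List[SampleLabel]:
    """Enumerate the full factorial design (24 ATAC + 36 RNA labels by default)."""
    labels = []
    for assay, n_reps in (("ATAC", n_atac_reps), ("RNA", n_rna_reps)):
        for g in genotypes:
            for t in times:
                for temp in temperatures:
                    for r in range(1, n_reps + 1):
                        labels.append(SampleLabel(g, t, temp, r, assay))
    return labels


@dataclass
class PeakSet:
    """Called peaks of one sample: sorted intervals with the sample label attached.

    Extra narrowPeak columns (name, score, summit, ...) are retained opaquely
    in ``extras`` (one tuple per peak, aligned with ``peaks``) but never used:
    the analysis consumes presence of intervals only.
    """

    label: SampleLabel
    peaks: List[GenomicInterval]
    extras: Optional[List[Tuple[str, ...]]] = None

    def __post_init__(self) -> None:
        order = sorted(range(len(self.peaks)), key=lambda i: (self.peaks[i].chrom, self.peaks[i].start, self.peaks[i].end))
        self.peaks = [self.peaks[i] for i in order]
        if self.extras is not None:
            if len(self.extras) != len(self.peaks):
                raise ValueError("extras must align with peaks")
            self.extras = [self.extras[i] for i in order]

    def __len__(self) -> int:
        return len(self.peaks)


def _parse_bed_line(line: str, lineno: int, path) -> Tuple[GenomicInterval, Tuple[str, ...]]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as e:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates: {e}") from None
    if start < 0 or start >= end:
        raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
    return GenomicInterval(chrom, start, end), tuple(fields[3:])


def read_peaks(path, label: SampleLabel) -> PeakSet:
    """Read a narrowPeak (BED6+4) or BED3+ file as a sorted :class:`PeakSet`.

    BED is already 0-based half-open, so coordinates are taken verbatim.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    peaks: List[GenomicInterval] = []
    extras: List[Tuple[str, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            iv, extra = _parse_bed_line(line, lineno, path)
            peaks.append(iv)
            extras.append(extra)
    return PeakSet(label=label, peaks=peaks, extras=extras)


def write_peaks_narrowpeak(peak_set: PeakSet, path) -> None:
    """Write a PeakSet as narrowPeak (BED6+4); extras are regenerated, not echoed."""
    with open(path, "w") as fh:
        for i, iv in enumerate(peak_set.peaks, start=1):
            summit = iv.length // 2
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tpeak_{i}\t100\t.\t0\t-1\t-1\t{summit}\n"
            )


def write_ocr_bed(ocrs, path) -> None:
    """Write a merged OCR set as BED5: name = OCR id, score = peak support."""
    with open(path, "w") as fh:
        fh.write("# crown-ocr merged OCR set: chrom start end ocr_id support\n")
        for ocr in ocrs:
            iv = ocr.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ocr.id}\t{ocr.support}\n")


def read_ocr_bed(path):
    """Read a BED file written by :func:`write_ocr_bed` back into an OCRSet."""
    from .ocr_construction import OCR, OCRSet  # local import to avoid a cycle

    ocrs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            iv, extra = _parse_bed_line(line, lineno, path)
            ocr_id = extra[0] if len(extra) >= 1 else f"OCR_{lineno}"
            support = int(extra[1]) if len(extra) >= 2 else 1
            ocrs.append(OCR(interval=iv, support=support, sources=frozenset(), id=ocr_id))
    return OCRSet(ocrs=ocrs, provenance=str(path))


def read_counts(path, design: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Read a gene x sample TSV of non-negative integer counts.

    First column = gene id, header row = sample ids.  Rejects duplicate gene
    ids, negative or non-integer entries, and (when a design table is given)
    samples absent from the design.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids: {dupes[:5]}")
    for col in df.columns:
        vals = df[col]
        if not pd.api.types.is_numeric_dtype(vals):
            raise ValueError(f"{path}: non-numeric counts in column {col}")
        if (vals < 0).any():
            raise ValueError(f"{path}: negative count in column {col}")
        if not (vals == vals.astype(int)).all():
            raise ValueError(f"{path}: non-integer count in column {col}")
    df = df.astype(int)
    if design is not None:
        missing = set(df.columns) - set(design["sample_id"])
        if missing:
            raise ValueError(f"{path}: samples absent from design: {sorted(missing)}")
    return df


_DESIGN_COLS = ["sample_id", "genotype", "time", "temperature", "replicate", "assay"]


def read_design(path) -> pd.DataFrame:
    """Read the sample design TSV (sample_id, genotype, time, temperature, replicate, assay)."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    missing = set(_DESIGN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in design")
    return df[_DESIGN_COLS]


def write_design(labels: Iterable[SampleLabel], path) -> None:
    rows = [
        {
            "sample_id": l.sample_id,
            "genotype": l.genotype,
            "time": l.time,
            "temperature": l.temperature,
            "replicate": l.replicate,
            "assay": l.assay,
        }
        for l in labels
    ]
    pd.DataFrame(rows, columns=_DESIGN_COLS).to_csv(path, sep="\t", index=False)


def design_labels(design: pd.DataFrame) -> List[SampleLabel]:
    return [
        SampleLabel(r.genotype, r.time, r.temperature, int(r.replicate), r.assay)
        for r in design.itertuples()
    ]


def read_gff3(path, chrom_sizes: Optional[Dict[str, int]] = None) -> GenomeAnnotation:
    """Read gene rows from a GFF3 file into a :class:`GenomeAnnotation`.

    GFF3 is 1-based inclusive; coordinates are converted to 0-based half-open.
    Chromosome sizes are taken from ``##sequence-region`` pragmas unless
    supplied explicitly; without either, each chromosome length falls back to
    the maximum gene end seen.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    sizes: Dict[str, int] = dict(chrom_sizes or {})
    if not sizes:
        with open(path) as fh:
            for line in fh:
                if line.startswith("##sequence-region"):
                    parts = line.split()
                    if len(parts) >= 4:
                        sizes[parts[1]] = int(parts[3])
                elif not line.startswith("#"):
                    break
    genes: List[GeneModel] = []
    for f in db.features_of_type("gene"):
        gene_id = f.attributes.get("ID", [f.id])[0]
        genes.append(
            GeneModel(
                id=gene_id,
                span=GenomicInterval(f.seqid, f.start - 1, f.end),
                strand=f.strand,
            )
        )
    if not sizes:
        for g in genes:
            sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.span.end)
    genes.sort(key=lambda g: (g.chrom, g.span.start, g.span.end))
    return GenomeAnnotation(genes=genes, chrom_sizes=sizes)


def write_gff3(annotation: GenomeAnnotation, path) -> None:
    """Write gene rows (with ##sequence-region pragmas) as GFF3, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.span.start)):
            fh.write(
                f"{g.chrom}\tcrown_ocr\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )


def read_gene_table(path, chrom_sizes: Optional[Dict[str, int]] = None) -> GenomeAnnotation:
    """Read the minimal TSV gene-model dialect: id, chrom, start_1based, end, strand."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "chrom", "start_1based", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: gene table missing columns: {sorted(missing)}")
    genes = [
        GeneModel(
            id=str(r.id),
            span=GenomicInterval(str(r.chrom), int(r.start_1based) - 1, int(r.end)),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]
    sizes = dict(chrom_sizes or {})
    if not sizes:
        for g in genes:
            sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.span.end)
    return GenomeAnnotation(genes=genes, chrom_sizes=sizes)


def read_term_map(path) -> Dict[str, Set[str]]:
    """Read a flat term->gene TSV (term_id \\t gene_id, one pair per line)."""
    terms: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            terms.setdefault(parts[0], set()).add(parts[1])
    return terms


def write_term_map(terms: Dict[str, Set[str]], path) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            for gene in sorted(terms[term]):
                fh.write(f"{term}\t{gene}\n")


# Defaults mirror the study's stated constants: 5 kb promoter window, 1 kb
# downstream extension, FPKM >= 0.5 expressed flag, DEG thresholds
# (mean >= 5 units, BH p < 0.05, |log2FC| > 2), FWER < 0.01 with 1000 random sets.
DEFAULT_CONFIG: Dict[str, object] = {
    "promoter_upstream": 5000,
    "downstream_extension": 1000,
    "fpkm_expressed_threshold": 0.5,
    "deg_min_mean": 5.0,
    "deg_alpha": 0.05,
    "deg_min_abs_lfc": 2.0,
    "enrichment_n_random": 1000,
    "enrichment_fwer_alpha": 0.01,
    "min_support": 1,
    "seed": 0,
}


def load_config(path=None) -> Dict[str, object]:
    """Load the flat YAML run configuration, filling unset keys from defaults."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        config.update(user)
    return config
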