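"""Coordinate conventions, gene models, and strand-aware derived intervals.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  GFF3 input (1-based,
inclusive) is converted on read by :mod:`crown_ocr.io_formats`.

The central derived windows are the *promoter region* ``[TSS-5 kb, TSS]``
and the *promoter-gene interval* ``[TSS-5 kb, TTS+1 kb]``, both taken in
transcription direction: "upstream" means before the TSS on the coding
strand, so windows for minus-strand genes are mirrored in genome
coordinates.  A gene is called *accessible* when an open chromatin region
(OCR) overlaps its promoter-gene interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "GenomeAnnotation",
    "tss_position",
    "tts_position",
    "promoter_interval",
    "promoter_gene_interval",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval.

    Invariants: ``0 <= start < end``; length is ``end - start > 0``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strict overlap: at least one shared base (bookends do not touch)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: identifier, span and strand.

    The transcription start site (TSS) is the first transcribed base:
    ``span.start`` on the plus strand, ``span.end - 1`` on the minus strand
    (last base, 0-based).  The transcription termination site (TTS) is the
    opposite end.
    """

    id: str
    span: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def tts(self) -> int:
        return self.span.end - 1 if self.strand == "+" else self.span.start


def tss_position(gene: GeneModel) -> int:
    """Strand-aware transcription start coordinate (0-based)."""
    return gene.tss


def tts_position(gene: GeneModel) -> int:
    """Strand-aware transcription termination coordinate (0-based)."""
    return gene.tts


def promoter_gene_interval(
    gene: GeneModel,
    chrom_len: int,
    upstream: int = 5000,
    downstream: int = 1000,
) -> GenomicInterval:
    """The window from ``upstream`` nt before the TSS to ``downstream`` nt past the TTS.

    Computed in transcription direction and clipped to ``[0, chrom_len)``.
    With the defaults this is the promoter-gene interval [TSS-5 kb, TTS+1 kb].

    Raises
    ------
    ValueError
        If ``upstream``/``downstream`` are negative or the clipped window is empty.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream extensions must be >= 0")
    if gene.strand == "+":
        lo = gene.span.start - upstream
        hi = gene.span.end + downstream
    else:
        lo = gene.span.start - downstream
        hi = gene.span.end + upstream
    lo = max(0, lo)
    hi = min(chrom_len, hi)
    if lo >= hi:
        raise ValueError(f"gene {gene.id}: promoter-gene interval empty after clipping")
    return GenomicInterval(gene.chrom, lo, hi)


def promoter_interval(
    gene: GeneModel,
    chrom_len: int,
    upstream: int = 5000,
) -> GenomicInterval:
    """The promoter window [TSS-5 kb, TSS): strictly upstream of the TSS.

    The TSS base itself is excluded (an OCR covering it is classified
    "over TSS", not "promoter").  Mirrored in genome coordinates for
    minus-strand genes; clipped to the chromosome.
    """
    if upstream < 0:
        raise ValueError("upstream must be >= 0")
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - upstream, tss
    else:
        lo, hi = tss + 1, tss + 1 + upstream
    lo = max(0, lo)
    hi = min(chrom_len, hi)
    if lo >= hi:
        raise ValueError(f"gene {gene.id}: promoter interval empty after clipping")
    return GenomicInterval(gene.chrom, lo, hi)


@dataclass
class GenomeAnnotation:
    """A collection of gene models plus chromosome lengths.

    Gene ids must be unique and every span must lie within its chromosome.
    """

    genes: List[GeneModel]
    chrom_sizes: Dict[str, int]
    _by_id: Dict[str, GeneModel] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        by_id: Dict[str, GeneModel] = {}
        for g in self.genes:
            if g.id in by_id:
                raise ValueError(f"duplicate gene id: {g.id}")
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chrom}")
            if g.span.end > self.chrom_sizes[g.chrom]:
                raise ValueError(
                    f"gene {g.id}: span end {g.span.end} exceeds "
                    f"{g.chrom} length {self.chrom_sizes[g.chrom]}"
                )
            by_id[g.id] = g
        object.__setattr__(self, "_by_id", by_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterable[GeneModel]:
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> List[str]:
        return [g.id for g in self.genes]

    def genes_by_chrom(self) -> Mapping[str, List[GeneModel]]:
        out: Dict[str, List[GeneModel]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for lst in out.values():
            lst.sort(key=lambda g: (g.span.start, g.span.end))
        return out

    def chrom_len(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]
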