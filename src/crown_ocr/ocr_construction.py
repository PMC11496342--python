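"""Merging per-replicate peaks into open chromatin regions (OCRs).

An OCR set for an experimental variant is the union-closure of all peaks
called in at least one replicate of that variant: peaks sharing at least one
base (half-open arithmetic; bookended intervals do not merge) collapse
transitively into one maximal region.  Each OCR records its *support* — the
number of source peaks absorbed — and the set of contributing sample labels.
"Marginal sets" pool every sample at one level of a factor (e.g. all HT
samples) and re-merge, which is why a marginal count can be far below the sum
of its component counts.
"""

from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

from .genome_model import GenomicInterval
from .io_formats import PeakSet, SampleLabel

__all__ = [
    "OCR",
    "OCRSet",
    "merge_peaks",
    "marginal_set",
    "reproducibility_pct",
    "support_distribution",
]


@dataclass(frozen=True)
class OCR:
    """One merged open-chromatin region.

    ``interval`` is the tight union hull of the constituent peaks; ``support``
    counts them; ``sources`` is the set of sample labels that contributed.
    """

    interval: GenomicInterval
    support: int
    sources: FrozenSet[SampleLabel]
    id: str = ""

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("OCR support must be >= 1")


@dataclass
class OCRSet:
    """A sorted, pairwise non-overlapping collection of OCRs."""

    ocrs: List[OCR]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.ocrs = sorted(self.ocrs, key=lambda o: (o.interval.chrom, o.interval.start, o.interval.end))

    def __len__(self) -> int:
        return len(self.ocrs)

    def __iter__(self):
        return iter(self.ocrs)

    @property
    def total_support(self) -> int:
        return sum(o.support for o in self.ocrs)

    def intervals_by_chrom(self) -> Dict[str, List[Tuple[int, int]]]:
        out: Dict[str, List[Tuple[int, int]]] = {}
        for o in self.ocrs:
            out.setdefault(o.interval.chrom, []).append((o.interval.start, o.interval.end))
        return out


_WeightedPeak = Tuple[str, int, int, int, FrozenSet[SampleLabel]]  # chrom, start, end, weight, sources


def _sweep_merge(
    weighted: List[_WeightedPeak], provenance: str, min_support: int
) -> OCRSet:
    """Single left-to-right sweep over (chrom, start)-sorted weighted intervals."""
    weighted.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: List[Tuple[str, int, int, int, set]] = []
    for chrom, start, end, weight, sources in weighted:
        if merged and merged[-1][0] == chrom and start < merged[-1][2]:
            last = merged[-1]
            merged[-1] = (chrom, last[1], max(last[2], end), last[3] + weight, last[4] | set(sources))
        else:
            merged.append((chrom, start, end, weight, set(sources)))
    ocrs = [
        OCR(
            interval=GenomicInterval(chrom, start, end),
            support=weight,
            sources=frozenset(sources),
            id=f"OCR_{i:06d}",
        )
        for i, (chrom, start, end, weight, sources) in enumerate(merged, start=1)
        if weight >= min_support
    ]
    return OCRSet(ocrs=ocrs, provenance=provenance)


def merge_peaks(
    peak_sets: Sequence[PeakSet],
    provenance: str = "",
    min_support: int = 1,
) -> OCRSet:
    """Merge peaks appearing in at least one of the given samples into OCRs.

    Overlap means >=1 shared base under half-open coordinates; merging is the
    transitive closure of pairwise overlap, so the output is pairwise disjoint
    and sorted.  ``min_support`` (default 1, i.e. presence in any replicate)
    optionally drops OCRs merged from fewer source peaks.

    Raises
    ------
    ValueError
        On an empty input *collection*; a collection of all-empty PeakSets is
        legitimate and yields an empty OCRSet.
    """
    peak_sets = list(peak_sets)
    if not peak_sets:
        raise ValueError("merge_peaks requires at least one PeakSet")
    weighted: List[_WeightedPeak] = []
    for ps in peak_sets:
        src = frozenset([ps.label])
        for iv in ps.peaks:
            weighted.append((iv.chrom, iv.start, iv.end, 1, src))
    return _sweep_merge(weighted, provenance, min_support)


def marginal_set(
    variant_sets: Sequence[Union[OCRSet, PeakSet]],
    provenance: str = "",
    min_support: int = 1,
) -> OCRSet:
    """Merge several variant OCR sets (or raw peak sets) into one marginal set.

    Equivalent to :func:`merge_peaks` on the pooled constituent peaks of all
    inputs: supports accumulate and overlapping regions from different levels
    collapse (hence marginal counts below the sum of component counts).
    Idempotent on a single already-merged set.
    """
    variant_sets = list(variant_sets)
    if not variant_sets:
        raise ValueError("marginal_set requires at least one input set")
    weighted: List[_WeightedPeak] = []
    for s in variant_sets:
        if isinstance(s, PeakSet):
            src = frozenset([s.label])
            for iv in s.peaks:
                weighted.append((iv.chrom, iv.start, iv.end, 1, src))
        else:
            for o in s.ocrs:
                weighted.append((o.interval.chrom, o.interval.start, o.interval.end, o.support, o.sources))
    return _sweep_merge(weighted, provenance, min_support)


def reproducibility_pct(set_a: OCRSet, set_b: OCRSet) -> float:
    """Percentage of OCRs from the smaller set intersecting OCRs of the larger set.

    Ties go to the first argument.  Raises on an empty set (the statistic is
    undefined).
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ValueError("reproducibility_pct is undefined for empty OCR sets")
    small, large = (set_a, set_b) if len(set_a) <= len(set_b) else (set_b, set_a)
    large_by_chrom = large.intervals_by_chrom()
    n_hit = 0
    for o in small.ocrs:
        ivs = large_by_chrom.get(o.interval.chrom)
        if not ivs:
            continue
        # ivs sorted and disjoint: binary search for a candidate overlapper
        idx = bisect.bisect_right(ivs, (o.interval.start, float("inf"))) - 1
        hit = False
        for j in (idx, idx + 1):
            if 0 <= j < len(ivs):
                s, e = ivs[j]
                if s < o.interval.end and o.interval.start < e:
                    hit = True
                    break
        if hit:
            n_hit += 1
    return 100.0 * n_hit / len(small)


def support_distribution(ocr_set: OCRSet) -> Dict[int, int]:
    """Histogram of peak-support values; totals to the number of OCRs."""
    return dict(Counter(o.support for o in ocr_set.ocrs))
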