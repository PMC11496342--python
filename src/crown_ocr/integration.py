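"""Integrating chromatin accessibility with gene expression.

Accessibility status of a gene in a variant is its OCR count within the
promoter-gene interval.  Between two variants a gene can *lose* accessibility
(>=1 OCR to none), *gain* it (none to >=1), or stay stable (accessible or
inaccessible in both).  The association between losing accessibility and
transcriptional down-regulation is quantified as a conditional 2x2 exact test
restricted to the DEGs of the matching contrast: rows lose vs. not-lose,
columns down- vs. up-regulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenomeAnnotation, promoter_gene_interval
from .ocr_construction import OCRSet

__all__ = [
    "AccessibilityChange",
    "CrossTab",
    "accessible_genes",
    "accessibility_change",
    "change_summary",
    "change_expression_crosstab",
    "expression_by_coverage",
]

CHANGE_LEVELS = ("lose", "gain", "stable_accessible", "stable_inaccessible")


@dataclass(frozen=True)
class AccessibilityChange:
    gene_id: str
    status_a: int  # OCR count in the reference variant
    status_b: int  # OCR count in the comparison variant
    change: str

    def __post_init__(self) -> None:
        if self.change not in CHANGE_LEVELS:
            raise ValueError(f"unknown change level {self.change!r}")


@dataclass
class CrossTab:
    """2x2 association table: rows (lose | not-lose) x columns (down | up), DEGs only.

    ``odds_ratio`` is the cross-product ratio a*d / (b*c), ``inf`` when a zero
    cell makes it unbounded; the confidence interval uses the Haldane-Anscombe
    +0.5 correction on the log odds ratio; ``p_value`` is the two-sided exact
    (Fisher) test, None when no DEGs were available.
    """

    table: np.ndarray
    odds_ratio: float
    p_value: Optional[float]
    ci_low: float
    ci_high: float
    direction: str = "lose"


def accessible_genes(
    ocr_set: OCRSet,
    annotation: GenomeAnnotation,
    upstream: int = 5000,
    downstream: int = 1000,
) -> Dict[str, int]:
    """Genes with >=1 OCR in the promoter-gene interval, with their OCR counts.

    Counting uses binary search over the sorted, disjoint OCR intervals
    (independent of the interval-tree route in :mod:`crown_ocr.genomic_context`,
    which serves as its cross-check).
    """
    by_chrom = ocr_set.intervals_by_chrom()
    starts = {c: np.array([s for s, _ in ivs]) for c, ivs in by_chrom.items()}
    ends = {c: np.array([e for _, e in ivs]) for c, ivs in by_chrom.items()}
    out: Dict[str, int] = {}
    for g in annotation.genes:
        if g.chrom not in starts:
            continue
        pg = promoter_gene_interval(g, annotation.chrom_len(g.chrom), upstream, downstream)
        # OCRs disjoint+sorted: overlappers are those starting before pg.end
        # minus those ending at or before pg.start.
        n = int(np.searchsorted(starts[g.chrom], pg.end, side="left")) - int(
            np.searchsorted(ends[g.chrom], pg.start, side="right")
        )
        if n > 0:
            out[g.id] = n
    return out


def accessibility_change(
    variant_a_genes: Dict[str, int],
    variant_b_genes: Dict[str, int],
    gene_ids: Iterable[str],
) -> List[AccessibilityChange]:
    """Classify every gene's accessibility transition from variant A to variant B.

    lose: >=1 OCR in A, none in B; gain: none in A, >=1 in B; otherwise
    stable (accessible or inaccessible).  Swapping the variant arguments
    swaps lose and gain exactly.
    """
    changes = []
    for gid in gene_ids:
        a = variant_a_genes.get(gid, 0)
        b = variant_b_genes.get(gid, 0)
        if a >= 1 and b == 0:
            change = "lose"
        elif a == 0 and b >= 1:
            change = "gain"
        elif a >= 1:
            change = "stable_accessible"
        else:
            change = "stable_inaccessible"
        changes.append(AccessibilityChange(gid, a, b, change))
    return changes


def change_summary(changes: List[AccessibilityChange]) -> Dict[str, int]:
    out = {lvl: 0 for lvl in CHANGE_LEVELS}
    for c in changes:
        out[c.change] += 1
    return out


def _crosstab_for(
    changes: List[AccessibilityChange], degs: pd.DataFrame, direction: str
) -> CrossTab:
    status = {c.gene_id: c.change for c in changes}
    down = degs["log2fc"] < 0
    in_row = degs["gene_id"].map(lambda g: status.get(g) == direction).to_numpy()
    a = int((in_row & down).sum())      # direction & down
    b = int((in_row & ~down).sum())     # direction & up
    c_ = int((~in_row & down).sum())    # other & down
    d = int((~in_row & ~down).sum())    # other & up
    table = np.array([[a, b], [c_, d]])
    if b * c_ == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c_)
    if table.sum() == 0:
        warnings.warn(f"no DEGs available for the {direction} cross-tabulation; no test performed")
        return CrossTab(table, float("nan"), None, float("nan"), float("nan"), direction)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    h = table + 0.5  # Haldane-Anscombe correction for the CI
    log_or = np.log(h[0, 0] * h[1, 1] / (h[0, 1] * h[1, 0]))
    se = np.sqrt((1.0 / h).sum())
    ci_low, ci_high = np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se)
    return CrossTab(table, odds, p, float(ci_low), float(ci_high), direction)


def change_expression_crosstab(
    changes: List[AccessibilityChange],
    de_results: pd.DataFrame,
) -> Tuple[CrossTab, CrossTab]:
    """Cross-tabulate accessibility change against expression change among DEGs.

    ``de_results`` must carry ``is_deg`` (see :func:`crown_ocr.expression.call_degs`)
    for the same variant pair as ``changes`` (reference variant = A, comparison
    = B, matching the DE contrast reference/alternative).  Returns the pair of
    tables (lose x down/up, gain x down/up).
    """
    if "is_deg" not in de_results.columns:
        raise ValueError("de_results must contain is_deg; run call_degs first")
    degs = de_results[de_results["is_deg"]].copy()
    return _crosstab_for(changes, degs, "lose"), _crosstab_for(changes, degs, "gain")


def expression_by_coverage(
    profiles: pd.DataFrame,
    fpkm_mean: pd.Series,
    bin_width: float = 10.0,
) -> Tuple[pd.DataFrame, pd.DataFrame, float]:
    """Mean/median FPKM per coverage bin and per gene class, plus a trend statistic.

    ``profiles`` is the per-gene table from
    :func:`crown_ocr.genomic_context.build_profiles`; ``fpkm_mean`` is the
    per-gene mean FPKM.  Genes are binned by the percent of their
    promoter-gene interval covered by OCRs (default 10% bins).  The trend
    statistic is the Spearman correlation of bin midpoint vs. median FPKM
    across occupied bins (0.0 when degenerate).

    Returns (per-bin table, per-class table, trend).
    """
    df = profiles.merge(
        fpkm_mean.rename("fpkm").rename_axis("gene_id").reset_index(), on="gene_id", how="inner"
    )
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    df["bin"] = pd.cut(df["coverage_pct"], bins=edges, include_lowest=True, right=True)
    per_bin = (
        df.groupby("bin", observed=True)["fpkm"]
        .agg(n="size", mean_fpkm="mean", median_fpkm="median")
        .reset_index()
    )
    per_bin["bin_mid"] = per_bin["bin"].map(lambda iv: (iv.left + iv.right) / 2.0).astype(float)
    acc = df[df["accessible"]]
    per_class = (
        acc.groupby("gene_class", observed=True)["fpkm"]
        .agg(n="size", mean_fpkm="mean", median_fpkm="median")
        .reset_index()
    )
    occupied = per_bin[per_bin["n"] > 0]
    if len(occupied) < 2 or occupied["median_fpkm"].nunique() == 1:
        trend = 0.0
    else:
        rho = stats.spearmanr(occupied["bin_mid"], occupied["median_fpkm"]).statistic
        trend = float(rho) if np.isfinite(rho) else 0.0
    return per_bin, per_class, trend
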