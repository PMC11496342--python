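"""Independent brute-force oracles used to validate the package's fast paths.

Each oracle favors obviousness over speed and shares no code with the
implementation it checks: union-find closure for interval merging, all-pairs
scans for intersection, per-base bitmaps for coverage, exact rational
enumeration for the hypergeometric tail and the 2x2 exact test, and a literal
step-up loop for Benjamini-Hochberg.
"""

from fractions import Fraction
from math import comb
from typing import Dict, List, Sequence, Tuple

Interval = Tuple[str, int, int]


def brute_merge(peaks: Sequence[Interval]) -> List[Tuple[str, int, int, int]]:
    """Union-closure of strict interval overlap by O(n^2) union-find.

    Returns sorted (chrom, start, end, n_source_peaks) hulls.
    """
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = peaks[i]
            cj, sj, ej = peaks[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    # transitive closure needs repeated passes: merging two clusters can make
    # a third overlap their hull only via a chain of actual peaks, which the
    # pairwise pass above already captures (overlap is between peaks, not hulls).
    groups: Dict[int, List[Interval]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    out = []
    for members in groups.values():
        chrom = members[0][0]
        out.append(
            (chrom, min(s for _, s, _ in members), max(e for _, _, e in members), len(members))
        )
    return sorted(out)


def brute_intersect(
    ocrs: Sequence[Tuple[str, Interval]], gene_windows: Sequence[Tuple[str, Interval]]
) -> set:
    """All (ocr_id, gene_id) pairs with >=1 nt overlap, by an O(n*m) scan."""
    hits = set()
    for ocr_id, (co, so, eo) in ocrs:
        for gene_id, (cg, sg, eg) in gene_windows:
            if co == cg and so < eg and sg < eo:
                hits.add((ocr_id, gene_id))
    return hits


def bitmap_coverage_pct(window: Tuple[int, int], ocrs: Sequence[Tuple[int, int]]) -> float:
    """Percent of window bases covered by the union of intervals, one base at a time."""
    lo, hi = window
    covered = 0
    for pos in range(lo, hi):
        if any(s <= pos < e for s, e in ocrs):
            covered += 1
    return 100.0 * covered / (hi - lo)


def brute_bh(pvals: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up, written directly from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, pvals[i] * m / rank_from_top)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def exact_hypergeom_upper(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) as an exact rational, by enumerating the tail."""
    total = comb(N, n)
    tail = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return Fraction(tail, total)


def exact_fisher_two_sided(table) -> Fraction:
    """Two-sided Fisher p for a 2x2 table: sum of P(tables) <= P(observed),
    enumerating all tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    denom = comb(N, c1)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)
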