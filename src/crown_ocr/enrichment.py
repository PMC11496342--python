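"""Over-representation analysis with hypergeometric p-values and permutation FWER.

Annotation arrives as a flat term -> gene map (assumed already propagated up
any ontology hierarchy — the DAG itself is out of scope).  Per term the
upper-tail hypergeometric p-value asks how surprising the observed overlap
between the study set and the term's genes is under uniform sampling from the
universe.  Family-wise error rates follow the min-p randomization scheme:
draw ``n_random`` random gene sets of the study-set size from the universe,
record the minimum p-value across all terms for each draw, and report
FWER(t) = fraction of draws whose minimum p is <= the observed p of term t.
Terms with FWER below the threshold (0.01 by default) are flagged
over-represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TermMap", "hypergeom_upper_tail", "fwer_enrichment"]


@dataclass
class TermMap:
    """Flat term -> gene annotation over a fixed gene universe."""

    terms: Dict[str, FrozenSet[str]]
    universe: FrozenSet[str]

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        self.universe = frozenset(self.universe)
        for t, genes in self.terms.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"term {t}: {len(extra)} annotated genes outside the universe "
                    f"(e.g. {sorted(extra)[:3]})"
                )

    @classmethod
    def from_dict(cls, terms: Mapping[str, Iterable[str]], universe: Optional[Iterable[str]] = None) -> "TermMap":
        tm = {t: frozenset(g) for t, g in terms.items()}
        if universe is None:
            universe = frozenset().union(*tm.values()) if tm else frozenset()
        return cls(terms=tm, universe=frozenset(universe))

    def __len__(self) -> int:
        return len(self.terms)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    k = study-set genes carrying the term, K = universe genes carrying it,
    n = study-set size, N = universe size.  k = 0 returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fwer_enrichment(
    study_set: Iterable[str],
    term_map: TermMap,
    n_random: int = 1000,
    seed: Optional[int] = None,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``study_set`` with min-p randomization FWER.

    Random sets are sampled without replacement, uniformly from the universe,
    with the same size as the study set; results are bit-reproducible for a
    fixed ``seed``.  Returns one row per term: term_id, k, K, n, N, p_hyper,
    fwer, over_represented (fwer < alpha).

    Raises
    ------
    ValueError
        If the study set is not a subset of the universe or ``n_random < 100``.
    """
    study = frozenset(study_set)
    if not study <= term_map.universe:
        extra = sorted(study - term_map.universe)[:3]
        raise ValueError(f"study set not contained in the universe (e.g. {extra})")
    if n_random < 100:
        raise ValueError("n_random must be >= 100 for a usable FWER estimate")
    if not term_map.terms:
        raise ValueError("term map is empty")

    genes = sorted(term_map.universe)
    gene_idx = {g: i for i, g in enumerate(genes)}
    N, n = len(genes), len(study)
    term_ids = sorted(term_map.terms)
    T = len(term_ids)

    membership = np.zeros((T, N), dtype=np.float32)
    for ti, t in enumerate(term_ids):
        for g in term_map.terms[t]:
            membership[ti, gene_idx[g]] = 1.0
    K = membership.sum(axis=1).astype(int)

    study_vec = np.zeros(N, dtype=np.float32)
    for g in study:
        study_vec[gene_idx[g]] = 1.0
    k_obs = (membership @ study_vec).astype(int)
    p_obs = stats.hypergeom.sf(k_obs - 1, N, K, n)
    p_obs = np.where(k_obs == 0, 1.0, p_obs)

    rng = np.random.default_rng(seed)
    # n_random draws without replacement in one shot: take the n smallest
    # uniform keys per row (a random n-subset of the universe).
    keys = rng.random((n_random, N))
    pick = np.argpartition(keys, n - 1, axis=1)[:, :n] if n > 0 else np.empty((n_random, 0), int)
    rand_ind = np.zeros((n_random, N), dtype=np.float32)
    np.put_along_axis(rand_ind, pick, 1.0, axis=1)
    k_rand = rand_ind @ membership.T  # (n_random, T)
    p_rand = stats.hypergeom.sf(np.rint(k_rand).astype(int) - 1, N, K[None, :], n)
    p_rand = np.where(np.rint(k_rand).astype(int) == 0, 1.0, p_rand)
    min_p = p_rand.min(axis=1)

    fwer = (min_p[:, None] <= p_obs[None, :]).mean(axis=0)
    return pd.DataFrame(
        {
            "term_id": term_ids,
            "k": k_obs,
            "K": K,
            "n": n,
            "N": N,
            "p_hyper": p_obs,
            "fwer": fwer,
            "over_represented": fwer < alpha,
        }
    )
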