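"""Hypergeometric GO-term enrichment of gene sets against an array-wide
background.

The urn model: a background of N genes contains K carrying a term; a set
of n genes drawn from it shows k carriers; the upper-tail probability
P(X ≥ k) is the enrichment p-value. Significance is called at raw
P ≤ α (α = 0.01 by default) with no multiple-testing correction —
Benjamini–Hochberg q-values are reported alongside for modern use but
never change the raw-threshold flags. Genes with no annotation stay in N:
they are draws without the term.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GoAnnotationTable


@dataclass
class EnrichmentRecord:
    """One GO term × gene-set hypergeometric test."""

    term: str
    set_id: str
    k: int  # annotated genes in the set
    n: int  # set size
    K: int  # annotated genes in the background
    N: int  # background size
    p_value: float
    q_value: float | None = None
    enriched: bool = False

    def __post_init__(self) -> None:
        _check_bounds(self.k, self.n, self.K, self.N)
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def _check_bounds(k: int, n: int, K: int, N: int) -> None:
    if not 0 <= k:
        raise ValueError(f"violated 0 ≤ k: k={k}")
    if k > min(n, K):
        raise ValueError(f"violated k ≤ min(n, K): k={k}, n={n}, K={K}")
    if n > N:
        raise ValueError(f"violated n ≤ N: n={n}, N={N}")
    if K > N:
        raise ValueError(f"violated K ≤ N: K={K}, N={N}")
    # 2x2 table validity: every cell non-negative
    if N - K - n + k < 0:
        raise ValueError(
            f"violated N − K − n + k ≥ 0: k={k}, n={n}, K={K}, N={N}"
        )


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    Computed through the survival function, which works in log space for
    stability; exact to float precision for small populations. k = 0
    returns 1.0 exactly.
    """
    _check_bounds(k, n, K, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_set(
    genes: set[str],
    background: set[str],
    annotations: GoAnnotationTable,
    alpha: float = 0.01,
    set_id: str = "set",
) -> list[EnrichmentRecord]:
    """Test every GO term present in the gene set for over-representation.

    One record per term with k ≥ 1 in the set, sorted by ascending
    p-value (term id breaks ties deterministically); ``enriched`` flags
    raw p ≤ alpha.
    """
    genes = set(genes)
    background = set(background)
    stray = genes - background
    if stray:
        raise ValueError(
            f"genes outside the background: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(genes)
    term_in_set: dict[str, int] = {}
    for g in genes:
        for t in annotations.terms_of(g):
            term_in_set[t] = term_in_set.get(t, 0) + 1
    term_in_bg: dict[str, int] = {t: 0 for t in term_in_set}
    for g in background:
        for t in annotations.terms_of(g):
            if t in term_in_bg:
                term_in_bg[t] += 1

    records = []
    for term in sorted(term_in_set):
        k = term_in_set[term]
        K = term_in_bg[term]
        p = hypergeom_upper_tail(k, n, K, N)
        records.append(
            EnrichmentRecord(
                term=term, set_id=set_id, k=k, n=n, K=K, N=N,
                p_value=p, enriched=p <= alpha,
            )
        )
    if records:
        _, q, _, _ = multipletests(
            [r.p_value for r in records], method="fdr_bh"
        )
        for r, qv in zip(records, q):
            r.q_value = float(qv)
    records.sort(key=lambda r: (r.p_value, r.term))
    return records
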