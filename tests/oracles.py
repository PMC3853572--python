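"""Independent brute-force oracles used only by the test suite."""

from fractions import Fraction
from itertools import combinations
from math import comb, sqrt


def hypergeom_upper_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """P(X ≥ k) by exact integer counting of favourable draws.

    Counts, over all C(N, n) equally likely draws of n genes from N, the
    number containing at least k of the K annotated genes. Exact rational
    arithmetic; independent of any library distribution.
    """
    total = comb(N, n)
    favourable = 0
    for i in range(k, min(n, K) + 1):
        favourable += comb(K, i) * comb(N - K, n - i)
    return float(Fraction(favourable, total))


def hypergeom_upper_tail_enumerate(k: int, n: int, K: int, N: int) -> float:
    """P(X ≥ k) by literally enumerating every size-n subset of the urn."""
    annotated = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total


def mutual_rank_bruteforce(pcc) -> list[list[float]]:
    """MR by an explicit double loop with mean-rank tie handling."""
    n = len(pcc)
    ranks = [[0.0] * n for _ in range(n)]
    for a in range(n):
        others = [b for b in range(n) if b != a]
        # descending PCC; compute mean rank over ties explicitly
        for b in others:
            higher = sum(1 for c in others if pcc[a][c] > pcc[a][b])
            tied = sum(1 for c in others if pcc[a][c] == pcc[a][b])
            # positions higher+1 .. higher+tied share the mean rank
            ranks[a][b] = higher + (tied + 1) / 2.0
    mr = [[0.0] * n for _ in range(n)]
    for a in range(n):
        for b in range(n):
            if a != b:
                mr[a][b] = sqrt(ranks[a][b] * ranks[b][a])
    return mr
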