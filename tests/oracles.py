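"""Independent exact oracles used to freeze expected values.

Everything here is rational arithmetic on stdlib integers — no shared code
with the implementation under test.
"""

from fractions import Fraction
from math import comb


def exact_hypergeom_tail(N: int, k: int, r: int, j: int) -> Fraction:
    """P(X >= j) for X ~ Hypergeometric(N, k successes, r draws), exact."""
    num = 0
    for i in range(j, min(k, r) + 1):
        if r - i <= N - k:
            num += comb(k, i) * comb(N - k, r - i)
    return Fraction(num, comb(N, r))


def exact_rsa(N: int, ranks: list[int]) -> tuple[Fraction, int]:
    """Exact RSA minimum tail over cutoffs at the gene's sorted ranks.

    Returns (min probability, best 1-based cutoff index j, smallest on ties).
    """
    ranks = sorted(ranks)
    best_p, best_j = None, None
    for j, r in enumerate(ranks, start=1):
        p = exact_hypergeom_tail(N, len(ranks), r, j)
        if best_p is None or p < best_p:
            best_p, best_j = p, j
    return best_p, best_j
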