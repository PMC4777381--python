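"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package (and of scipy's
correlation/Fisher routines): ranking is done by hand, and hypergeometric
tail probabilities are exhaustively enumerated in exact rational arithmetic.
"""

from fractions import Fraction
from math import comb


def rank_average(xs):
    """Average ranks (1-based) with ties sharing the mean rank."""
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman r = Pearson correlation of average ranks, by hand."""
    rx, ry = rank_average(list(x)), rank_average(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    if vx == 0 or vy == 0:
        return float("nan")
    return num / (vx * vy) ** 0.5


def hypergeom_sf_exact(x, total, n_marked, n_drawn) -> Fraction:
    """P(X >= x) for X ~ Hypergeometric(total, n_marked, n_drawn), exact."""
    denom = comb(total, n_drawn)
    hi = min(n_marked, n_drawn)
    num = sum(
        comb(n_marked, j) * comb(total - n_marked, n_drawn - j)
        for j in range(max(x, 0), hi + 1)
    )
    return Fraction(num, denom)


def fisher_greater_oracle(x, k, p, n, mode) -> Fraction:
    """One-sided 'greater' Fisher p-value by exhaustive enumeration on the
    margins of the chosen 2x2 construction."""
    if mode == "paper":
        # table [x, k-x; p-x, n-k]: population n+p-x, p marked, k drawn
        return hypergeom_sf_exact(x, n + p - x, p, k)
    if mode == "standard":
        return hypergeom_sf_exact(x, n, p, k)
    raise ValueError(mode)
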