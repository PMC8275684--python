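"""Independent brute-force oracles for the statistical primitives.

These deliberately avoid scipy's tail functions (which the implementation
uses): the binomial and hypergeometric tails are exact rational sums via
``fractions.Fraction`` and ``math.comb``; the Poisson tail is a term-by-term
summation in extended precision.
"""

from fractions import Fraction
from math import comb, exp, lgamma, log

import numpy as np


def binom_upper_tail(k: int, n: int, p) -> float:
    """P(X >= k), X ~ Binomial(n, p), as an exact rational summed to float."""
    pf = Fraction(str(p))
    total = Fraction(0)
    for i in range(k, n + 1):
        total += comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return float(total)


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k), X ~ Poisson(lam), summed term by term from k upward."""
    if k <= 0:
        return 1.0
    # first term in log space, then recurrence t_{i+1} = t_i * lam / (i+1)
    log_t = -lam + k * log(lam) - lgamma(k + 1)
    if log_t < -745:  # below double-precision range
        return 0.0
    term = exp(log_t)
    total = 0.0
    i = k
    while term > 0.0:
        total += term
        i += 1
        term *= lam / i
        if term < total * 1e-18 and i > lam:
            break
    return total


def hypergeom_upper_tail(a: int, row1: int, col1: int, n: int) -> float:
    """P(A >= a) for the 2x2 Fisher table with fixed margins, exact.

    A is the top-left cell; row1 = a + b, col1 = a + c, n = a + b + c + d.
    """
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    denom = comb(n, col1)
    total = Fraction(0)
    for x in range(max(a, lo), hi + 1):
        total += Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)
    return float(total)


def holm_bruteforce(pvalues) -> np.ndarray:
    """Literal evaluation of the Holm step-down definition."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return np.array(adj)


def median_of_ratios_bruteforce(raw) -> np.ndarray:
    """Independent median-of-ratios size factors (pure-python loops)."""
    import statistics

    rows = [list(map(float, r)) for r in raw]
    kept = [r for r in rows if all(v > 0 for v in r)]
    n = len(kept[0])
    refs = [statistics.geometric_mean(r) for r in kept]
    return np.array([statistics.median(r[j] / ref for r, ref in zip(kept, refs))
                     for j in range(n)])


def pearson_permutation_pvalue(x, y, n_perm: int, rng) -> float:
    """Two-sided permutation p-value for the Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(np.corrcoef(x, y)[0, 1])
    hits = 0
    for _ in range(n_perm):
        r = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(r) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
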