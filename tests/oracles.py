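"""Independent brute-force oracles used to pin down exact-test conventions.

Everything here works from first principles with exact rational
arithmetic (`fractions.Fraction` over `math.comb`), independent of the
scipy-based implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

#: relative tie tolerance of the probability-mass two-sided convention
#: (as in R's binom.test / fisher.test)
GAMMA = Fraction(10_000_001, 10_000_000)


def binom_minlike_pvalue(c: int, n: int, p_num: int, p_den: int) -> float:
    """Two-sided probability-mass binomial p-value, exact rational.

    Success probability is ``p_num / p_den``.  Sums P(X = k) over all k
    whose point probability does not exceed the observed one (up to the
    conventional relative tie tolerance).
    """
    p = Fraction(p_num, p_den)
    q = 1 - p
    pmf = [comb(n, k) * p**k * q ** (n - k) for k in range(n + 1)]
    obs = pmf[c]
    total = sum(x for x in pmf if x <= obs * GAMMA)
    return float(min(Fraction(1), total))


def conditional_rate_pvalue(
    c_a: int, length_a: Fraction | float, c_b: int, length_b: Fraction | float
) -> float:
    """Exact conditional Poisson rate-test oracle.

    Conditions on N = c_a + c_b; under equal per-Mb rates c_a is binomial
    with success probability L_a / (L_a + L_b).  Lengths are taken as
    exact rationals.
    """
    la, lb = Fraction(length_a).limit_denominator(10**9), Fraction(
        length_b
    ).limit_denominator(10**9)
    n = c_a + c_b
    if n == 0:
        return 1.0
    p = la / (la + lb)
    return binom_minlike_pvalue(c_a, n, p.numerator, p.denominator)


def fisher_minlike_pvalue(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value oracle for the table [[a, b], [c, d]].

    Enumerates every table with the observed margins, computes its
    hypergeometric probability exactly, and sums those no more likely than
    the observed table (probability-mass convention).
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    obs = pmf[a]
    total = sum(x for x in pmf.values() if x <= obs * GAMMA)
    return float(min(Fraction(1), total))


def rank_sum_two_sided_exact(x: list[float], y: list[float]) -> float:
    """Exact two-sided rank-sum p-value by full enumeration (no ties).

    Enumerates all choices of rank assignments to the first sample and
    doubles the smaller tail of the rank-sum statistic.
    """
    from itertools import combinations

    pooled = sorted(x + y)
    if len(set(pooled)) != len(pooled):
        raise ValueError("ties not supported by this oracle")
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    sums = [
        sum(rs) for rs in combinations(range(1, len(pooled) + 1), len(x))
    ]
    n_tot = len(sums)
    lower = sum(s <= obs for s in sums) / n_tot
    upper = sum(s >= obs for s in sums) / n_tot
    return min(1.0, 2 * min(lower, upper))
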