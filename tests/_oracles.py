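"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: probabilities are exact
rationals built from binomial coefficients, and every sum enumerates the
full support directly.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by exhaustive enumeration of all 2x2 tables with
    the margins of [[a, b], [c, d]]: the sum of exact hypergeometric
    probabilities that do not exceed the observed table's probability."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    den = comb(n, c1)
    observed = Fraction(comb(r1, a) * comb(r2, c), den)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, k) * comb(r2, c1 - k), den)
        if p <= observed:
            total += p
    return float(total)


def adapted_expansion_oracle(n_x: int, N: int, m_x: int, M: int) -> float:
    """The adapted test recomputed from its definition: P = 1 unless the
    frequency at least doubled, else the two-sided enumeration on the
    half-rescaled baseline table."""
    doubled = m_x * N >= 2 * n_x * M and m_x > 0  # exact integer comparison
    if not doubled:
        return 1.0
    if N % 2 == 0:
        half = N // 2
    else:  # N/2 ends in .5: round half to even
        k = N // 2
        half = k if k % 2 == 0 else k + 1
    return fisher_two_sided_oracle(n_x, max(half - n_x, 0), m_x, M - m_x)


def binomial_tail_oracle(k: int, n: int, p0: Fraction = Fraction(1, 5)
                         ) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), summed exactly."""
    total = Fraction(0)
    for j in range(k, n + 1):
        total += comb(n, j) * p0**j * (1 - p0) ** (n - j)
    return float(total)


def binomial_tails_all(n: int, p0: Fraction = Fraction(1, 5)) -> list[float]:
    """P(X >= k) for k = 0..n via exact suffix summation."""
    pmf = [comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    tails = [Fraction(0)] * (n + 2)
    for j in range(n, -1, -1):
        tails[j] = tails[j + 1] + pmf[j]
    return [float(t) for t in tails[: n + 1]]
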