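"""Independent brute-force oracles used to pin expected values.

Everything here is deliberately naive (dynamic programming, sliding
windows, exact enumeration over Fractions) and shares no code with the
implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def sliding_window_sites(seq: str, motif_options: list[str]) -> list[int]:
    """All start positions where any concrete motif matches, via brute scan."""
    seq = seq.upper()
    k = len(motif_options[0])
    return [i for i in range(len(seq) - k + 1)
            if seq[i:i + k] in motif_options]


def binom_tail_enum(successes: int, n: int, p: Fraction | float) -> Fraction:
    """P(X >= successes) by exact summation over the outcome space."""
    p = Fraction(p).limit_denominator(10**6) if not isinstance(p, Fraction) else p
    q = 1 - p
    return sum((comb(n, j) * p**j * q**(n - j) for j in range(successes, n + 1)),
               Fraction(0))


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher exact p by full enumeration at fixed margins.

    Minimum-likelihood convention: sum the hypergeometric probabilities
    of every table no more likely than the observed one.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return total
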