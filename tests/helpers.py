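"""Independent oracles used by the test suite.

These are deliberately naive (exact integer arithmetic, direct summation)
and share no code with the implementation they check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def exact_upper_tail(N: int, M: int, n: int, m: int) -> Fraction:
    """P(X >= m) for X ~ Hypergeometric(N, M, n), as an exact rational.

    Direct summation of pmf terms with integer binomials; terms with k > M
    or n - k > N - M are zero.
    """
    denom = math.comb(N, n)
    num = 0
    for k in range(m, n + 1):
        if k > M or n - k > N - M:
            continue
        num += math.comb(M, k) * math.comb(N - M, n - k)
    return Fraction(num, denom)


def exact_tail_table(N: int, M: int, n: int) -> list[Fraction]:
    """Upper tails P(X >= m) for every m in 0..min(M, n), exact rationals."""
    hi = min(M, n)
    pmf = [
        math.comb(M, k) * math.comb(N - M, n - k)
        if (k <= M and n - k <= N - M)
        else 0
        for k in range(hi + 1)
    ]
    denom = math.comb(N, n)
    tails = []
    suffix = sum(pmf)
    for k in range(hi + 1):
        tails.append(Fraction(suffix, denom))
        suffix -= pmf[k]
    return tails


def brute_force_mi(labels: np.ndarray, states: np.ndarray, base: float = 2.0) -> float:
    """Mutual information by direct summation over the raw (label, state) pairs."""
    labels = np.asarray(labels)
    states = np.asarray(states)
    n = len(labels)
    total = 0.0
    for c in (0, 1):
        pc = float((labels == c).sum()) / n
        if pc == 0:
            continue
        for s in (0, 1, 2):
            ps = float((states == s).sum()) / n
            pcs = float(((labels == c) & (states == s)).sum()) / n
            if pcs > 0:
                total += pcs * math.log(pcs / (pc * ps), base)
    return total


def brute_force_mi_from_table(counts: np.ndarray, base: float = 2.0) -> float:
    """Mutual information by direct summation over a 2x3 contingency table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    total = 0.0
    for c in range(2):
        for s in range(3):
            pcs = counts[c, s] / n
            if pcs == 0:
                continue
            pc = counts[c, :].sum() / n
            ps = counts[:, s].sum() / n
            total += pcs * math.log(pcs / (pc * ps), base)
    return total
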