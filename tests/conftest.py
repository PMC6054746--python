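"""Shared fixtures and independent brute-force oracles.

The oracles re-derive tail probabilities and adjustment procedures by
direct enumeration so the library implementations are checked against
something that shares no code path with them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from rvburden.denovo import TrinucRateTable, annotate_cds


# ---------------------------------------------------------------- oracles
def binom_upper_tail_bruteforce(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct pmf summation."""
    total = 0.0
    for x in range(max(k, 0), n + 1):
        total += math.comb(n, x) * p**x * (1 - p) ** (n - x)
    return min(total, 1.0) if k <= n else 0.0


def poisson_upper_tail_bruteforce(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam) via 1 - sum_{x<k} pmf."""
    if k <= 0:
        return 1.0
    acc = 0.0
    for x in range(k):
        acc += math.exp(-lam) * lam**x / math.factorial(x)
    return max(0.0, 1.0 - acc)


def bh_stepup_bruteforce(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up by the textbook cummin construction."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest rank down
    for i in range(m - 2, -1, -1):
        adjusted[i] = min(adjusted[i], adjusted[i + 1])
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def fisher_twosided_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed (up to rounding slack) the observed one.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x: int) -> float:
        # P(a = x) under the hypergeometric with these margins
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        px = table_prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def toy_rate_table() -> TrinucRateTable:
    """Small non-uniform rate table: transition-biased, documented for tests."""
    rates = {}
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for five in "ACGT":
        for ref in "ACGT":
            for three in "ACGT":
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    base = 1e-8
                    if transitions[ref] == alt:
                        base *= 3  # transitions ~3x transversions
                    if ref == "C" and three == "G":
                        base *= 10  # CpG elevation
                    rates[(five, ref, three, alt)] = base
    return TrinucRateTable(rates)


@pytest.fixture(scope="session")
def toy_cds():
    """9-codon CDS with full per-substitution annotation and real flanks."""
    # ATG AAA TGC GGA TTT CAC CCG TGG TAA
    return annotate_cds("TOY1", "ATGAAATGCGGATTTCACCCGTGGTAA", flank5="C", flank3="G")
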