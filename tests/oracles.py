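"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — enumeration and direct formula
application — kept free of any import from the package's statistics code so
they can vouch for it.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np


def bh_stepup(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up by direct application of the definition."""
    p = [float(v) for v in p_values]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adjusted[i] = min(1.0, running)
    return adjusted


def signed_rank_exact_p(differences: Sequence[float]) -> float:
    """Two-sided exact signed-rank p by enumerating all 2^n sign flips.

    Expects nonzero differences with distinct magnitudes.
    """
    d = [float(v) for v in differences if v != 0]
    n = len(d)
    absd = [abs(v) for v in d]
    order = sorted(range(n), key=lambda i: absd[i])
    ranks = [0] * n
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    w_obs = sum(ranks[i] for i in range(n) if d[i] > 0)
    dist = [
        sum(r for r, pos in zip(ranks, signs) if pos)
        for signs in itertools.product((False, True), repeat=n)
    ]
    total = len(dist)
    p_le = sum(w <= w_obs for w in dist) / total
    p_ge = sum(w >= w_obs for w in dist) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Expects tie-free pooled data.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    m, n = len(x), len(y)
    pooled = sorted(x + y)
    rank_of = {v: r for r, v in enumerate(pooled, start=1)}
    u_obs = sum(rank_of[v] for v in x) - m * (m + 1) / 2
    us = []
    for combo in itertools.combinations(range(m + n), m):
        r1 = sum(r + 1 for r in combo)
        us.append(r1 - m * (m + 1) / 2)
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def loo_zscore_brute(values: Sequence[float], index: int) -> float:
    """Leave-one-out z-score by physically removing the focal value."""
    values = [float(v) for v in values]
    focal = values[index]
    ref = values[:index] + values[index + 1:]
    mean = sum(ref) / len(ref)
    var = sum((v - mean) ** 2 for v in ref) / (len(ref) - 1)
    if var == 0:
        return math.nan
    return (focal - mean) / math.sqrt(var)


def binom_interval_99(n: int, p: float) -> tuple[float, float]:
    """Central exact-binomial 99% interval for a frequency estimate."""
    from scipy import stats

    lo = stats.binom.ppf(0.005, n, p) / n
    hi = stats.binom.ppf(0.995, n, p) / n
    return float(lo), float(hi)
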