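"""Independent brute-force oracles used to verify the statistical kernels.

Every function here is deliberately written from first principles (exhaustive
enumeration, direct formulas, math.comb) and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def u_statistic(x, y) -> float:
    """Mann-Whitney U of x vs y counted pair by pair (ties count half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mw_permutation_p(x, y, tail: str) -> float:
    """Exact Mann-Whitney p by enumerating all C(n1+n2, n1) group labelings."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)
    u_obs = u_statistic(x, y)
    idx = range(len(pooled))
    n_le = n_ge = total = 0
    for case_idx in combinations(idx, n1):
        case = [pooled[i] for i in case_idx]
        ctrl = [pooled[i] for i in idx if i not in case_idx]
        u = u_statistic(case, ctrl)
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    p_less = n_le / total
    p_greater = n_ge / total
    if tail == "less":
        return p_less
    if tail == "greater":
        return p_greater
    if tail == "two-sided":
        return min(1.0, 2.0 * min(p_less, p_greater))
    raise ValueError(tail)


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg by direct sort, scale and cumulative minimum."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


def chi2_direct(table, yates: bool = False) -> float:
    """Pearson chi-square by direct sum of (|O-E| - c)^2 / E over four cells."""
    t = np.asarray(table, dtype=float)
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / n
            d = abs(t[i, j] - e)
            if yates:
                d = max(0.0, d - 0.5)
            stat += d * d / e
    return stat


def hypergeom_tail(k_min: int, universe: int, set_size: int, query: int) -> float:
    """P(X >= k_min) for X ~ Hypergeom(universe, set_size, query), by
    enumerating every 2x2 table with those fixed margins via math.comb."""
    denom = math.comb(universe, query)
    lo = max(0, query + set_size - universe)
    hi = min(query, set_size)
    total = 0
    for k in range(max(k_min, lo), hi + 1):
        total += math.comb(set_size, k) * math.comb(universe - set_size, query - k)
    return total / denom


def welch_t_one_tailed_p(a, b) -> float:
    """One-tailed (a greater) Welch t-test from the textbook formulas."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(stats.t.sf(t, df))
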