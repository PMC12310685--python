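"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles (explicit formulas, Python
loops, exact enumeration) so that tests compare the package's vectorized
implementations against a genuinely independent route. Only distribution
tail functions (scipy.stats.t.sf) are taken from scipy.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def welch_oracle(a, b) -> tuple[float, float, float]:
    """(mean difference, Welch t, two-sided p) for two samples, by the formulas."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    delta = m1 - m2
    if se2 == 0:
        return delta, math.copysign(math.inf, delta) if delta else 0.0, 0.0 if delta else 1.0
    t = delta / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return delta, t, p


def bh_stepup(pvalues) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the explicit step-up recursion."""
    p = [float(x) for x in pvalues]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def pairwise_auc(labels, scores) -> float:
    """AUC as the exhaustive concordance count over all (positive, negative) pairs."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def pearson_scratch(x, y) -> float:
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def spearman_scratch(x, y) -> float:
    """Rank correlation: Pearson of midranks, handling ties."""
    return pearson_scratch(_midranks(list(x)), _midranks(list(y)))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for overlap of an n-subset with a K-subset of an N-universe."""
    total = math.comb(N, n)
    upper = min(K, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, upper + 1)) / total
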