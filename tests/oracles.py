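"""Brute-force reference implementations used as independent oracles.

Each function implements its statistic directly from the definition
(loops, exhaustive enumeration, closed forms), with no shared code paths
with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bh_stepup(p: list[float]) -> list[float]:
    """BH q-values by literal evaluation of q_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


def two_way_anova_cellmeans(y: np.ndarray) -> dict[str, tuple[float, float]]:
    """Balanced two-way ANOVA from first principles.

    ``y`` has shape (a, b, n): factor A levels x factor B levels x
    replicates.  Returns {"A"|"B"|"AB": (F, p)} using plain sums of
    squares computed with explicit loops.
    """
    from scipy.stats import f as fdist

    a, b, n = y.shape
    grand = y.mean()
    ss_a = sum(b * n * (y[i].mean() - grand) ** 2 for i in range(a))
    ss_b = sum(a * n * (y[:, j].mean() - grand) ** 2 for j in range(b))
    ss_ab = 0.0
    for i in range(a):
        for j in range(b):
            ss_ab += n * (y[i, j].mean() - y[i].mean() - y[:, j].mean() + grand) ** 2
    ss_err = 0.0
    for i in range(a):
        for j in range(b):
            for r in range(n):
                ss_err += (y[i, j, r] - y[i, j].mean()) ** 2
    df_err = a * b * (n - 1)
    out = {}
    for key, ss, df in (("A", ss_a, a - 1), ("B", ss_b, b - 1),
                        ("AB", ss_ab, (a - 1) * (b - 1))):
        f = (ss / df) / (ss_err / df_err)
        out[key] = (f, float(fdist.sf(f, df, df_err)))
    return out


def hypergeom_tail(x: int, n_univ: int, n_marked: int, n_drawn: int) -> float:
    """P(overlap >= x) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for k in range(x, min(n_marked, n_drawn) + 1):
        total += (math.comb(n_marked, k) * math.comb(n_univ - n_marked, n_drawn - k)
                  / math.comb(n_univ, n_drawn))
    return min(total, 1.0)


def tom_triple_loop(a: np.ndarray) -> np.ndarray:
    """Topological overlap by the elementwise definition."""
    n = a.shape[0]
    t = np.zeros((n, n))
    k = [sum(a[i, u] for u in range(n)) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                t[i, j] = 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            denom = min(k[i], k[j]) + 1.0 - a[i, j]
            t[i, j] = (l_ij + a[i, j]) / denom if denom != 0 else 0.0
    return t


def ks_one_sided_d(x: list[float], y: list[float], side: str = "down") -> float:
    """One-sided two-sample KS statistic from explicit ECDF evaluation."""
    def ecdf(sample, v):
        return sum(1 for s in sample if s <= v) / len(sample)

    best = 0.0
    for v in list(x) + list(y):
        diff = ecdf(x, v) - ecdf(y, v)
        if side == "up":
            diff = -diff
        best = max(best, diff)
    return best


def student_t_3v3(x1: list[float], x2: list[float]) -> tuple[float, float]:
    """Equal-variance two-sample t from the textbook formula."""
    from scipy.stats import t as tdist

    n1, n2 = len(x1), len(x2)
    m1 = sum(x1) / n1
    m2 = sum(x2) / n2
    s1 = sum((v - m1) ** 2 for v in x1) / (n1 - 1)
    s2 = sum((v - m2) ** 2 for v in x2) / (n2 - 1)
    sp = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    t = (m2 - m1) / (sp * math.sqrt(1 / n1 + 1 / n2))
    p = 2 * tdist.sf(abs(t), n1 + n2 - 2)
    return t, p


def quantile_normalize_small(columns: list[list[float]]) -> list[list[float]]:
    """Quantile normalization of tie-free small matrices by sorting."""
    n = len(columns[0])
    ref = [sum(sorted(col)[i] for col in columns) / len(columns) for i in range(n)]
    out = []
    for col in columns:
        ranks = sorted(range(n), key=lambda i: col[i])
        new = [0.0] * n
        for pos, idx in enumerate(ranks):
            new[idx] = ref[pos]
        out.append(new)
    return out
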