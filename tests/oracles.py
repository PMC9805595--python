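"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: loops, closed forms and exhaustive enumeration only,
sharing no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pearson_textbook(x, y):
    """Loop-based pairwise-complete Pearson r with two-sided t-test p.

    Returns (r, p, n); (nan, nan, n) when n < 3 or either side constant.
    """
    pairs = [
        (a, b) for a, b in zip(x, y)
        if not (math.isnan(a) or math.isnan(b))
    ]
    n = len(pairs)
    if n < 3:
        return math.nan, math.nan, n
    xs = [a for a, _ in pairs]
    ys = [b for _, b in pairs]
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((a - mx) * (b - my) for a, b in pairs)
    sxx = sum((a - mx) ** 2 for a in xs)
    syy = sum((b - my) ** 2 for b in ys)
    if sxx == 0.0 or syy == 0.0:
        return math.nan, math.nan, n
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, p, n


def bh_stepup(p_values):
    """Reference Benjamini-Hochberg step-up over the non-missing entries."""
    p = list(p_values)
    idx = [i for i, v in enumerate(p) if not math.isnan(v)]
    m = len(idx)
    out = [math.nan] * len(p)
    if m == 0:
        return out
    order = sorted(idx, key=lambda i: p[i])
    q_sorted = [math.nan] * m
    running_min = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        q_sorted[rank - 1] = min(running_min, 1.0)
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


def hypergeom_tail_enum(k, K, n, N):
    """P(X >= k) by summing exact hypergeometric point masses."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def welch_closed_form(a, b):
    """Welch t, Satterthwaite df and two-sided p from the closed formulas."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def ward_d2_lance_williams(X):
    """O(L^3) agglomerative Ward.D2 via the Lance-Williams recurrence.

    Works on squared Euclidean dissimilarities; reported merge heights are
    on the original (unsquared) distance scale.  Returns the list of L-1
    merge heights in merge order.
    """
    X = np.asarray(X, dtype=float)
    L = X.shape[0]
    active = list(range(L))
    sizes = {i: 1 for i in range(L)}
    S = {}
    for i in range(L):
        for j in range(i + 1, L):
            S[(i, j)] = float(((X[i] - X[j]) ** 2).sum())

    def get(i, j):
        return S[(i, j) if i < j else (j, i)]

    heights = []
    next_id = L
    for _ in range(L - 1):
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = get(i, j)
                if best is None or d < best[0]:
                    best = (d, i, j)
        d_ij, i, j = best
        heights.append(math.sqrt(d_ij))
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            d_new = (
                (ni + nk) * get(i, k)
                + (nj + nk) * get(j, k)
                - nk * d_ij
            ) / (ni + nj + nk)
            S[(min(k, next_id), max(k, next_id))] = d_new
        sizes[next_id] = ni + nj
        active = [a for a in active if a not in (i, j)] + [next_id]
        next_id += 1
    return heights
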