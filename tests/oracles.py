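"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths:
structures are enumerated recursively, scored by a free-standing recursive
loop decomposition, and ensemble quantities are obtained by direct
summation.  Only the *parameter tables* are shared with the package (the
model definition is the convention under test, the algorithms are not).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from mapfold.energy import DEFAULT_MODEL, PAIR_TYPES

WC_GU = set(PAIR_TYPES.keys())


def pairable(a: str, b: str) -> bool:
    return (a, b) in WC_GU


def enumerate_structures(
    seq: str, minloop: int = 3, maxd: int = 600
) -> list[tuple[tuple[int, int], ...]]:
    """All pseudoknot-free structures as tuples of 0-based (i, j) pairs."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if j - i < minloop + 1:
            return ((),)
        out = list(rec(i + 1, j))  # i unpaired
        for k in range(i + minloop + 1, min(j, i + maxd) + 1):
            if not pairable(seq[i], seq[k]):
                continue
            for inner in rec(i + 1, k - 1):
                for outer in rec(k + 1, j):
                    out.append(((i, k),) + inner + outer)
        return tuple(out)

    return list(rec(0, n - 1))


def score_structure(
    seq: str,
    pairs: tuple[tuple[int, int], ...],
    ps: np.ndarray | None = None,
    model=DEFAULT_MODEL,
    max_interior: int = 30,
) -> float:
    """Free energy of one structure by direct recursive loop classification."""
    if not pairs:
        return 0.0
    n = len(seq)
    partner = {i: j for i, j in pairs}
    partner.update({j: i for i, j in pairs})
    if ps is None:
        ps = np.zeros(n)

    def enclosed(i: int, j: int) -> list[tuple[int, int]]:
        kids, k = [], i + 1
        while k < j:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        return kids

    def loop_energy(i: int, j: int) -> float:
        kids = enclosed(i, j)
        if not kids:
            return model.hairpin(j - i - 1)
        if len(kids) == 1:
            k, l = kids[0]
            u1, u2 = k - i - 1, j - l - 1
            if u1 == 0 and u2 == 0:
                t_out = PAIR_TYPES[(seq[i], seq[j])]
                t_in = PAIR_TYPES[(seq[k], seq[l])]
                return model.stack[t_out, t_in] + ps[i] + ps[j] + ps[k] + ps[l]
            if u1 + u2 > max_interior:
                return math.inf
            if u1 == 0 or u2 == 0:
                return model.bulge(u1 + u2)
            return model.internal(u1, u2)
        return model.ml_close + model.ml_branch * (1 + len(kids))

    total = 0.0
    for i, j in pairs:
        total += loop_energy(i, j)
    return float(total)


def brute_force_mfe(seq: str, ps=None, minloop=3, maxd=600) -> float:
    return min(
        score_structure(seq, s, ps)
        for s in enumerate_structures(seq, minloop, maxd)
    )


def brute_force_ensemble(
    seq: str, RT: float, ps=None, minloop: int = 3, maxd: int = 600
) -> tuple[float, np.ndarray]:
    """(partition function Z, pair probability matrix) by direct summation."""
    n = len(seq)
    Z = 0.0
    P = np.zeros((n, n))
    for s in enumerate_structures(seq, minloop, maxd):
        e = score_structure(seq, s, ps)
        if not math.isfinite(e):
            continue
        w = math.exp(-e / RT)
        Z += w
        for i, j in s:
            P[i, j] += w
            P[j, i] += w
    P /= Z
    return Z, P


def naive_sliding(values, mask, window, stat, min_frac=0.5):
    """Reference sliding-window statistic with centered windows."""
    n = len(values)
    half = window // 2
    out = np.full(n, np.nan)
    for c in range(n):
        lo, hi = max(0, c - half), min(n, c + half + 1)
        v = np.asarray(values[lo:hi], dtype=float)
        m = np.asarray(mask[lo:hi], dtype=bool)
        v = v[~m]
        if len(v) < (hi - lo) * min_frac or len(v) == 0:
            continue
        out[c] = stat(v)
    return out


def naive_gini(x) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2 or x.mean() == 0:
        return np.nan
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2 * n * n * x.mean()))
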