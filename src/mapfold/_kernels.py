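"""Numba dynamic-programming kernels for the folding engine.

Zuker-style minimum-free-energy fill and McCaskill-style inside/outside
partition-function recursions over the nearest-neighbor model defined in
:mod:`mapfold.energy`.  The decomposition is the classic one:

* ``V[i,j]``  — best energy / Boltzmann sum of structures closed by pair (i,j)
  (hairpin, interior loop including the stack special case, or multiloop);
* ``WM``      — multiloop segment with >= 1 branch (branch cost ``b``,
  unpaired bases free);
* ``W``/``Zx``/``Zy`` — exterior segments.

SHAPE pseudo-energies ``ps`` are attached to the stack transition: each
stack adds ps over all four participating nucleotides, so helix-interior
nucleotides are counted once per stack they join (twice for interior
positions), matching the standard pseudo-energy convention.

The partition function is computed in per-nucleotide rescaled form: every
stored cell carries a factor kappa**span, with kappa chosen from the MFE so
that magnitudes stay finite for long windows; the rescaling cancels exactly
in the pair-probability ratio.  Interior loops are capped at
``max_interior`` unpaired nucleotides (a model constraint, as in standard
implementations); structures containing a larger interior loop are
excluded from both the MFE and the partition function.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e30


@njit(cache=True)
def _interior_energy(u1, u2, bu, it, asym_coef, asym_max):
    """Bulge / internal loop penalty (u1, u2 >= 0, not both zero)."""
    if u1 == 0 or u2 == 0:
        return bu[u1 + u2]
    asym = asym_coef * abs(u1 - u2)
    if asym > asym_max:
        asym = asym_max
    return it[u1 + u2] + asym


@njit(cache=True)
def mfe_fill(ptype, ES, hp, bu, it, asym_coef, asym_max, ml_a, ml_b,
             ps, minloop, maxd, max_interior):
    """Fill V (closed), WM (multiloop segment) and W (exterior prefix)."""
    n = ptype.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    W = np.zeros(n + 1)  # W[j+1] = best energy of exterior prefix 0..j
    for span in range(minloop + 1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V: structures closed by pair (i, j) ---
            if ptype[i, j] > 0 and span <= maxd:
                best = hp[span - 1]  # hairpin, loop length j-i-1
                kmax = min(i + max_interior + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    lmin = max(k + minloop + 1, j - 1 - (max_interior - u1))
                    for l in range(j - 1, lmin - 1, -1):
                        if ptype[k, l] == 0 or V[k, l] >= INF:
                            continue
                        u2 = j - l - 1
                        if u1 == 0 and u2 == 0:
                            e = (ES[ptype[i, j], ptype[k, l]]
                                 + ps[i] + ps[j] + ps[k] + ps[l])
                        else:
                            e = _interior_energy(u1, u2, bu, it,
                                                 asym_coef, asym_max)
                        cand = e + V[k, l]
                        if cand < best:
                            best = cand
                # multiloop: a + b + two multiloop sub-segments
                for u in range(i + 1, j - 1):
                    if WM[i + 1, u] < INF and WM[u + 1, j - 1] < INF:
                        cand = ml_a + ml_b + WM[i + 1, u] + WM[u + 1, j - 1]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # --- WM: >= 1 branch in [i, j], unpaired free ---
            best = WM[i + 1, j] if WM[i + 1, j] < INF else INF
            if WM[i, j - 1] < best:
                best = WM[i, j - 1]
            if V[i, j] < INF and V[i, j] + ml_b < best:
                best = V[i, j] + ml_b
            for u in range(i, j):
                if WM[i, u] < INF and WM[u + 1, j] < INF:
                    cand = WM[i, u] + WM[u + 1, j]
                    if cand < best:
                        best = cand
            WM[i, j] = best
    for j in range(n):
        best = W[j]  # position j unpaired
        for u in range(max(0, j - maxd), j):
            if V[u, j] < INF:
                cand = W[u] + V[u, j]
                if cand < best:
                    best = cand
        if j >= minloop + 1 and V[0, j] < INF and V[0, j] < best:
            best = V[0, j]
        W[j + 1] = best
    return V, WM, W


@njit(cache=True)
def pf_inside(ptype, ES, hp, bu, it, asym_coef, asym_max, ml_a, ml_b,
              ps, minloop, maxd, max_interior, RT, kappa):
    """Scaled inside partition function.

    Returns Zb, Zm, Zm1 (all carrying kappa**span), the exterior prefix
    array zx (zx[i] = Z(0..i-1) * kappa**i) and suffix array zy.
    """
    n = ptype.shape[0]
    Zb = np.zeros((n, n))
    Zm = np.zeros((n, n))
    Zm1 = np.zeros((n, n))
    kpow = np.empty(n + 2)
    kpow[0] = 1.0
    for s in range(1, n + 2):
        kpow[s] = kpow[s - 1] * kappa
    beta = np.exp(-ml_b / RT)
    ab2 = np.exp(-(ml_a + ml_b) / RT) * kappa * kappa
    for span in range(minloop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if ptype[i, j] > 0 and span <= maxd:
                z = np.exp(-hp[span - 1] / RT) * kpow[span + 1]
                kmax = min(i + max_interior + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    lmin = max(k + minloop + 1, j - 1 - (max_interior - u1))
                    for l in range(j - 1, lmin - 1, -1):
                        if ptype[k, l] == 0 or Zb[k, l] == 0.0:
                            continue
                        u2 = j - l - 1
                        if u1 == 0 and u2 == 0:
                            e = (ES[ptype[i, j], ptype[k, l]]
                                 + ps[i] + ps[j] + ps[k] + ps[l])
                        else:
                            e = _interior_energy(u1, u2, bu, it,
                                                 asym_coef, asym_max)
                        z += (np.exp(-e / RT) * kpow[u1 + u2 + 2]
                              * Zb[k, l])
                # multiloop closure
                s_ml = 0.0
                for u in range(i + 2, j - 1):
                    if Zm[i + 1, u - 1] > 0.0 and Zm1[u, j - 1] > 0.0:
                        s_ml += Zm[i + 1, u - 1] * Zm1[u, j - 1]
                z += ab2 * s_ml
                Zb[i, j] = z
            # Zm1[i, j]: exactly one branch starting at i, ending <= j
            z1 = Zm1[i, j - 1] * kappa if j - 1 >= i else 0.0
            if Zb[i, j] > 0.0:
                z1 += beta * Zb[i, j]
            Zm1[i, j] = z1
            # Zm[i, j]: >= 1 branch, last branch ends exactly at j, or j unpaired
            zm = Zm[i, j - 1] * kappa if j - 1 >= i else 0.0
            for u in range(max(i, j - maxd), j - minloop):
                if Zb[u, j] > 0.0:
                    prefix = kpow[u - i]
                    if u - 1 >= i:
                        prefix += Zm[i, u - 1]
                    zm += prefix * beta * Zb[u, j]
            Zm[i, j] = zm
    zx = np.empty(n + 1)
    zx[0] = 1.0
    for j in range(n):
        z = zx[j] * kappa
        for u in range(max(0, j - maxd), j + 1):
            if Zb[u, j] > 0.0:
                z += zx[u] * Zb[u, j]
        zx[j + 1] = z
    zy = np.empty(n + 2)
    zy[n] = 1.0
    zy[n + 1] = 1.0
    for i in range(n - 1, -1, -1):
        z = zy[i + 1] * kappa
        for w in range(i, min(n, i + maxd + 1)):
            if Zb[i, w] > 0.0:
                z += Zb[i, w] * zy[w + 1]
        zy[i] = z
    return Zb, Zm, Zm1, zx, zy, kpow


@njit(cache=True)
def pf_outside(ptype, ES, bu, it, asym_coef, asym_max, ml_a, ml_b,
               ps, minloop, maxd, max_interior, RT,
               Zb, Zm, Zm1, zx, zy, kpow):
    """Scaled outside pass; returns the base-pair probability matrix."""
    n = ptype.shape[0]
    kappa = kpow[1]
    beta = np.exp(-ml_b / RT)
    ab2 = np.exp(-(ml_a + ml_b) / RT) * kappa * kappa
    Ob = np.zeros((n, n))
    Om = np.zeros((n, n))
    ObSk = np.zeros((n, n + 1))  # ObSk[k, m] = sum_{l>=m} Ob[k,l] * kappa**(l-m)
    Ztot = zx[n]
    for span in range(n - 1, minloop, -1):
        # --- Om for this span (depends on strictly larger spans) ---
        for i in range(0, n - span):
            j = i + span
            if span > maxd:
                continue
            acc = Om[i, j + 1] * kappa if j + 1 < n else 0.0
            # Zm[i, j] inside Zm[i, j'] via a later branch (j+1, j')
            jmax = min(n - 1, j + 1 + maxd)
            for jp in range(j + minloop + 2, jmax + 1):
                if Zb[j + 1, jp] > 0.0 and Om[i, jp] > 0.0:
                    acc += Om[i, jp] * beta * Zb[j + 1, jp]
            # Zm[k+1, u-1] inside the multiloop of pair (k, l) = (i-1, l)
            if i >= 1:
                k = i - 1
                lmax = min(n - 1, k + maxd)
                for l in range(j + 2 + minloop, lmax + 1):
                    if Ob[k, l] > 0.0 and Zm1[j + 1, l - 1] > 0.0:
                        acc += Ob[k, l] * ab2 * Zm1[j + 1, l - 1]
            Om[i, j] = acc
        # --- Ob for this span ---
        for i in range(0, n - span):
            j = i + span
            if ptype[i, j] == 0 or span > maxd or Zb[i, j] == 0.0:
                ObSk[i, j] = (ObSk[i, j + 1] * kappa) if j + 1 <= n else 0.0
                continue
            acc = zx[i] * zy[j + 1]  # exterior context
            # interior loop of an enclosing pair (k, l)
            kmin = max(0, i - max_interior - 1)
            for k in range(kmin, i):
                u1 = i - k - 1
                lmax = min(n - 1, j + 1 + (max_interior - u1), k + maxd)
                for l in range(j + 1, lmax + 1):
                    if ptype[k, l] == 0 or Ob[k, l] == 0.0:
                        continue
                    u2 = l - j - 1
                    if u1 == 0 and u2 == 0:
                        e = (ES[ptype[k, l], ptype[i, j]]
                             + ps[i] + ps[j] + ps[k] + ps[l])
                    else:
                        e = _interior_energy(u1, u2, bu, it,
                                             asym_coef, asym_max)
                    acc += Ob[k, l] * np.exp(-e / RT) * kpow[u1 + u2 + 2]
            # last branch of a multiloop closed by (k, l), l > j, k <= i-2
            s_ml = 0.0
            for k in range(max(0, i - maxd), i - 1):
                if Zm[k + 1, i - 1] > 0.0 and ObSk[k, j + 1] > 0.0:
                    s_ml += Zm[k + 1, i - 1] * ObSk[k, j + 1]
            acc += ab2 * beta * s_ml
            # non-last branch inside a Zm segment ending at j
            s_m = 0.0
            for ip in range(max(0, i - maxd), i + 1):
                if Om[ip, j] > 0.0:
                    prefix = kpow[i - ip]
                    if i - 1 >= ip:
                        prefix += Zm[ip, i - 1]
                    s_m += Om[ip, j] * prefix
            acc += beta * s_m
            Ob[i, j] = acc
            ObSk[i, j] = acc + (ObSk[i, j + 1] * kappa if j + 1 <= n else 0.0)
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if Zb[i, j] > 0.0 and Ob[i, j] > 0.0:
                p = Ob[i, j] * Zb[i, j] / Ztot
                if p > 1.0:
                    p = min(p, 1.0 + 1e-9)
                P[i, j] = p
                P[j, i] = p
    return P
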