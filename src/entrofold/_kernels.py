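"""Numba kernels for the cubic-time recursions.

All kernels work on a dense, precomputed view of the energy model:

* ``ptype``  -- pair-type matrix (0 = cannot pair or below theta),
* ``hp``     -- hairpin energies incl. per-pair bonus (kcal/mol, BIG if closed
  by a non-pair),
* flat interior-loop tables in kcal/mol,
* ``au_ext`` / ``au_ml`` -- terminal-AU penalties charged to stems facing the
  exterior loop resp. a multiloop,
* multiloop affine coefficients ``a`` (incl. per-pair bonus), ``b``, ``c``.

Energies are plain float64 kcal/mol here; the 0.01 kcal/mol integer grid was
applied when the tables were built.  ``BIG`` marks forbidden motifs; its
Boltzmann factor underflows to exactly zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e9


@njit(cache=True)
def _interior(k: int, l: int, i: int, j: int, seq, ptype,
              stack, bulge, internal, mm_int, mm_1n, mm_23,
              i11, i21, i22, ninio_m, ninio_max, lxc, au_bulge,
              max_loop: int) -> float:
    """Energy of the internal loop between outer pair (k,l), inner (i,j)."""
    pt = ptype[k, l]
    pt2 = ptype[j, i]
    n1 = i - k - 1
    n2 = l - j - 1
    if n1 + n2 > max_loop:
        return BIG
    if n1 >= n2:
        nl, ns = n1, n2
    else:
        nl, ns = n2, n1
    if nl == 0:
        return stack[pt, pt2]
    if ns == 0:
        if nl <= 30:
            e = bulge[nl]
        else:
            e = bulge[30] + np.trunc(lxc * np.log(nl / 30.0)) / 100.0
        if nl == 1:
            e += stack[pt, pt2]
        else:
            if pt > 2:
                e += au_bulge
            if pt2 > 2:
                e += au_bulge
        return e
    si1 = seq[k + 1]
    sj1 = seq[l - 1]
    sp1 = seq[i - 1]
    sq1 = seq[j + 1]
    if ns == 1:
        if nl == 1:
            return i11[pt, pt2, si1, sj1]
        if nl == 2:
            if n1 == 1:
                return i21[pt, pt2, si1, sq1, sj1]
            return i21[pt2, pt, sq1, si1, sp1]
        u = nl + 1
        if u <= 30:
            e = internal[u]
        else:
            e = internal[30] + np.trunc(lxc * np.log(u / 30.0)) / 100.0
        d = (nl - ns) * ninio_m
        if d > ninio_max:
            d = ninio_max
        return e + d + mm_1n[pt, si1, sj1] + mm_1n[pt2, sq1, sp1]
    if ns == 2:
        if nl == 2:
            return i22[pt, pt2, si1, sp1, sq1, sj1]
        if nl == 3:
            return (internal[5] + ninio_m
                    + mm_23[pt, si1, sj1] + mm_23[pt2, sq1, sp1])
    u = nl + ns
    if u <= 30:
        e = internal[u]
    else:
        e = internal[30] + np.trunc(lxc * np.log(u / 30.0)) / 100.0
    d = (nl - ns) * ninio_m
    if d > ninio_max:
        d = ninio_max
    return e + d + mm_int[pt, si1, sj1] + mm_int[pt2, sq1, sp1]


@njit(cache=True)
def fill_inside(n, theta, rt, seq, ptype, hp, au_ext, au_ml,
                stack, bulge, internal, mm_int, mm_1n, mm_23,
                i11, i21, i22, ninio_m, ninio_max, lxc, au_bulge,
                pair_bonus, a, b, c, max_loop, want_q):
    """Inside recursions for Z/ZB/ZM/ZM1 and the energy-weighted Q set."""
    Z = np.zeros((n, n))
    ZB = np.zeros((n, n))
    ZM = np.zeros((n, n))
    ZM1 = np.zeros((n, n))
    Q = np.zeros((n, n))
    QB = np.zeros((n, n))
    QM = np.zeros((n, n))
    QM1 = np.zeros((n, n))
    for i in range(n):
        for j in range(i, min(n, i + theta + 1)):
            Z[i, j] = 1.0
    for d in range(theta + 1, n):
        for i in range(n - d):
            j = i + d
            # --- ZB / QB -------------------------------------------------
            if ptype[i, j] != 0:
                e = hp[i, j]
                if e < 1e8:
                    w = np.exp(-e / rt)
                    ZB[i, j] = w
                    if want_q:
                        QB[i, j] = w * e
                lmax = min(i + max_loop + 1, j - theta - 2)
                for l in range(i + 1, lmax + 1):
                    n1 = l - i - 1
                    rmin = max(l + theta + 1, j - 1 - (max_loop - n1))
                    for r in range(rmin, j):
                        if ptype[l, r] == 0 or ZB[l, r] == 0.0:
                            continue
                        e = _interior(i, j, l, r, seq, ptype, stack, bulge,
                                      internal, mm_int, mm_1n, mm_23,
                                      i11, i21, i22, ninio_m, ninio_max,
                                      lxc, au_bulge, max_loop) + pair_bonus
                        if e >= 1e8:
                            continue
                        w = np.exp(-e / rt)
                        ZB[i, j] += w * ZB[l, r]
                        if want_q:
                            QB[i, j] += w * (e * ZB[l, r] + QB[l, r])
                e0 = a + b + au_ml[i, j]
                w0 = np.exp(-e0 / rt)
                acc = 0.0
                accq = 0.0
                for r in range(i + theta + 3, j - theta - 1):
                    zl = ZM[i + 1, r - 1]
                    zr = ZM1[r, j - 1]
                    if zl == 0.0 or zr == 0.0:
                        continue
                    acc += zl * zr
                    if want_q:
                        accq += QM[i + 1, r - 1] * zr + zl * QM1[r, j - 1]
                ZB[i, j] += w0 * acc
                if want_q:
                    QB[i, j] += w0 * (e0 * acc + accq)
            # --- ZM1 / QM1 -----------------------------------------------
            zm1 = 0.0
            qm1 = 0.0
            for k in range(i + theta + 1, j + 1):
                if ptype[i, k] == 0 or ZB[i, k] == 0.0:
                    continue
                e1 = b + au_ml[i, k] + c * (j - k)
                w = np.exp(-e1 / rt)
                zm1 += w * ZB[i, k]
                if want_q:
                    qm1 += w * (e1 * ZB[i, k] + QB[i, k])
            ZM1[i, j] = zm1
            QM1[i, j] = qm1
            # --- ZM / QM -------------------------------------------------
            zm = 0.0
            qm = 0.0
            for r in range(i, j - theta):
                if ZM1[r, j] == 0.0 and QM1[r, j] == 0.0:
                    continue
                e1 = c * (r - i)
                w = np.exp(-e1 / rt)
                zm += w * ZM1[r, j]
                if want_q:
                    qm += w * (e1 * ZM1[r, j] + QM1[r, j])
            for r in range(i + theta + 2, j - theta):
                if ZM[i, r - 1] == 0.0 or ZM1[r, j] == 0.0:
                    continue
                zm += ZM[i, r - 1] * ZM1[r, j]
                if want_q:
                    qm += QM[i, r - 1] * ZM1[r, j] + ZM[i, r - 1] * QM1[r, j]
            ZM[i, j] = zm
            QM[i, j] = qm
            # --- Z / Q ---------------------------------------------------
            z = Z[i, j - 1]
            q = Q[i, j - 1]
            for k in range(i, j - theta):
                if ptype[k, j] == 0 or ZB[k, j] == 0.0:
                    continue
                e2 = au_ext[k, j]
                w = np.exp(-e2 / rt)
                if k > i:
                    zl = Z[i, k - 1]
                    ql = Q[i, k - 1]
                else:
                    zl = 1.0
                    ql = 0.0
                z += w * zl * ZB[k, j]
                if want_q:
                    q += w * (e2 * zl * ZB[k, j] + ql * ZB[k, j]
                              + zl * QB[k, j])
            Z[i, j] = z
            Q[i, j] = q
    return Z, ZB, ZM, ZM1, Q, QB, QM, QM1


@njit(cache=True)
def fill_outside(n, theta, rt, seq, ptype, Z, ZB, ZM, ZM1, au_ext, au_ml,
                 stack, bulge, internal, mm_int, mm_1n, mm_23,
                 i11, i21, i22, ninio_m, ninio_max, lxc, au_bulge,
                 pair_bonus, a, b, c, max_loop):
    """Outside weights O[i,j]; base-pair probability = O * ZB / Z[0, n-1]."""
    O = np.zeros((n, n))
    Opab = np.zeros((n, n))  # O * Boltzmann(a + b + au) of the closing stem
    Aarr = np.zeros(n)
    Barr = np.zeros(n)
    for i in range(n):
        # left-context accumulators over enclosing pairs (k, l), k < i
        for l in range(n):
            Aarr[l] = 0.0
            Barr[l] = 0.0
        for k in range(0, i):
            if i - 1 >= k + 1 + theta + 1:
                zml = ZM[k + 1, i - 1]
            else:
                zml = 0.0
            wleft = np.exp(-c * (i - k - 1) / rt)
            for l in range(i + theta + 2, n):
                if Opab[k, l] == 0.0:
                    continue
                if zml != 0.0:
                    Aarr[l] += Opab[k, l] * zml
                Barr[l] += Opab[k, l] * wleft
        for j in range(i + theta + 1, n):
            if ptype[i, j] == 0:
                continue
            # exterior context
            zpre = Z[0, i - 1] if i > 0 else 1.0
            zsuf = Z[j + 1, n - 1] if j < n - 1 else 1.0
            val = zpre * zsuf * np.exp(-au_ext[i, j] / rt)
            # enclosed in an internal loop of pair (k, l)
            kmin = max(0, i - max_loop - 1)
            for k in range(kmin, i):
                n1 = i - k - 1
                lmax = min(n - 1, j + 1 + (max_loop - n1))
                for l in range(j + 1, lmax + 1):
                    if ptype[k, l] == 0 or O[k, l] == 0.0:
                        continue
                    e = _interior(k, l, i, j, seq, ptype, stack, bulge,
                                  internal, mm_int, mm_1n, mm_23,
                                  i11, i21, i22, ninio_m, ninio_max,
                                  lxc, au_bulge, max_loop) + pair_bonus
                    if e >= 1e8:
                        continue
                    val += O[k, l] * np.exp(-e / rt)
            # branch of a multiloop closed by some (k, l)
            wbr = np.exp(-(b + au_ml[i, j]) / rt)
            s = 0.0
            for l in range(j + 1, n):
                if Aarr[l] == 0.0 and Barr[l] == 0.0:
                    continue
                if l - 1 >= j + 1 + theta + 1:
                    zmr = ZM[j + 1, l - 1]
                else:
                    zmr = 0.0
                cr = np.exp(-c * (l - 1 - j) / rt)
                s += Aarr[l] * (cr + zmr) + Barr[l] * zmr
            val += wbr * s
            O[i, j] = val
        for l in range(i + theta + 1, n):
            if ptype[i, l] != 0 and O[i, l] != 0.0:
                Opab[i, l] = O[i, l] * np.exp(-(a + b + au_ml[i, l]) / rt)
    return O


@njit(cache=True)
def fill_mfe(n, theta, seq, ptype, hp, au_ext, au_ml,
             stack, bulge, internal, mm_int, mm_1n, mm_23,
             i11, i21, i22, ninio_m, ninio_max, lxc, au_bulge,
             pair_bonus, a, b, c, max_loop):
    """Min-plus analogue of the inside recursions (minimum free energy)."""
    W = np.zeros((n, n))
    V = np.full((n, n), BIG)
    VM = np.full((n, n), BIG)
    VM1 = np.full((n, n), BIG)
    for d in range(theta + 1, n):
        for i in range(n - d):
            j = i + d
            if ptype[i, j] != 0:
                best = hp[i, j]
                lmax = min(i + max_loop + 1, j - theta - 2)
                for l in range(i + 1, lmax + 1):
                    n1 = l - i - 1
                    rmin = max(l + theta + 1, j - 1 - (max_loop - n1))
                    for r in range(rmin, j):
                        if ptype[l, r] == 0 or V[l, r] >= 1e8:
                            continue
                        e = _interior(i, j, l, r, seq, ptype, stack, bulge,
                                      internal, mm_int, mm_1n, mm_23,
                                      i11, i21, i22, ninio_m, ninio_max,
                                      lxc, au_bulge, max_loop) + pair_bonus
                        if e + V[l, r] < best:
                            best = e + V[l, r]
                e0 = a + b + au_ml[i, j]
                for r in range(i + theta + 3, j - theta - 1):
                    if VM[i + 1, r - 1] >= 1e8 or VM1[r, j - 1] >= 1e8:
                        continue
                    cand = e0 + VM[i + 1, r - 1] + VM1[r, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best
            best1 = BIG
            for k in range(i + theta + 1, j + 1):
                if ptype[i, k] == 0 or V[i, k] >= 1e8:
                    continue
                cand = V[i, k] + b + au_ml[i, k] + c * (j - k)
                if cand < best1:
                    best1 = cand
            VM1[i, j] = best1
            bestm = BIG
            for r in range(i, j - theta):
                if VM1[r, j] >= 1e8:
                    continue
                cand = c * (r - i) + VM1[r, j]
                if cand < bestm:
                    bestm = cand
            for r in range(i + theta + 2, j - theta):
                if VM[i, r - 1] >= 1e8 or VM1[r, j] >= 1e8:
                    continue
                cand = VM[i, r - 1] + VM1[r, j]
                if cand < bestm:
                    bestm = cand
            VM[i, j] = bestm
            bw = W[i, j - 1]
            for k in range(i, j - theta):
                if ptype[k, j] == 0 or V[k, j] >= 1e8:
                    continue
                left = W[i, k - 1] if k > i else 0.0
                cand = left + V[k, j] + au_ext[k, j]
                if cand < bw:
                    bw = cand
            W[i, j] = bw
    return W, V, VM, VM1
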