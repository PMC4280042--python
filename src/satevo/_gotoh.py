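"""Numba kernels for affine-gap pairwise alignment (Gotoh three-state DP).

Sequences are encoded as int8 arrays over {A:0, C:1, G:2, T:3, N:4}.
The affine convention: a gap of length L costs ``gap_open + L * gap_extend``
(opening a gap includes the first extension).  All kernels are deterministic,
including traceback tie-breaking: diagonal, then up (gap in b), then left
(gap in a); within a gap state, closing the gap is preferred over extending.
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int64(-(10**15))

# traceback ops
DIAG = 0
UP = 1  # consume a[i], gap in b
LEFT = 2  # consume b[j], gap in a


@njit(cache=True)
def _fill(a, b, submat, go, ge, local):
    """Fill H/E/F matrices. E = gap in a (left moves), F = gap in b (up)."""
    m = a.shape[0]
    n = b.shape[0]
    H = np.empty((m + 1, n + 1), dtype=np.int64)
    E = np.empty((m + 1, n + 1), dtype=np.int64)
    F = np.empty((m + 1, n + 1), dtype=np.int64)
    H[0, 0] = 0
    E[0, 0] = NEG_INF
    F[0, 0] = NEG_INF
    for j in range(1, n + 1):
        if local:
            H[0, j] = 0
            E[0, j] = NEG_INF
        else:
            E[0, j] = go + j * ge
            H[0, j] = E[0, j]
        F[0, j] = NEG_INF
    for i in range(1, m + 1):
        if local:
            H[i, 0] = 0
            F[i, 0] = NEG_INF
        else:
            F[i, 0] = go + i * ge
            H[i, 0] = F[i, 0]
        E[i, 0] = NEG_INF
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = H[i, j - 1] + go + ge
            t = E[i, j - 1] + ge
            if t > e:
                e = t
            E[i, j] = e
            f = H[i - 1, j] + go + ge
            t = F[i - 1, j] + ge
            if t > f:
                f = t
            F[i, j] = f
            h = H[i - 1, j - 1] + submat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _traceback(H, E, F, a, b, submat, go, ge, local, end_i, end_j):
    """Trace back from (end_i, end_j); returns ops (reversed) and start coords."""
    ops = np.empty(end_i + end_j, dtype=np.int8)
    k = 0
    i = end_i
    j = end_j
    state = 0  # 0=H, 1=E (left/gap-in-a), 2=F (up/gap-in-b)
    while i > 0 or j > 0:
        if state == 0:
            h = H[i, j]
            if local and h == 0:
                break
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + submat[a[i - 1], b[j - 1]]:
                ops[k] = DIAG
                k += 1
                i -= 1
                j -= 1
            elif i > 0 and h == F[i, j]:
                state = 2
            elif j > 0 and h == E[i, j]:
                state = 1
            elif not local and i > 0 and j == 0:
                ops[k] = UP
                k += 1
                i -= 1
            elif not local and j > 0 and i == 0:
                ops[k] = LEFT
                k += 1
                j -= 1
            else:  # pragma: no cover - unreachable on consistent matrices
                break
        elif state == 1:
            ops[k] = LEFT
            k += 1
            # prefer closing the gap (origin H) over extending
            if E[i, j] == H[i, j - 1] + go + ge:
                state = 0
            j -= 1
        else:
            ops[k] = UP
            k += 1
            if F[i, j] == H[i - 1, j] + go + ge:
                state = 0
            i -= 1
    return ops[:k], i, j


@njit(cache=True)
def _local_argmax(H):
    """Coordinates of the maximal cell; smallest i then j on ties."""
    m = H.shape[0]
    n = H.shape[1]
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(m):
        for j in range(n):
            if H[i, j] > best:
                best = H[i, j]
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _score_only_global(a, b, submat, go, ge):
    """Linear-memory global score (used by batch/score-only paths)."""
    m = a.shape[0]
    n = b.shape[0]
    Hp = np.empty(n + 1, dtype=np.int64)
    Fp = np.empty(n + 1, dtype=np.int64)
    Hp[0] = 0
    Fp[0] = NEG_INF
    for j in range(1, n + 1):
        Hp[j] = go + j * ge
        Fp[j] = NEG_INF
    for i in range(1, m + 1):
        h_diag = Hp[0]
        Fp[0] = go + i * ge
        Hp[0] = Fp[0]
        e = NEG_INF
        ai = a[i - 1]
        for j in range(1, n + 1):
            f = Hp[j] + go + ge
            t = Fp[j] + ge
            if t > f:
                f = t
            Fp[j] = f
            e2 = Hp[j - 1] + go + ge
            if e + ge > e2:
                e2 = e + ge
            e = e2
            h = h_diag + submat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            h_diag = Hp[j]
            Hp[j] = h
    return Hp[n]
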