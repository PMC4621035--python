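"""Dynamic-programming kernels over real-valued score matrices.

Both kernels use the affine gap cost g(k) = alpha + beta*(k-1) and a fixed
deterministic traceback tie-break (diagonal, then vertical, then horizontal)
so that identical inputs always yield identical alignments.  Compiled with
numba; matrices are small (protein lengths), the win is the per-cell loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30


@njit(cache=False)
def _fill_local(S, alpha, beta):
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)   # horizontal: gap consuming columns
    F = np.full((n + 1, m + 1), NEG_INF)   # vertical: gap consuming rows
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - alpha
            if E[i, j - 1] - beta > e:
                e = E[i, j - 1] - beta
            E[i, j] = e
            f = H[i - 1, j] - alpha
            if F[i - 1, j] - beta > f:
                f = F[i - 1, j] - beta
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if f > h:
                h = f
            if e > h:
                h = e
            if h < 0.0:
                h = 0.0
            H[i, j] = h
    return H, E, F


@njit(cache=False)
def _traceback(H, E, F, S, alpha, beta, i, j, local):
    # state 0 = H, 1 = E (horizontal), 2 = F (vertical)
    out = np.empty((min(H.shape[0], H.shape[1]), 2), dtype=np.int64)
    k = 0
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if local and h == 0.0:
                break
            if h == H[i - 1, j - 1] + S[i - 1, j - 1]:
                out[k, 0] = i - 1
                out[k, 1] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            elif h == E[i, j]:
                state = 1
            else:
                break  # local zero-floor reached through no move
        elif state == 2:
            if F[i, j] == H[i - 1, j] - alpha:
                state = 0
            i -= 1
        else:
            if E[i, j] == H[i, j - 1] - alpha:
                state = 0
            j -= 1
    return out[:k][::-1].copy()


@njit(cache=False)
def sw_affine_kernel(S, alpha, beta):
    """Best local alignment: returns (score, pairs) with pairs (L, 2)."""
    n, m = S.shape
    H, E, F = _fill_local(S, alpha, beta)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if H[i, j] > best:
                best = H[i, j]
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, np.empty((0, 2), dtype=np.int64)
    pairs = _traceback(H, E, F, S, alpha, beta, bi, bj, True)
    return best, pairs


@njit(cache=False)
def nw_semiglobal_kernel(S, alpha, beta):
    """Global alignment with free end gaps: returns (score, pairs)."""
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)
    F = np.full((n + 1, m + 1), NEG_INF)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - alpha
            if E[i, j - 1] - beta > e:
                e = E[i, j - 1] - beta
            E[i, j] = e
            f = H[i - 1, j] - alpha
            if F[i - 1, j] - beta > f:
                f = F[i - 1, j] - beta
            F[i, j] = f
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if f > h:
                h = f
            if e > h:
                h = e
            H[i, j] = h
    # free trailing gaps: best over last row and last column
    best = NEG_INF
    bi = n
    bj = m
    for j in range(1, m + 1):
        if H[n, j] > best:
            best = H[n, j]
            bi = n
            bj = j
    for i in range(1, n + 1):
        if H[i, m] > best:
            best = H[i, m]
            bi = i
            bj = m
    if best <= NEG_INF / 2:
        return 0.0, np.empty((0, 2), dtype=np.int64)
    pairs = _traceback(H, E, F, S, alpha, beta, bi, bj, False)
    return best, pairs
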