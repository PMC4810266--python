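"""Numba DP kernels for local and profile alignment.

These kernels are deliberately free of Python objects: sequences arrive as
int8 codes over the 21-letter alphabet (20 standard residues + X), the
substitution matrix as an int32 array.  Tie-breaking in the traceback is
fixed (diagonal > up > left) so alignments are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=True)
def sw_align(a, b, matrix, gap_open, gap_extend):
    """Optimal local alignment of coded sequences under affine gaps.

    Gap of length k costs gap_open + k*gap_extend.  Returns
    (score, qstart, qend, sstart, send, matches, columns), coordinates
    1-based inclusive; all zeros if the best score is 0.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), -1000000, dtype=np.int32)  # gap in a (left)
    F = np.full((m + 1, n + 1), -1000000, dtype=np.int32)  # gap in b (up)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 stop,1 diag,2 up,3 left
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 1 = extend
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    go = np.int32(gap_open)
    ge = np.int32(gap_extend)
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - go - ge
            e_ext = E[i, j - 1] - ge
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 0
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] - go - ge
            f_ext = F[i - 1, j] - ge
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 0
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            diag = H[i - 1, j - 1] + matrix[ai, b[j - 1]]
            # priority: diagonal > up (F) > left (E) > stop
            h = np.int32(0)
            p = np.uint8(0)
            if diag >= h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if diag <= 0 and F[i, j] <= 0 and E[i, j] <= 0:
                h = np.int32(0)
                p = 0
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:  # first maximum in row-major order wins
                best = h
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    j = bj
    matches = 0
    columns = 0
    state = 0  # 0=H, 1=E, 2=F
    qend = bi
    send = bj
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: gap in a, consume b
            columns += 1
            ext = ptrE[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:  # F: gap in b, consume a
            columns += 1
            ext = ptrF[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return int(best), i + 1, qend, j + 1, send, matches, columns


@njit(cache=True)
def nw_profile_traceback(S, gap_open, gap_extend):
    """Global affine alignment over a precomputed column-score matrix.

    S[i, j] is the score of aligning column i of profile A with column j of
    profile B.  Returns an array of moves from start to end:
    1 = diagonal, 2 = gap in B (consume A), 3 = gap in A (consume B).
    """
    m = S.shape[0]
    n = S.shape[1]
    NEG = -1e18
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -gap_open - gap_extend * j
        H[0, j] = E[0, j]
        ptrH[0, j] = 3
        ptrE[0, j] = 1
    for i in range(1, m + 1):
        F[i, 0] = -gap_open - gap_extend * i
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 2
        ptrF[i, 0] = 1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 0
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 0
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            h = diag
            p = np.uint8(1)
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            ptrH[i, j] = p
    # traceback
    moves = np.zeros(m + n, dtype=np.uint8)
    k = m + n
    i = m
    j = n
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 1:
                k -= 1
                moves[k] = 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 1
        elif state == 1:
            k -= 1
            moves[k] = 3
            ext = ptrE[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            k -= 1
            moves[k] = 2
            ext = ptrF[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return moves[k:]
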