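"""Smith-Waterman affine-gap kernel (numba-compiled).

Three-matrix recurrence: H holds the best local score ending in a
match/mismatch cell, E the best score ending in a gap that consumes the
reference (a deletion, D, relative to the read), F a gap that consumes the
read (an insertion, I).  A gap of length L costs |gap_open| for its first
base and |gap_extend| for each further base.

Tie-breaking is fully deterministic so output is bit-reproducible:
the best cell is (max score, smallest ref end, smallest read end); cell
moves prefer diagonal over D over I; gap extension is preferred over
re-opening when scores tie.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**9))

# traceback op codes shared with the wrapper
OP_EQ, OP_X, OP_D, OP_I = 0, 1, 2, 3


@njit(cache=True)
def sw_affine(read, ref, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = read.size
    m = ref.size
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, np.int32)
    F = np.full((n + 1, m + 1), NEG_INF, np.int32)
    PH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    PE = np.zeros((n + 1, m + 1), np.uint8)  # 0 open, 1 extend
    PF = np.zeros((n + 1, m + 1), np.uint8)

    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ri = read[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext >= e_open:
                E[i, j] = e_ext
                PE[i, j] = 1
            else:
                E[i, j] = e_open
                PE[i, j] = 0
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext >= f_open:
                F[i, j] = f_ext
                PF[i, j] = 1
            else:
                F[i, j] = f_open
                PF[i, j] = 0
            if ri == ref[j - 1] and ri < 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] + mismatch
            # priority on ties: diagonal > E (D op) > F (I op) > stop
            h = np.int32(0)
            p = np.uint8(0)
            if F[i, j] >= h and F[i, j] > 0:
                h = F[i, j]
                p = np.uint8(3)
            if E[i, j] >= h and E[i, j] > 0:
                h = E[i, j]
                p = np.uint8(2)
            if diag >= h and diag > 0:
                h = diag
                p = np.uint8(1)
            H[i, j] = h
            PH[i, j] = p
            if h > best or (h == best and h > 0 and (j < bj or (j == bj and i < bi))):
                best = h
                bi = i
                bj = j

    # traceback
    ops = np.empty(n + m, np.uint8)
    nops = 0
    i = bi
    j = bj
    state = 0  # 0: H, 1: E, 2: F
    while True:
        if state == 0:
            p = PH[i, j]
            if p == 0 or H[i, j] == 0:
                break
            if p == 1:
                if read[i - 1] == ref[j - 1] and read[i - 1] < 4:
                    ops[nops] = OP_EQ
                else:
                    ops[nops] = OP_X
                nops += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # deletion consuming ref base j
            ops[nops] = OP_D
            nops += 1
            pe = PE[i, j]
            j -= 1
            if pe == 0:
                state = 0
        else:  # insertion consuming read base i
            ops[nops] = OP_I
            nops += 1
            pf = PF[i, j]
            i -= 1
            if pf == 0:
                state = 0
    return best, i, bi, j, bj, ops[:nops][::-1].copy()
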