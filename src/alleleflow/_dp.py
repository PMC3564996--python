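"""Banded overlap-alignment dynamic programming kernel (numba).

Scoring: match +1, mismatch -2, gap -3 (linear).  The alignment starts at
the top-left corner of the implied overlap and ends on the last row or last
column (free end): residues of the longer sequence beyond the overlap are
left unaligned rather than forced into terminal gaps.

Sequences are uint8 code arrays (A=0, C=1, G=2, T=3, N=4); N matches
nothing, including another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
GAP = -3

# traceback / column op codes
OP_MATCH = 0
OP_MISMATCH = 1
OP_DEL = 2  # consumes a (gap in b)
OP_INS = 3  # consumes b (gap in a)

_NEG = np.int64(-(10**9))


@njit(cache=True)
def banded_overlap_align(a, b, band):  # pragma: no cover - exercised via wrapper
    """Align code arrays ``a`` and ``b`` within ``band`` of diagonal 0.

    Returns ``(score, end_i, end_j, ops)`` where ``ops`` is the per-column
    op-code array (OP_* codes) of the optimal path from (0, 0) to
    (end_i, end_j), with the path ending on the last row or column.
    """
    n = a.size
    m = b.size
    width = 2 * band + 1
    H = np.full((n + 1, width), _NEG, dtype=np.int64)
    P = np.zeros((n + 1, width), dtype=np.int8)
    for d in range(width):
        j = d - band
        if 0 <= j <= m:
            H[0, d] = GAP * j
            P[0, d] = OP_INS
    for i in range(1, n + 1):
        for d in range(width):
            j = i + d - band
            if j < 0 or j > m:
                continue
            best = _NEG
            ptr = np.int8(0)
            if j >= 1 and H[i - 1, d] > _NEG:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    v = H[i - 1, d] + MATCH
                    op = OP_MATCH
                else:
                    v = H[i - 1, d] + MISMATCH
                    op = OP_MISMATCH
                if v > best:
                    best = v
                    ptr = np.int8(op)
            if d + 1 < width and H[i - 1, d + 1] > _NEG:
                v = H[i - 1, d + 1] + GAP
                if v > best:
                    best = v
                    ptr = np.int8(OP_DEL)
            if d >= 1 and j >= 1 and H[i, d - 1] > _NEG:
                v = H[i, d - 1] + GAP
                if v > best:
                    best = v
                    ptr = np.int8(OP_INS)
            H[i, d] = best
            P[i, d] = ptr
    # free end: best cell on the last row or the last column, inside the band
    best = _NEG
    bi = 0
    bd = band
    for d in range(width):
        j = n + d - band
        if 0 <= j <= m and H[n, d] > best:
            best = H[n, d]
            bi = n
            bd = d
    for i in range(n + 1):
        d = m - i + band
        if 0 <= d < width and H[i, d] > best:
            best = H[i, d]
            bi = i
            bd = d
    # traceback
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i = bi
    d = bd
    while True:
        j = i + d - band
        if i == 0 and j == 0:
            break
        op = P[i, d]
        ops[k] = op
        k += 1
        if op == OP_MATCH or op == OP_MISMATCH:
            i -= 1
        elif op == OP_DEL:
            i -= 1
            d += 1
        else:
            d -= 1
    # reverse in place
    for t in range(k // 2):
        tmp = ops[t]
        ops[t] = ops[k - 1 - t]
        ops[k - 1 - t] = tmp
    return best, bi, bi + bd - band, ops[:k]
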