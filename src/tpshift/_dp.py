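"""Numba kernels for the path-dependent global DP and the local WT DP.

The global recursion is

    F(i, j) = max( F(i-1, j-1) + w(a(i), n),  F(i, j-1) - d,  F(i-1, j) - d )

over model positions i = 1..N+h (a(i) cycles 1,2,3) and sequence positions
j = 1..N.  The diagonal weight is path dependent: the dinucleotide row
n = s(k) + 4*(s(j) - 1) uses the previous *aligned* sequence base k of the
best path into the predecessor cell, and after q skipped model columns the
weight is read from the skip-1 / skip-2 / parent matrix according to
q mod 3.  The first aligned base of a path (no predecessor base) is scored
with the 3x4 boundary matrix indexed by s(j) alone.  The recursion is
greedy (Viterbi-like): one best predecessor is fixed per cell at fill time
and the per-cell path state (last aligned base, pending model-skip count,
gap units spent) is propagated from it.

Tie-breaking: diagonal > gap in S (horizontal) > gap in model (vertical).
Gap moves are refused once the path has spent h gap units, so the budget
is a hard bound and the alignment degrades to gapless rather than failing.

The per-cell state is packed into one int32 --
``lastk | vgap%3 << 18 | move << 20 | gaps << 22`` -- to keep the fill
memory-bound footprint small; this caps N at 2**18-1 nt and h at 511,
far beyond any cds.
"""

import numpy as np
from numba import njit

#: "minus infinity" of the zero row/column; finite so adding -d cannot overflow
NEG = -1.0e9

# move codes stored in the packed state
MOVE_NONE = 0
MOVE_DIAG = 1
MOVE_SKIP_S = 2  # horizontal: sequence base j left unaligned
MOVE_SKIP_MODEL = 3  # vertical: model column i skipped

_LK_MASK = (1 << 18) - 1
MAX_N = _LK_MASK
MAX_H = 511


@njit(cache=True, fastmath=True)
def fill_global(s, w2t, skip1, skip2, boundary, d, h):
    """Fill the global F matrix; returns (F, state).

    ``s`` is the int8 base-code vector (values 1..4).  All matrices are
    float64: w2t/skip1/skip2 are (3, 16), boundary is (3, 4).  ``state``
    packs (last aligned base, model-skip count mod 3, move, gap units).
    """
    N = s.shape[0]
    rows = N + h + 1
    cols = N + 1
    F = np.full((rows, cols), NEG)
    state = np.zeros((rows, cols), np.int32)
    for i in range(0, min(h, rows - 1) + 1):
        F[i, 0] = 0.0
    half_neg = NEG / 2.0
    for j in range(1, cols):
        sj = s[j - 1]
        row_off = 4 * (sj - 1)
        for i in range(1, rows):
            ai = (i - 1) % 3  # 0-based model position a(i) - 1
            best = NEG * 4.0
            move = MOVE_NONE
            fd = F[i - 1, j - 1]
            if fd > half_neg:
                st = state[i - 1, j - 1]
                lk = st & _LK_MASK
                if lk == 0:
                    w = boundary[ai, sj - 1]
                else:
                    n = s[lk - 1] + row_off  # 1..16
                    q = (st >> 18) & 3
                    if q == 0:
                        w = w2t[ai, n - 1]
                    elif q == 1:
                        w = skip1[ai, n - 1]
                    else:
                        w = skip2[ai, n - 1]
                best = fd + w
                move = MOVE_DIAG
            st_h = state[i, j - 1]
            if (st_h >> 22) < h:
                cand = F[i, j - 1] - d
                if cand > best:
                    best = cand
                    move = MOVE_SKIP_S
            st_v = state[i - 1, j]
            if (st_v >> 22) < h:
                cand = F[i - 1, j] - d
                if cand > best:
                    best = cand
                    move = MOVE_SKIP_MODEL
            if move == MOVE_NONE:
                continue  # unreachable cell stays at NEG
            F[i, j] = best
            if move == MOVE_DIAG:
                st = state[i - 1, j - 1]
                new = j | (MOVE_DIAG << 20) | (st & (((1 << 10) - 1) << 22))
            elif move == MOVE_SKIP_S:
                st = state[i, j - 1]
                new = (
                    (st & _LK_MASK)
                    | (st & (3 << 18))
                    | (MOVE_SKIP_S << 20)
                    | ((((st >> 22) & ((1 << 10) - 1)) + 1) << 22)
                )
            else:
                st = state[i - 1, j]
                q = ((st >> 18) & 3) + 1
                if q == 3:
                    q = 0
                new = (
                    (st & _LK_MASK)
                    | (q << 18)
                    | (MOVE_SKIP_MODEL << 20)
                    | ((((st >> 22) & ((1 << 10) - 1)) + 1) << 22)
                )
            state[i, j] = new
    return F, state


@njit(cache=True)
def unpack_move(st):
    return (st >> 20) & 3


@njit(cache=True, fastmath=True)
def global_fmax(s, w2t, skip1, skip2, boundary, d, h):
    """Fmax only: max of F(N..N+h, N), ties resolved toward the smallest i."""
    F, state = fill_global(s, w2t, skip1, skip2, boundary, d, h)
    N = s.shape[0]
    best = F[N, N]
    for i in range(N + 1, N + h + 1):
        if F[i, N] > best:
            best = F[i, N]
    return best


@njit(cache=True, fastmath=True)
def fill_local_wt(s, wt, d, h):
    """Local DP of the sequence against the periodic WT(3, 4) model.

    E(i, j) = max(0, E(i-1, j-1) + WT(a(i), s(j)), E(i, j-1) - d, E(i-1, j) - d)

    Returns (E, ptr) with ptr move codes as in the global DP (0 marks a
    fresh segment start).
    """
    N = s.shape[0]
    rows = N + h + 1
    cols = N + 1
    E = np.zeros((rows, cols))
    ptr = np.zeros((rows, cols), np.int8)
    for j in range(1, cols):
        sj = s[j - 1]
        for i in range(1, rows):
            ai = (i - 1) % 3
            best = 0.0
            move = MOVE_NONE
            cand = E[i - 1, j - 1] + wt[ai, sj - 1]
            if cand > best:
                best = cand
                move = MOVE_DIAG
            cand = E[i, j - 1] - d
            if cand > best:
                best = cand
                move = MOVE_SKIP_S
            cand = E[i - 1, j] - d
            if cand > best:
                best = cand
                move = MOVE_SKIP_MODEL
            E[i, j] = best
            ptr[i, j] = move
    return E, ptr
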