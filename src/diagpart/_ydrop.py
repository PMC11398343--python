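"""Banded y-drop gapped extension (affine gaps, vectorized rows).

The DP aligns prefixes of ``t`` against prefixes of ``q`` starting from the
cell (0, 0) — the anchor.  Cell (i, j) holds the best score of an alignment
of ``t[:i]`` vs ``q[:j]``; cells whose score falls more than ``y_drop``
below the best score seen so far are abandoned, so the live window of each
row stays narrow and the whole computation is linear in (rows x band).

Rows are computed with numpy.  The within-row affine horizontal recurrence
is vectorized with the prefix-max identity
``E[j] = max_{j'<j}(Hn[j'] + e*j') - open - e*j``, valid because closing
and immediately reopening a horizontal gap is never optimal, so a
horizontal run always originates from a diagonal- or vertical-scored cell.

Tie-breaking is explicit and direction-dependent: on equal scores the
caller chooses whether a vertical step (gap character in the query,
consuming target) or a horizontal step (gap in the target, consuming
query) is preferred after the diagonal.  Forward and backward extensions
of one anchor use opposite preferences, mirroring the asymmetry of the
production aligner's forward/reverse tiebreakers.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = ["ExtensionResult", "ydrop_extend"]

_NEG = -(1 << 40)
_DEAD = _NEG // 2  # anything below this is treated as unreachable

# traceback pointer codes
_DIAG = 0
_VERT = 1
_HORZ = 2


class ExtensionResult(NamedTuple):
    score: int
    # aligned base pairs (i, j), 0-based into t and q, ascending
    pairs: list[tuple[int, int]]
    end: tuple[int, int]
    cells: int


class _Row(NamedTuple):
    lo: int
    c_full: np.ndarray  # chosen move for H
    c_noe: np.ndarray   # chosen move for max(D, F): origin of a horizontal run
    f_open: np.ndarray  # vertical state: True if the run opens here
    h_start: np.ndarray  # column where the chosen horizontal run begins


def ydrop_extend(
    t: np.ndarray,
    q: np.ndarray,
    matrix: np.ndarray,
    gap_open: int,
    gap_extend: int,
    y_drop: int,
    prefer_horizontal: bool,
) -> ExtensionResult:
    """Extend from (0, 0) over ``t`` x ``q``; returns the best-cell traceback.

    ``prefer_horizontal`` selects the tie order among equal-scoring moves:
    False -> diagonal, then vertical, then horizontal (forward extension);
    True  -> diagonal, then horizontal, then vertical (backward extension).
    The best cell is the highest-scoring one, ties resolved to the smallest
    row then the smallest column.
    """
    n, m = len(t), len(q)
    if y_drop > gap_open:
        reach = min(m, (y_drop - gap_open) // max(gap_extend, 1))
    else:
        reach = 0

    best = 0
    best_cell = (0, 0)
    cells = 0
    rows: list[_Row] = []

    # row 0: only horizontal gap runs from the origin
    hi = reach
    W = hi + 1
    js = np.arange(0, hi + 1, dtype=np.int64)
    H_prev = np.where(js == 0, 0, -gap_open - gap_extend * js)
    F_prev = np.full(W, _NEG, dtype=np.int64)
    c_full0 = np.full(W, _HORZ, dtype=np.int8)
    c_full0[0] = _DIAG  # sentinel, never read at (0, 0)
    rows.append(
        _Row(0, c_full0, np.zeros(W, dtype=np.int8), np.zeros(W, dtype=bool),
             np.zeros(W, dtype=np.int64))
    )
    cells += W
    lo_prev, hi_prev = 0, hi

    for i in range(1, n + 1):
        lo = lo_prev
        hi = min(m, hi_prev + 1 + reach)
        if lo > hi or lo > m:
            break
        W = hi - lo + 1
        js = np.arange(lo, hi + 1, dtype=np.int64)
        cells += W

        # previous-row values aligned to this row's window (lo == lo_prev)
        Hp = np.full(W, _NEG, dtype=np.int64)
        Fp = np.full(W, _NEG, dtype=np.int64)
        b = min(hi, hi_prev) - lo
        Hp[: b + 1] = H_prev[: b + 1]
        Fp[: b + 1] = F_prev[: b + 1]

        # diagonal: D[j] = Hp[j-1] + s(t[i-1], q[j-1]); the cell left of lo
        # belongs to the dead region, so D is defined for j >= lo+1 only
        D = np.full(W, _NEG, dtype=np.int64)
        if W >= 2:
            sub = matrix[t[i - 1], q[lo : hi]]
            D[1:] = Hp[:-1] + sub
            np.copyto(D, _NEG, where=np.concatenate(([True], Hp[:-1] < _DEAD)))

        # vertical (gap character in the query)
        open_src = Hp - gap_open
        f_open = open_src >= Fp
        F = np.where(f_open, open_src, Fp) - gap_extend
        np.copyto(F, _NEG, where=(Hp < _DEAD) & (Fp < _DEAD))

        Hn = np.maximum(D, F)
        c_noe = np.where(D >= F, _DIAG, _VERT).astype(np.int8)

        # horizontal (gap in the target) via exclusive prefix max
        G = np.where(Hn < _DEAD, _NEG, Hn + gap_extend * js)
        Pincl = np.maximum.accumulate(G)
        E = np.full(W, _NEG, dtype=np.int64)
        h_start = np.zeros(W, dtype=np.int64)
        if W > 1:
            prev_max = Pincl[:-1]
            E[1:] = np.where(prev_max < _DEAD, _NEG,
                             prev_max - gap_open - gap_extend * js[1:])
            shifted = np.concatenate(([np.int64(_NEG - 1)], prev_max))
            starts = np.where(G > shifted, js, np.int64(-1))
            run_origin = np.maximum.accumulate(starts)
            h_start[1:] = run_origin[:-1]

        if prefer_horizontal:
            EF = np.maximum(E, F)
            H = np.maximum(D, EF)
            c_full = np.where(
                D >= EF, _DIAG, np.where(E >= F, _HORZ, _VERT)
            ).astype(np.int8)
        else:
            H = np.maximum(Hn, E)
            c_full = np.where(Hn >= E, c_noe, _HORZ).astype(np.int8)

        row_best = int(H.max())
        if row_best > best:
            best = row_best
            best_cell = (i, lo + int(np.argmax(H)))

        rows.append(_Row(lo, c_full, c_noe, f_open, h_start))

        alive_h = H > best - y_drop
        alive_f = F > best - y_drop
        alive = alive_h | alive_f
        if not alive.any():
            break
        H = np.where(alive_h, H, _NEG)
        F = np.where(alive_f, F, _NEG)
        first = int(np.argmax(alive))
        last = W - 1 - int(np.argmax(alive[::-1]))
        lo_prev = lo + first
        hi_prev = lo + last
        H_prev = H[first : last + 1]
        F_prev = F[first : last + 1]
        if lo_prev > m:
            break

    pairs = _traceback(rows, best_cell)
    return ExtensionResult(best, pairs, best_cell, cells)


def _traceback(rows: list[_Row], best_cell: tuple[int, int]) -> list[tuple[int, int]]:
    i, j = best_cell
    state = "H"
    pairs: list[tuple[int, int]] = []
    while not (i == 0 and j == 0):
        row = rows[i]
        col = j - row.lo
        if state in ("H", "NOE"):
            move = row.c_full[col] if state == "H" else row.c_noe[col]
            if move == _DIAG:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
                state = "H"
            elif move == _VERT:
                state = "F"
            else:  # horizontal run back to its origin cell, scored from max(D, F)
                j = int(row.h_start[col])
                state = "NOE" if i > 0 else "H"
        else:  # state F: vertical run
            opened = bool(row.f_open[col])
            i -= 1
            state = "H" if opened else "F"
    pairs.reverse()
    return pairs
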