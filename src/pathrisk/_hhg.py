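"""Fast univariate HHG dependence statistic.

The statistic sums, over every ordered pair (i, j), the Pearson chi-square
of the 2x2 table that classifies the remaining N-2 points k by whether
|x_i - x_k| <= |x_i - x_j| and |y_i - y_k| <= |y_i - y_j|.  A literal
implementation is O(N^4); this module computes the identical quantity in
roughly O(N^2 log N) by, for each focal point i, sweeping the other points
in order of increasing x-distance while maintaining a bitset indexed by
y-distance rank, so that each table's dominance count A11 is a prefix
popcount.  Ties (which winsorized scores produce in bulk) are handled by
processing equal-distance groups atomically: "<=" classification means a
point's whole tie group is counted on the "close" side.

Only y changes across permutations of the pairing, so the permutation-batch
entry point builds the x-side distance orders once and reuses all buffers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["hhg_statistic_fast", "hhg_perm_stats"]

_ONE = np.uint64(1)
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)
_C55 = np.uint64(0x5555555555555555)
_C33 = np.uint64(0x3333333333333333)
_C0F = np.uint64(0x0F0F0F0F0F0F0F0F)
_C01 = np.uint64(0x0101010101010101)


@njit(cache=True, inline="always")
def _popcount(w):
    w = w - ((w >> np.uint64(1)) & _C55)
    w = (w & _C33) + ((w >> np.uint64(2)) & _C33)
    w = (w + (w >> np.uint64(4))) & _C0F
    return np.int64((w * _C01) >> np.uint64(56))


@njit(cache=True)
def _dist_orders_into(v, sv, pos, dbuf, order, grp_last):
    """Per focal point i: indices k != i by ascending |v_i - v_k|.

    Fills order[i, t] (t-th closest point to i) and grp_last[i, t] (last
    member of each equal-distance group) via an outward two-pointer merge
    over the globally sorted values: O(N^2) after one sort.
    """
    n = v.shape[0]
    for t in range(n):
        pos[sv[t]] = t
    for i in range(n):
        vi = v[i]
        left = pos[i] - 1
        right = pos[i] + 1
        c = 0
        while c < n - 1:
            if left >= 0 and (right >= n or vi - v[sv[left]] <= v[sv[right]] - vi):
                order[i, c] = sv[left]
                dbuf[c] = vi - v[sv[left]]
                left -= 1
            else:
                order[i, c] = sv[right]
                dbuf[c] = v[sv[right]] - vi
                right += 1
            c += 1
        for t in range(n - 2):
            grp_last[i, t] = dbuf[t] != dbuf[t + 1]
        grp_last[i, n - 2] = True


@njit(cache=True)
def _hhg_core(ordx, xlast, ordy, ylast, words, wcnt, ry_slot, ry_max):
    n = ordx.shape[0]
    m = n - 1  # points other than the focal one
    nw = (m + 63) // 64
    total = 0.0
    nm2 = n - 2
    fnm2 = float(nm2)
    for i in range(n):
        for t in range(m):
            ry_slot[ordy[i, t]] = t
        g = 0
        for t in range(m):
            if ylast[i, t]:
                for u in range(g, t + 1):
                    ry_max[ordy[i, u]] = t
                g = t + 1
        for w in range(nw):
            words[w] = np.uint64(0)
            wcnt[w] = 0
        t = 0
        while t < m:
            e = t
            while not xlast[i, e]:
                e += 1
            # insert the whole equal-dx group, then answer its queries
            for u in range(t, e + 1):
                sl = ry_slot[ordx[i, u]]
                words[sl >> 6] |= _ONE << np.uint64(sl & 63)
                wcnt[sl >> 6] += 1
            s_cnt = e + 1
            for u in range(t, e + 1):
                j = ordx[i, u]
                mx = ry_max[j]
                wi = mx >> 6
                c = np.int64(0)
                for w in range(wi):
                    c += wcnt[w]
                c += _popcount(words[wi] & (_FULL >> np.uint64(63 - (mx & 63))))
                a11 = c - 1
                a1 = s_cnt - 1          # row margin: dx <= dx_ij
                ac1 = mx                # col margin: dy <= dy_ij
                a12 = a1 - a11
                a21 = ac1 - a11
                a22 = nm2 - a11 - a12 - a21
                a2 = nm2 - a1
                ac2 = nm2 - ac1
                if a1 > 0 and a2 > 0 and ac1 > 0 and ac2 > 0:
                    num = float(a12 * a21 - a11 * a22)
                    total += fnm2 * num * num / (
                        float(a1) * float(a2) * float(ac1) * float(ac2)
                    )
            t = e + 1
    return total


@njit(cache=True)
def _hhg_stat(x, y):
    n = x.shape[0]
    pos = np.empty(n, np.int64)
    dbuf = np.empty(n - 1, np.float64)
    ordx = np.empty((n, n - 1), np.int32)
    xlast = np.empty((n, n - 1), np.bool_)
    ordy = np.empty((n, n - 1), np.int32)
    ylast = np.empty((n, n - 1), np.bool_)
    _dist_orders_into(x, np.argsort(x, kind="mergesort"), pos, dbuf, ordx, xlast)
    _dist_orders_into(y, np.argsort(y, kind="mergesort"), pos, dbuf, ordy, ylast)
    words = np.empty((n + 62) // 64, np.uint64)
    wcnt = np.empty((n + 62) // 64, np.int64)
    ry_slot = np.empty(n, np.int64)
    ry_max = np.empty(n, np.int64)
    return _hhg_core(ordx, xlast, ordy, ylast, words, wcnt, ry_slot, ry_max)


@njit(cache=True)
def _hhg_perm_batch(x, y, perms):
    n = x.shape[0]
    pos = np.empty(n, np.int64)
    dbuf = np.empty(n - 1, np.float64)
    ordx = np.empty((n, n - 1), np.int32)
    xlast = np.empty((n, n - 1), np.bool_)
    ordy = np.empty((n, n - 1), np.int32)
    ylast = np.empty((n, n - 1), np.bool_)
    _dist_orders_into(x, np.argsort(x, kind="mergesort"), pos, dbuf, ordx, xlast)
    words = np.empty((n + 62) // 64, np.uint64)
    wcnt = np.empty((n + 62) // 64, np.int64)
    ry_slot = np.empty(n, np.int64)
    ry_max = np.empty(n, np.int64)
    # permuting the pairing only permutes y; sort y once and push the
    # permutation through the sorted order instead of re-sorting each time
    sy = np.argsort(y, kind="mergesort")
    yy = np.empty(n, np.float64)
    syy = np.empty(n, np.int64)
    inv = np.empty(n, np.int64)
    nb = perms.shape[0]
    out = np.empty(nb, np.float64)
    for b in range(nb):
        p = perms[b]
        for k in range(n):
            yy[k] = y[p[k]]
            inv[p[k]] = k
        for t in range(n):
            syy[t] = inv[sy[t]]
        _dist_orders_into(yy, syy, pos, dbuf, ordy, ylast)
        out[b] = _hhg_core(ordx, xlast, ordy, ylast, words, wcnt, ry_slot, ry_max)
    return out


def hhg_statistic_fast(x: np.ndarray, y: np.ndarray) -> float:
    """HHG sum statistic T for two equal-length 1-d samples."""
    x = np.ascontiguousarray(x, np.float64)
    y = np.ascontiguousarray(y, np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if x.shape[0] < 3:
        raise ValueError("HHG needs at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("HHG input must be finite")
    return float(_hhg_stat(x, y))


def hhg_perm_stats(x: np.ndarray, y: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """HHG statistics for a batch of permuted pairings (x_k, y[perm[k]])."""
    return _hhg_perm_batch(
        np.ascontiguousarray(x, np.float64),
        np.ascontiguousarray(y, np.float64),
        np.ascontiguousarray(perms, np.int64),
    )
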