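"""Recursive adaptive-partition mutual-information core.

Darbellay–Vajda style estimator generalized to vector arguments: the joint
rank (copula) space of (X, Y) is recursively partitioned into boxes, and a
cell is refined only while a chi-square test still rejects independence of
the X block and the Y block inside it.  Each refinement is a 4-way split:
one cut coordinate is chosen in the X block and one in the Y block (the
pair with the largest 2x2 independence chi-square), each cut at the cell's
conditional median, so child occupancy stays balanced at any
dimensionality.  Following Darbellay's original procedure, a cell that
passes the 2x2 test is additionally probed with a 4x4 quartile grid (9 df)
on the best cut pair before it is accepted as independent, which guards
against dependence a single median cut cannot see.

The MI estimate over terminal cells C is

    sum_C  (n_C / N) * log2( n_C * N / (n_C^X * n_C^Y) )

where ``n_C^X`` counts points whose X coordinates fall in C's X box
irrespective of Y (and symmetrically for ``n_C^Y``).  The X-box and Y-box
membership sets are carried down the recursion and filtered at each cut,
so no global rescan is needed.  An unsplit root gives exactly 0 bits,
which is the correct answer under independence.

The hot loop is numba-compiled; a pure-NumPy twin keeps the package
importable (and the algorithm auditable) if numba is unavailable.
"""

from __future__ import annotations

import numpy as np


def _best_cut_pair(xs: np.ndarray, ys: np.ndarray, crit1: float, crit9: float):
    """Choose the (x, y) cut-coordinate pair with the largest 2x2
    independence chi-square at the conditional medians; fall back to a 4x4
    quartile test on that pair.  Returns (reject, bi, bj, cx, cy)."""
    nc = xs.shape[0]
    xmed = np.median(xs, axis=0)
    ymed = np.median(ys, axis=0)
    ax = xs > xmed[np.newaxis, :]
    by = ys > ymed[np.newaxis, :]
    n11 = ax.astype(float).T @ by.astype(float)
    rx = ax.sum(axis=0).astype(float)
    ry = by.sum(axis=0).astype(float)
    best = -1.0
    bi = bj = -1
    for i in range(xs.shape[1]):
        for j in range(ys.shape[1]):
            e11 = rx[i] * ry[j] / nc
            e10 = rx[i] * (nc - ry[j]) / nc
            e01 = (nc - rx[i]) * ry[j] / nc
            e00 = (nc - rx[i]) * (nc - ry[j]) / nc
            if min(e11, e10, e01, e00) < 1e-12:
                continue
            o11 = n11[i, j]
            o10 = rx[i] - o11
            o01 = ry[j] - o11
            o00 = nc - rx[i] - o01
            chi2 = ((o11 - e11) ** 2 / e11 + (o10 - e10) ** 2 / e10
                    + (o01 - e01) ** 2 / e01 + (o00 - e00) ** 2 / e00)
            if chi2 > best:
                best = chi2
                bi, bj = i, j
    if bi < 0:
        return False, -1, -1, 0.0, 0.0
    reject = best > crit1
    if not reject and nc >= 32:
        qx = np.quantile(xs[:, bi], [0.25, 0.5, 0.75])
        qy = np.quantile(ys[:, bj], [0.25, 0.5, 0.75])
        gi = np.searchsorted(qx, xs[:, bi], side="left")
        gj = np.searchsorted(qy, ys[:, bj], side="left")
        table = np.zeros((4, 4))
        np.add.at(table, (gi, gj), 1.0)
        rows = table.sum(axis=1)
        cols = table.sum(axis=0)
        exp = np.outer(rows, cols) / nc
        ok = exp > 1e-12
        chi2b = float(np.sum((table[ok] - exp[ok]) ** 2 / exp[ok]))
        reject = chi2b > crit9
    return reject, bi, bj, float(xmed[bi]), float(ymed[bj])


def _dv_core(xr, yr, crit1, crit9, min_cell):
    """Pure-NumPy reference implementation (mirrors the jitted core)."""
    n = xr.shape[0]
    all_idx = np.arange(n)
    stack = [(all_idx, all_idx, all_idx)]  # (cell, x-box, y-box) point sets
    mi = 0.0
    while stack:
        cell, xbox, ybox = stack.pop()
        nc = cell.size
        if nc >= 4 * min_cell:
            xs = xr[cell]
            ys = yr[cell]
            reject, bi, bj, cx, cy = _best_cut_pair(xs, ys, crit1, crit9)
            if reject:
                a = xs[:, bi] > cx
                b = ys[:, bj] > cy
                groups = a.astype(int) * 2 + b.astype(int)
                if np.bincount(groups, minlength=4).min() >= min_cell:
                    x_hi = xr[xbox, bi] > cx
                    y_hi = yr[ybox, bj] > cy
                    xparts = (xbox[~x_hi], xbox[x_hi])
                    yparts = (ybox[~y_hi], ybox[y_hi])
                    for g in range(4):
                        stack.append((cell[groups == g],
                                      xparts[g // 2], yparts[g % 2]))
                    continue
        if nc > 0:
            mi += (nc / n) * np.log2(nc * n / (xbox.size * ybox.size))
    return mi


try:
    from numba import njit

    @njit(cache=True)
    def _dv_core_nb(xr, yr, crit1, crit9, min_cell):  # pragma: no cover
        n, dx = xr.shape
        dy = yr.shape[1]
        all_idx = np.arange(n)
        # stack of (cell, xbox, ybox) index arrays
        stack = [(all_idx, all_idx, all_idx)]
        mi = 0.0
        probs = np.array([0.25, 0.5, 0.75])
        while len(stack) > 0:
            cell, xbox, ybox = stack.pop()
            nc = cell.size
            if nc >= 4 * min_cell:
                xs = np.empty((nc, dx))
                ys = np.empty((nc, dy))
                for k in range(nc):
                    p = cell[k]
                    for i in range(dx):
                        xs[k, i] = xr[p, i]
                    for j in range(dy):
                        ys[k, j] = yr[p, j]
                xmed = np.empty(dx)
                for i in range(dx):
                    xmed[i] = np.median(xs[:, i])
                ymed = np.empty(dy)
                for j in range(dy):
                    ymed[j] = np.median(ys[:, j])
                n11 = np.zeros((dx, dy))
                rx = np.zeros(dx)
                ry = np.zeros(dy)
                ax = np.empty(dx, dtype=np.bool_)
                by = np.empty(dy, dtype=np.bool_)
                for k in range(nc):
                    for i in range(dx):
                        ax[i] = xs[k, i] > xmed[i]
                        if ax[i]:
                            rx[i] += 1.0
                    for j in range(dy):
                        by[j] = ys[k, j] > ymed[j]
                        if by[j]:
                            ry[j] += 1.0
                    for i in range(dx):
                        if ax[i]:
                            for j in range(dy):
                                if by[j]:
                                    n11[i, j] += 1.0
                best = -1.0
                bi = -1
                bj = -1
                for i in range(dx):
                    for j in range(dy):
                        e11 = rx[i] * ry[j] / nc
                        e10 = rx[i] * (nc - ry[j]) / nc
                        e01 = (nc - rx[i]) * ry[j] / nc
                        e00 = (nc - rx[i]) * (nc - ry[j]) / nc
                        if e11 < 1e-12 or e10 < 1e-12 or e01 < 1e-12 or e00 < 1e-12:
                            continue
                        o11 = n11[i, j]
                        o10 = rx[i] - o11
                        o01 = ry[j] - o11
                        o00 = nc - rx[i] - o01
                        chi2 = ((o11 - e11) ** 2 / e11 + (o10 - e10) ** 2 / e10
                                + (o01 - e01) ** 2 / e01 + (o00 - e00) ** 2 / e00)
                        if chi2 > best:
                            best = chi2
                            bi = i
                            bj = j
                if bi >= 0:
                    reject = best > crit1
                    if (not reject) and nc >= 32:
                        qx = np.quantile(xs[:, bi], probs)
                        qy = np.quantile(ys[:, bj], probs)
                        table = np.zeros((4, 4))
                        for k in range(nc):
                            gi = 0
                            while gi < 3 and xs[k, bi] > qx[gi]:
                                gi += 1
                            gj = 0
                            while gj < 3 and ys[k, bj] > qy[gj]:
                                gj += 1
                            table[gi, gj] += 1.0
                        chi2b = 0.0
                        for gi in range(4):
                            rtot = 0.0
                            for gj in range(4):
                                rtot += table[gi, gj]
                            for gj in range(4):
                                ctot = 0.0
                                for gk in range(4):
                                    ctot += table[gk, gj]
                                ex = rtot * ctot / nc
                                if ex > 1e-12:
                                    chi2b += (table[gi, gj] - ex) ** 2 / ex
                        reject = chi2b > crit9
                    if reject:
                        cx = xmed[bi]
                        cy = ymed[bj]
                        cnt = np.zeros(4, dtype=np.int64)
                        grp = np.empty(nc, dtype=np.int64)
                        for k in range(nc):
                            g = 0
                            if xs[k, bi] > cx:
                                g += 2
                            if ys[k, bj] > cy:
                                g += 1
                            grp[k] = g
                            cnt[g] += 1
                        if cnt.min() >= min_cell:
                            c0 = np.empty(cnt[0], dtype=np.int64)
                            c1 = np.empty(cnt[1], dtype=np.int64)
                            c2 = np.empty(cnt[2], dtype=np.int64)
                            c3 = np.empty(cnt[3], dtype=np.int64)
                            pos = np.zeros(4, dtype=np.int64)
                            for k in range(nc):
                                g = grp[k]
                                if g == 0:
                                    c0[pos[0]] = cell[k]
                                elif g == 1:
                                    c1[pos[1]] = cell[k]
                                elif g == 2:
                                    c2[pos[2]] = cell[k]
                                else:
                                    c3[pos[3]] = cell[k]
                                pos[g] += 1
                            nxlo = 0
                            for k in range(xbox.size):
                                if xr[xbox[k], bi] <= cx:
                                    nxlo += 1
                            xlo_set = np.empty(nxlo, dtype=np.int64)
                            xhi_set = np.empty(xbox.size - nxlo, dtype=np.int64)
                            plo = 0
                            phi = 0
                            for k in range(xbox.size):
                                if xr[xbox[k], bi] <= cx:
                                    xlo_set[plo] = xbox[k]
                                    plo += 1
                                else:
                                    xhi_set[phi] = xbox[k]
                                    phi += 1
                            nylo = 0
                            for k in range(ybox.size):
                                if yr[ybox[k], bj] <= cy:
                                    nylo += 1
                            ylo_set = np.empty(nylo, dtype=np.int64)
                            yhi_set = np.empty(ybox.size - nylo, dtype=np.int64)
                            plo = 0
                            phi = 0
                            for k in range(ybox.size):
                                if yr[ybox[k], bj] <= cy:
                                    ylo_set[plo] = ybox[k]
                                    plo += 1
                                else:
                                    yhi_set[phi] = ybox[k]
                                    phi += 1
                            stack.append((c0, xlo_set, ylo_set))
                            stack.append((c1, xlo_set, yhi_set))
                            stack.append((c2, xhi_set, ylo_set))
                            stack.append((c3, xhi_set, yhi_set))
                            continue
            if nc > 0:
                mi += (nc / n) * np.log2(nc * n / (xbox.size * ybox.size))
        return mi

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _dv_core_nb = None
    HAVE_NUMBA = False


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Map each column to (0, 1] by its empirical rank (copula transform).

    Ties are broken by position so ranks are distinct, which keeps median
    cuts balanced.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, np.newaxis]
    n = values.shape[0]
    ranks = np.empty_like(values)
    idx = np.argsort(values, axis=0, kind="stable")
    grid = (np.arange(1, n + 1, dtype=float) / n)[:, np.newaxis]
    np.put_along_axis(ranks, idx, np.broadcast_to(grid, values.shape), axis=0)
    return ranks


def adaptive_mi(xr: np.ndarray, yr: np.ndarray, crit1: float, crit9: float,
                min_cell: int) -> float:
    """MI in bits between rank-transformed blocks ``xr`` and ``yr``.

    ``crit1``/``crit9`` are chi-square critical values (1 and 9 df) for the
    refinement tests; ``min_cell`` is the minimum child occupancy.
    """
    xr = np.ascontiguousarray(xr, dtype=np.float64)
    yr = np.ascontiguousarray(yr, dtype=np.float64)
    if HAVE_NUMBA:
        return float(_dv_core_nb(xr, yr, float(crit1), float(crit9), int(min_cell)))
    return float(_dv_core(xr, yr, float(crit1), float(crit9), int(min_cell)))
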