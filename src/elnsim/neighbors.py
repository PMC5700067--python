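"""Fixed-radius neighbor search between two point sets.

A uniform spatial hash with cell size equal to the search radius, built
over the second ("data") set and queried per point of the first set over
its 3x3 cell neighborhood.  Cells are mapped into a power-of-two bucket
table by hashing their integer coordinates, so the structure is insensitive
to the spatial extent of the points (the simulation domain is unbounded);
bucket collisions are resolved by comparing exact cell coordinates, so the
result is exact -- identical to brute-force all-pairs -- and returned in
deterministic (query-major, data-index ascending) order.  The kernel is
numba-compiled: it runs every simulated minute against the activated-APC
population, which reaches tens of thousands of cells in a 30-day run.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["pairs_within", "pairs_within_bruteforce"]

_P1 = np.int64(73856093)
_P2 = np.int64(19349663)


@njit(cache=True)
def _pairs_kernel(qx, qy, dx, dy, radius):
    n_data = dx.size
    n_query = qx.size
    max_pairs = 16
    out_q = np.empty(max_pairs, np.int64)
    out_d = np.empty(max_pairs, np.int64)
    out_r = np.empty(max_pairs, np.float64)
    n_out = 0
    if n_data == 0 or n_query == 0:
        return out_q[:0], out_d[:0], out_r[:0]

    cell = radius
    size = 16
    while size < 2 * n_data:
        size *= 2
    mask = np.int64(size - 1)

    cx = np.empty(n_data, np.int64)
    cy = np.empty(n_data, np.int64)
    bucket = np.empty(n_data, np.int64)
    counts = np.zeros(size + 1, np.int64)
    for i in range(n_data):
        cx[i] = np.int64(np.floor(dx[i] / cell))
        cy[i] = np.int64(np.floor(dy[i] / cell))
        bucket[i] = ((cx[i] * _P1) ^ (cy[i] * _P2)) & mask
        counts[bucket[i] + 1] += 1
    for b in range(size):
        counts[b + 1] += counts[b]
    order = np.empty(n_data, np.int64)
    fill = counts[:-1].copy()
    for i in range(n_data):
        order[fill[bucket[i]]] = i
        fill[bucket[i]] += 1

    r2 = radius * radius
    for q in range(n_query):
        qcx = np.int64(np.floor(qx[q] / cell))
        qcy = np.int64(np.floor(qy[q] / cell))
        for ox in range(-1, 2):
            gx = qcx + ox
            for oy in range(-1, 2):
                gy = qcy + oy
                b = ((gx * _P1) ^ (gy * _P2)) & mask
                for s in range(counts[b], counts[b + 1]):
                    j = order[s]
                    if cx[j] != gx or cy[j] != gy:
                        continue  # bucket collision from another cell
                    ddx = qx[q] - dx[j]
                    ddy = qy[q] - dy[j]
                    d2 = ddx * ddx + ddy * ddy
                    if d2 <= r2:
                        if n_out == max_pairs:
                            max_pairs *= 2
                            nq = np.empty(max_pairs, np.int64)
                            nd = np.empty(max_pairs, np.int64)
                            nr = np.empty(max_pairs, np.float64)
                            nq[:n_out] = out_q[:n_out]
                            nd[:n_out] = out_d[:n_out]
                            nr[:n_out] = out_r[:n_out]
                            out_q, out_d, out_r = nq, nd, nr
                        out_q[n_out] = q
                        out_d[n_out] = j
                        out_r[n_out] = np.sqrt(d2)
                        n_out += 1
    return out_q[:n_out], out_d[:n_out], out_r[:n_out]


def _sorted_pairs(iq, jd, dist):
    # query-major, data-index ascending (kernel emits bucket order per query)
    order = np.lexsort((jd, iq))
    return iq[order], jd[order], dist[order]


def pairs_within(query: np.ndarray, data: np.ndarray, radius: float):
    """All (i, j, distance) with ``query[i]`` within ``radius`` of ``data[j]``.

    The boundary is inclusive.  Pairs come back sorted by query index then
    data index.
    """
    query = np.ascontiguousarray(query, dtype=np.float64).reshape(-1, 2)
    data = np.ascontiguousarray(data, dtype=np.float64).reshape(-1, 2)
    iq, jd, dist = _pairs_kernel(query[:, 0], query[:, 1],
                                 data[:, 0], data[:, 1], float(radius))
    return _sorted_pairs(iq, jd, dist)


def pairs_within_bruteforce(query: np.ndarray, data: np.ndarray, radius: float):
    """O(n m) reference implementation used to verify the spatial hash."""
    query = np.asarray(query, dtype=float).reshape(-1, 2)
    data = np.asarray(data, dtype=float).reshape(-1, 2)
    if query.size == 0 or data.size == 0:
        empty = np.empty(0, np.int64)
        return empty, empty.copy(), np.empty(0, np.float64)
    d = np.linalg.norm(query[:, None, :] - data[None, :, :], axis=-1)
    iq, jd = np.nonzero(d <= radius)
    return iq.astype(np.int64), jd.astype(np.int64), d[iq, jd]
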