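"""Numba-compiled kernels behind enumeration and bulk descriptor scans.

Graphs live here as arrays of adjacency-row bitmasks (``int64``, bit ``v``
of row ``u`` set iff ``u ~ v``), one row vector of length ``n`` per graph.
A whole isomorphism class is identified by its *canonical code*: the
upper-triangle bits of the canonically relabeled adjacency matrix packed
big-endian in graph6 column-major order into one ``int64`` (hence the hard
``n <= 11`` cap on this fast path; the pure-Python engine in
:mod:`topodisc.canonical` has no such cap and computes the identical code).

The canonical search is the same colour-refinement + individualization
backtracking as the Python engine, minimizing the packed code over leaves.
"""

from __future__ import annotations

import numpy as np
import numba as nb
from numba.core import types
from numba.typed import Dict

MAX_FAST_N = 11  # n*(n-1)/2 <= 55 bits must fit an int64 code

_POP = np.array([bin(i).count("1") for i in range(1 << 16)], dtype=np.int64)


@nb.njit(cache=True, inline="always")
def _popcount(x):
    return _POP[x & 0xFFFF] + _POP[(x >> 16) & 0xFFFF]


@nb.njit(cache=True)
def _refine(n, adj, colors):
    """In-place colour refinement; returns the number of colours."""
    keys = np.empty(n, dtype=np.int64)
    cellmask = np.zeros(n, dtype=np.int64)
    # normalize incoming colours to ranks 0..k-1 (individualization passes
    # values up to 2n-1 and the cell indexing below needs values < n)
    order0 = np.argsort(colors, kind="mergesort")
    prev = colors[order0[0]]
    rank = 0
    for i in range(n):
        cur = colors[order0[i]]
        if cur != prev:
            rank += 1
            prev = cur
        keys[order0[i]] = rank
    for v in range(n):
        colors[v] = keys[v]
    while True:
        ncol = 0
        for v in range(n):
            if colors[v] + 1 > ncol:
                ncol = colors[v] + 1
        for c in range(ncol):
            cellmask[c] = 0
        for v in range(n):
            cellmask[colors[v]] |= np.int64(1) << v
        # key(v) = (colour, neighbour count per cell) encoded base n+2;
        # bounded by n * (n+2)^n which fits int64 for n <= 11
        for v in range(n):
            k = colors[v]
            for c in range(ncol):
                k = k * (n + 2) + _popcount(adj[v] & cellmask[c])
            keys[v] = k
        order = np.argsort(keys, kind="mergesort")
        newc = np.empty(n, dtype=np.int64)
        r = 0
        newc[order[0]] = 0
        for i in range(1, n):
            if keys[order[i]] != keys[order[i - 1]]:
                r += 1
            newc[order[i]] = r
        changed = False
        for v in range(n):
            if newc[v] != colors[v]:
                changed = True
            colors[v] = newc[v]
        if not changed or r == n - 1:
            return r + 1


@nb.njit(cache=True)
def _leaf_code(n, adj, colors):
    inv = np.empty(n, dtype=np.int64)
    for v in range(n):
        inv[colors[v]] = v
    code = np.int64(0)
    for j in range(1, n):
        vj = inv[j]
        for i in range(j):
            code = (code << 1) | ((adj[inv[i]] >> vj) & 1)
    return code


@nb.njit  # recursive: numba cannot cache self-recursive functions reliably
def _search(n, adj, colors):
    work = colors.copy()
    while True:
        ncol = _refine(n, adj, work)
        if ncol == n:
            return _leaf_code(n, adj, work)
        sizes = np.zeros(ncol, dtype=np.int64)
        for v in range(n):
            sizes[work[v]] += 1
        best_c = -1
        best_s = n + 1
        for c in range(ncol):
            if 1 < sizes[c] < best_s:
                best_s = sizes[c]
                best_c = c
        cmask = np.int64(0)
        for v in range(n):
            if work[v] == best_c:
                cmask |= np.int64(1) << v
        # interchangeable cell (identical adjacency outside, complete or
        # empty inside): every ordering is automorphic -> discretize in
        # index order instead of branching factorially
        first = -1
        for v in range(n):
            if work[v] == best_c:
                first = v
                break
        outside = adj[first] & ~cmask
        empty = (adj[first] & cmask) == 0
        inter = True
        for v in range(n):
            if work[v] != best_c:
                continue
            if (adj[v] & ~cmask) != outside:
                inter = False
                break
            ins = adj[v] & cmask
            if empty:
                if ins != 0:
                    inter = False
                    break
            elif ins != (cmask & ~(np.int64(1) << v)):
                inter = False
                break
        if inter:
            k = best_s + 1
            i = 0
            for v in range(n):
                work[v] = work[v] * k
            for v in range(n):
                if (cmask >> v) & 1:
                    work[v] += i
                    i += 1
            continue
        break
    best = np.int64(0x7FFFFFFFFFFFFFFF)
    for v in range(n):
        if work[v] == best_c:
            child = np.empty(n, dtype=np.int64)
            for u in range(n):
                child[u] = 2 * work[u]
                if work[u] == best_c and u != v:
                    child[u] += 1
            r = _search(n, adj, child)
            if r < best:
                best = r
    return best


@nb.njit
def canon_code(n, adj):
    """Canonical packed code of one graph (adjacency bitmask rows)."""
    if n == 1:
        return np.int64(0)
    colors = np.zeros(n, dtype=np.int64)
    return _search(n, adj, colors)


@nb.njit(cache=True)
def is_connected(n, adj):
    seen = np.int64(1)
    frontier = np.int64(1)
    full = (np.int64(1) << n) - 1
    while frontier != 0:
        nxt = np.int64(0)
        for v in range(n):
            if (frontier >> v) & 1:
                nxt |= adj[v]
        frontier = nxt & ~seen
        seen |= nxt
        if seen == full:
            return True
    return seen == full


@nb.njit(cache=True)
def decode_code(code, n):
    """Inverse of the packed code: adjacency bitmask rows."""
    adj = np.zeros(n, dtype=np.int64)
    idx = n * (n - 1) // 2 - 1
    for j in range(1, n):
        for i in range(j):
            if (code >> idx) & 1:
                adj[i] |= np.int64(1) << j
                adj[j] |= np.int64(1) << i
            idx -= 1
    return adj


@nb.njit(cache=True)
def decode_codes(codes, n):
    out = np.zeros((codes.shape[0], n), dtype=np.int64)
    for i in range(codes.shape[0]):
        out[i] = decode_code(codes[i], n)
    return out


@nb.njit
def extend_classes(parent_codes, n, connected_only):
    """One vertex-extension level of the exhaustive enumerator.

    Every isomorphism class on ``n`` vertices (connected classes, if
    ``connected_only``) arises from some class on ``n - 1`` vertices by
    attaching one new vertex with some neighbourhood, so extending every
    parent by every neighbourhood and deduplicating canonical codes is
    complete.  Returns the sorted array of canonical codes.
    """
    out = Dict.empty(types.int64, types.boolean)
    m = n - 1
    child = np.zeros(n, dtype=np.int64)
    for pi in range(parent_codes.shape[0]):
        padj = decode_code(parent_codes[pi], m)
        lo = 1 if connected_only else 0
        for nbm in range(lo, 1 << m):
            for i in range(m):
                child[i] = padj[i]
                if (nbm >> i) & 1:
                    child[i] |= np.int64(1) << m
            child[m] = nbm
            if connected_only and not is_connected(n, child):
                continue
            out[canon_code(n, child)] = True
    res = np.empty(len(out), dtype=np.int64)
    i = 0
    for k in out:
        res[i] = k
        i += 1
    return np.sort(res)


# -- bulk descriptor scans ------------------------------------------------


@nb.njit(cache=True)
def degree_stats(masks):
    """Per-graph degree-based sums: M1, M2 (int64), Randic R, modified
    Zagreb, augmented Zagreb (float64), Narumi-Katayama product (int64),
    log-degree-entropy f-sums are left to callers."""
    N, n = masks.shape
    m1 = np.zeros(N, np.int64)
    m2 = np.zeros(N, np.int64)
    nk = np.ones(N, np.int64)
    rn = np.zeros(N, np.float64)
    mz = np.zeros(N, np.float64)
    az = np.zeros(N, np.float64)
    deg = np.zeros(n, np.int64)
    for g in range(N):
        adj = masks[g]
        for v in range(n):
            deg[v] = _popcount(adj[v])
        for v in range(n):
            m1[g] += deg[v] * deg[v]
            nk[g] *= deg[v]
        for u in range(n):
            for v in range(u + 1, n):
                if (adj[u] >> v) & 1:
                    p = deg[u] * deg[v]
                    m2[g] += p
                    rn[g] += 1.0 / np.sqrt(p)
                    mz[g] += 1.0 / p
                    s = deg[u] + deg[v] - 2
                    if s > 0:
                        t = p / s
                        az[g] += t * t * t
                    else:
                        az[g] = np.nan
    return m1, m2, nk, rn, mz, az


@nb.njit(cache=True)
def distance_stats(masks, hlcm):
    """Per-graph distance-based sums from bitmask BFS.

    Returns (W, H_scaled, J, PRS) where W is the Wiener index, H_scaled the
    Harary index times ``hlcm`` (exact int64 when ``hlcm`` is a common
    multiple of 1..diameter, e.g. lcm(1..n-1)), J the Balaban distance
    connectivity index and PRS the log product-of-row-sums
    ``sum_v ln D_v``.
    """
    N, n = masks.shape
    W = np.zeros(N, np.int64)
    H = np.zeros(N, np.int64)
    J = np.zeros(N, np.float64)
    PRS = np.zeros(N, np.float64)
    d = np.zeros((n, n), np.int64)
    D = np.zeros(n, np.int64)
    for g in range(N):
        adj = masks[g]
        for s in range(n):
            for t in range(n):
                d[s, t] = 0
            seen = np.int64(1) << s
            frontier = seen
            dist = 0
            while frontier != 0:
                nxt = np.int64(0)
                for v in range(n):
                    if (frontier >> v) & 1:
                        nxt |= adj[v]
                frontier = nxt & ~seen
                dist += 1
                for v in range(n):
                    if (frontier >> v) & 1:
                        d[s, v] = dist
                seen |= frontier
        m = 0
        for v in range(n):
            m += _popcount(adj[v])
            s = 0
            for u in range(n):
                s += d[v, u]
            D[v] = s
        m //= 2
        w = 0
        h = 0
        for u in range(n):
            for v in range(u + 1, n):
                w += d[u, v]
                h += hlcm // d[u, v]
        W[g] = w
        H[g] = h
        mu = m - n + 1
        acc = 0.0
        prs = 0.0
        for v in range(n):
            prs += np.log(D[v])
        for u in range(n):
            for v in range(u + 1, n):
                if (adj[u] >> v) & 1:
                    acc += 1.0 / np.sqrt(D[u] * D[v])
        J[g] = m / (mu + 1.0) * acc
        PRS[g] = prs
    return W, H, J, PRS


@nb.njit(cache=True)
def dense_adjacency(masks):
    """Stack of dense symmetric 0/1 adjacency matrices, float64."""
    N, n = masks.shape
    A = np.zeros((N, n, n), np.float64)
    for g in range(N):
        for i in range(n):
            row = masks[g, i]
            for j in range(n):
                if (row >> j) & 1:
                    A[g, i, j] = 1.0
    return A
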