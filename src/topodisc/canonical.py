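"""Canonical labeling, isomorphism certificates, orbits and |Aut|.

The canonical form is computed by iterative colour refinement (vertices are
repeatedly re-partitioned by the multiset of neighbour colours) followed by
backtracking individualization over the vertices of the first smallest
non-singleton cell.  Among all leaf labelings the one minimizing the packed
upper-triangle bit string of the permuted adjacency matrix (in graph6
column-major bit order) is the canonical form, so certificate bytes are the
graph6 record of the canonically relabeled graph.

Two graphs receive equal certificates if and only if they are isomorphic.
Automorphism orbits fall out of the same machinery: vertices ``u`` and ``v``
lie in one orbit iff individualizing ``u`` and individualizing ``v`` yield
the same canonical code.  The group order is computed by the
orbit-stabilizer recursion |Aut| = |orbit(v)| * |Stab(v)|, individualizing
one vertex per level.

This is the pure-Python engine, valid for any ``n`` (arbitrary-precision
bitmasks).  The enumeration pipeline uses an independently written numba
kernel (:mod:`topodisc._kernels`) that computes the identical canonical
code for ``n <= 11``; the two are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

from .graph import Graph, write_graph6

__all__ = ["Certificate", "certificate", "canonical_code", "canonical_graph"]


@dataclass(frozen=True)
class Certificate:
    """Canonical identity of an isomorphism class.

    ``bytes_`` is the graph6 record of the canonical relabeling (equal for
    two graphs iff they are isomorphic), ``aut_order`` the order of the
    automorphism group, and ``orbits`` the partition of ``0..n-1`` into
    automorphism orbits (each orbit sorted, orbits sorted by minimum).
    """

    bytes_: bytes
    aut_order: int
    orbits: tuple[tuple[int, ...], ...]


def _refine(n: int, masks, colors: list[int]) -> tuple[list[int], int]:
    """Stable colour refinement; returns (normalized colors, #colors)."""
    # normalize incoming colors to ranks
    ranks = {c: i for i, c in enumerate(sorted(set(colors)))}
    colors = [ranks[c] for c in colors]
    while True:
        ncol = max(colors) + 1
        cellmask = [0] * ncol
        for v in range(n):
            cellmask[colors[v]] |= 1 << v
        keys = [
            (colors[v],) + tuple(
                bin(masks[v] & cellmask[c]).count("1") for c in range(ncol)
            )
            for v in range(n)
        ]
        ranks = {k: i for i, k in enumerate(sorted(set(keys)))}
        new = [ranks[keys[v]] for v in range(n)]
        if new == colors:
            return colors, ncol
        colors = new
        if max(colors) + 1 == n:
            return colors, n


def _leaf_code(n: int, masks, colors: list[int]) -> int:
    inv = [0] * n
    for v in range(n):
        inv[colors[v]] = v
    code = 0
    for j in range(1, n):
        vj = inv[j]
        for i in range(j):
            code = (code << 1) | ((masks[inv[i]] >> vj) & 1)
    return code


def _interchangeable(masks, cell: list[int], cmask: int) -> bool:
    """True if every permutation of ``cell`` is an automorphism of the
    colored graph: identical adjacency outside the cell, and the induced
    subgraph on the cell is complete or empty.  Lets the search discretize
    such cells (duplicate vertices, cliques, independent sets) without
    factorial branching."""
    first = cell[0]
    outside = masks[first] & ~cmask
    inside = masks[first] & cmask
    empty = inside == 0
    for v in cell:
        if (masks[v] & ~cmask) != outside:
            return False
        ins = masks[v] & cmask
        if empty:
            if ins != 0:
                return False
        elif ins != (cmask & ~(1 << v)):
            return False
    return True


def _search(n: int, masks, colors: list[int]) -> int:
    while True:
        colors, ncol = _refine(n, masks, colors)
        if ncol == n:
            return _leaf_code(n, masks, colors)
        sizes = [0] * ncol
        for c in colors:
            sizes[c] += 1
        target = min(
            (c for c in range(ncol) if sizes[c] > 1),
            key=lambda c: (sizes[c], c),
        )
        cell = [v for v in range(n) if colors[v] == target]
        cmask = 0
        for v in cell:
            cmask |= 1 << v
        if _interchangeable(masks, cell, cmask):
            # all orderings of the cell give the same leaf: fix index order
            colors = [c * (len(cell) + 1) for c in colors]
            for i, v in enumerate(cell):
                colors[v] += i
            continue
        break
    best = None
    for v in cell:
        child = [
            2 * colors[u] + (1 if colors[u] == target and u != v else 0)
            for u in range(n)
        ]
        r = _search(n, masks, child)
        if best is None or r < best:
            best = r
    return best


def canonical_code(g: Graph, colors: list[int] | None = None) -> int:
    """Packed upper-triangle bit string of the canonical relabeling.

    ``colors`` optionally constrains the search to colour-preserving
    relabelings (used for individualization; cells are ordered by colour
    value).
    """
    n = g.n
    if n == 1:
        return 0
    if colors is None:
        colors = [0] * n
    return _search(n, g.masks, list(colors))


def canonical_graph(g: Graph) -> Graph:
    """The canonical representative of ``g``'s isomorphism class."""
    code = canonical_code(g)
    n = g.n
    nbits = n * (n - 1) // 2
    edges = []
    idx = nbits - 1
    for j in range(1, n):
        for i in range(j):
            if (code >> idx) & 1:
                edges.append((i, j))
            idx -= 1
    return Graph(n, edges)


def _orbits_under(g: Graph, colors: list[int]) -> list[list[int]]:
    """Orbits of the colour-preserving automorphism group."""
    n = g.n
    sig: dict[tuple[int, int], list[int]] = {}
    for v in range(n):
        child = [2 * c for c in colors]
        child[v] += 1  # individualize v within its cell
        key = (colors[v], canonical_code(g, child))
        sig.setdefault(key, []).append(v)
    return sorted(sig.values())


def _aut_order(g: Graph, colors: list[int]) -> int:
    orbs = _orbits_under(g, colors)
    for orb in orbs:
        if len(orb) > 1:
            v = orb[0]
            child = [2 * c for c in colors]
            child[v] += 1
            return len(orb) * _aut_order(g, child)
    return 1


def certificate(g: Graph) -> Certificate:
    """Canonical certificate with automorphism orbits and group order."""
    n = g.n
    if n == 1:
        return Certificate(write_graph6(g).encode(), 1, ((0,),))
    canon = canonical_graph(g)
    colors = [0] * n
    orbs = tuple(tuple(o) for o in _orbits_under(g, colors))
    order = _aut_order(g, colors)
    return Certificate(write_graph6(canon).encode(), order, orbs)
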