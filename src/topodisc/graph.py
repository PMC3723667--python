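"""Simple undirected graphs with cached structure.

Vertices are the integers ``0..n-1``; edges are unordered pairs with no
self-loops or multi-edges.  Graphs are immutable once built.  The module
also provides the graph6 text codec (the interchange format of the geng
ecosystem), plain edge-list I/O, distance preprocessing (:class:`DistanceData`)
and the standard matrices (adjacency, Laplacian, distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Graph",
    "DistanceData",
    "GraphFormatError",
    "parse_graph6",
    "write_graph6",
    "parse_edgelist",
    "write_edgelist",
    "distance_data",
    "matrix",
    "path_graph",
    "cycle_graph",
    "star_graph",
    "complete_graph",
]


class GraphFormatError(ValueError):
    """Raised for malformed graph6 or edge-list input."""


class Graph:
    """An undirected simple graph on vertices ``0..n-1``.

    Parameters
    ----------
    n:
        Number of vertices (``>= 1``).
    edges:
        Iterable of vertex pairs.  Order within a pair and duplicates are
        normalized away; self-loops are rejected.
    """

    __slots__ = ("n", "edges", "_masks", "_connected")

    def __init__(self, n: int, edges: Iterable[tuple[int, int]] = ()):
        if n < 1:
            raise ValueError(f"vertex count must be >= 1, got {n}")
        norm = set()
        for u, v in edges:
            u, v = int(u), int(v)  # tolerate numpy integers
            if u == v:
                raise ValueError(f"self-loop at vertex {u}")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) outside vertex range [0,{n})")
            norm.add((u, v) if u < v else (v, u))
        self.n = n
        self.edges = frozenset(norm)
        self._masks: tuple[int, ...] | None = None
        self._connected: bool | None = None

    # -- basic structure -------------------------------------------------

    @property
    def m(self) -> int:
        """Edge count."""
        return len(self.edges)

    @property
    def masks(self) -> tuple[int, ...]:
        """Adjacency rows as bitmasks: bit ``v`` of ``masks[u]`` is 1 iff u~v."""
        if self._masks is None:
            rows = [0] * self.n
            for u, v in self.edges:
                rows[u] |= 1 << v
                rows[v] |= 1 << u
            self._masks = tuple(rows)
        return self._masks

    def degree(self, v: int | None = None):
        if v is not None:
            return bin(self.masks[v]).count("1")
        return [bin(r).count("1") for r in self.masks]

    @property
    def connected(self) -> bool:
        if self._connected is None:
            masks = self.masks
            seen = 1
            frontier = 1
            full = (1 << self.n) - 1
            while frontier and seen != full:
                nxt = 0
                f = frontier
                while f:
                    v = (f & -f).bit_length() - 1
                    nxt |= masks[v]
                    f &= f - 1
                frontier = nxt & ~seen
                seen |= nxt
            self._connected = seen == full
        return self._connected

    def relabel(self, perm: Sequence[int]) -> "Graph":
        """Return the graph with vertex ``v`` renamed to ``perm[v]``."""
        return Graph(self.n, [(perm[u], perm[v]) for u, v in self.edges])

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other) -> bool:  # labeled equality, not isomorphism
        return (
            isinstance(other, Graph)
            and self.n == other.n
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.n, self.edges))

    def __repr__(self) -> str:
        return f"Graph(n={self.n}, m={self.m})"


# -- named toy graphs ----------------------------------------------------


def path_graph(n: int) -> Graph:
    return Graph(n, [(i, i + 1) for i in range(n - 1)])


def cycle_graph(n: int) -> Graph:
    if n < 3:
        raise ValueError("cycle needs n >= 3")
    return Graph(n, [(i, (i + 1) % n) for i in range(n)])


def star_graph(n: int) -> Graph:
    """Star on ``n`` vertices: centre 0 joined to the ``n-1`` leaves."""
    return Graph(n, [(0, i) for i in range(1, n)])


def complete_graph(n: int) -> Graph:
    return Graph(n, [(i, j) for i in range(n) for j in range(i + 1, n)])


# -- graph6 codec --------------------------------------------------------
#
# Short-form graph6 (n <= 62): one printable byte chr(n+63), then the upper
# triangle of the adjacency matrix in column-major order (x01, x02, x12,
# x03, ...) packed big-endian into 6-bit groups, each offset by 63.


def _g6_bits(record: str) -> tuple[int, list[int]]:
    if not record:
        raise GraphFormatError("empty graph6 record")
    for off, ch in enumerate(record):
        o = ord(ch)
        if not (63 <= o <= 126):
            raise GraphFormatError(
                f"non-printable graph6 byte {o!r} at offset {off}"
            )
    n = ord(record[0]) - 63
    if n == 63:
        raise GraphFormatError(
            "long-form graph6 (n > 62) is not supported"
        )
    nbits = n * (n - 1) // 2
    need = (nbits + 5) // 6
    body = record[1:]
    if len(body) != need:
        raise GraphFormatError(
            f"graph6 record for n={n} needs {need} body bytes, got "
            f"{len(body)} (offset {len(record)})"
        )
    bits = []
    for ch in body:
        x = ord(ch) - 63
        bits.extend((x >> k) & 1 for k in range(5, -1, -1))
    if any(bits[nbits:]):
        raise GraphFormatError("nonzero padding bits in graph6 record")
    return n, bits[:nbits]


def parse_graph6(text: str) -> Graph:
    """Parse a one-line short-form graph6 record (optionally ``>>graph6<<``-prefixed)."""
    record = text.strip()
    if record.startswith(">>graph6<<"):
        record = record[len(">>graph6<<"):]
    n, bits = _g6_bits(record)
    edges = []
    idx = 0
    for j in range(1, n):
        for i in range(j):
            if bits[idx]:
                edges.append((i, j))
            idx += 1
    return Graph(n, edges)


def write_graph6(g: Graph) -> str:
    """Encode a graph as a short-form graph6 record."""
    if g.n > 62:
        raise GraphFormatError("short-form graph6 supports n <= 62 only")
    masks = g.masks
    bits = []
    for j in range(1, g.n):
        for i in range(j):
            bits.append((masks[i] >> j) & 1)
    while len(bits) % 6:
        bits.append(0)
    out = [chr(g.n + 63)]
    for k in range(0, len(bits), 6):
        x = 0
        for b in bits[k : k + 6]:
            x = (x << 1) | b
        out.append(chr(x + 63))
    return "".join(out)


# -- edge-list I/O -------------------------------------------------------


def parse_edgelist(text: str, n: int | None = None) -> Graph:
    """Parse a plain edge list, one 0-based ``u v`` pair per line.

    ``n`` defaults to 1 + the largest vertex mentioned.
    """
    edges = []
    top = -1
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphFormatError(f"line {lineno}: expected 'u v', got {line!r}")
        u, v = (int(p) for p in parts)
        top = max(top, u, v)
        edges.append((u, v))
    if n is None:
        n = top + 1 if top >= 0 else 1
    return Graph(n, edges)


def write_edgelist(g: Graph) -> str:
    return "\n".join(f"{u} {v}" for u, v in sorted(g.edges)) + "\n"


# -- distances -----------------------------------------------------------


@dataclass(frozen=True)
class DistanceData:
    """Shortest-path (hop) structure of a connected graph.

    Attributes
    ----------
    d:
        ``n x n`` integer matrix of shortest-path lengths.
    rowsum:
        Per-vertex distance sums ``D_v = sum_u d(v, u)``.
    ecc:
        Per-vertex eccentricities.
    spheres:
        ``spheres[v][k-1] = |S_k(v)|``, the number of vertices at exact
        distance ``k`` from ``v`` for ``k = 1..ecc(v)``.
    diameter:
        ``max_v ecc(v)``.
    """

    d: np.ndarray
    rowsum: tuple[int, ...]
    ecc: tuple[int, ...]
    spheres: tuple[tuple[int, ...], ...]
    diameter: int = field(default=0)


def distance_data(g: Graph) -> DistanceData:
    """BFS-exact hop distances and derived per-vertex summaries.

    Raises
    ------
    ValueError
        If the graph is disconnected (distances undefined; callers must
        filter rather than rely on an infinite-distance convention).
    """
    if not g.connected:
        raise ValueError("distance_data requires a connected graph")
    n = g.n
    masks = g.masks
    d = np.zeros((n, n), dtype=np.int64)
    for s in range(n):
        seen = 1 << s
        frontier = seen
        dist = 0
        while frontier:
            nxt = 0
            f = frontier
            while f:
                v = (f & -f).bit_length() - 1
                nxt |= masks[v]
                f &= f - 1
            frontier = nxt & ~seen
            dist += 1
            f = frontier
            while f:
                v = (f & -f).bit_length() - 1
                d[s, v] = dist
                f &= f - 1
            seen |= frontier
    rowsum = tuple(int(x) for x in d.sum(axis=1))
    ecc = tuple(int(x) for x in d.max(axis=1))
    spheres = tuple(
        tuple(int((d[v] == k).sum()) for k in range(1, ecc[v] + 1))
        for v in range(n)
    )
    return DistanceData(d=d, rowsum=rowsum, ecc=ecc, spheres=spheres,
                        diameter=max(ecc))


_MATRIX_KINDS = ("adjacency", "laplacian", "distance")


def matrix(g: Graph, kind: str) -> np.ndarray:
    """Return the adjacency, Laplacian (``Deg - A``) or distance matrix."""
    if kind not in _MATRIX_KINDS:
        raise ValueError(
            f"unknown matrix kind {kind!r}; supported: {', '.join(_MATRIX_KINDS)}"
        )
    n = g.n
    if kind == "distance":
        return distance_data(g).d.astype(np.float64)
    a = np.zeros((n, n), dtype=np.float64)
    for u, v in g.edges:
        a[u, v] = a[v, u] = 1.0
    if kind == "adjacency":
        return a
    lap = -a
    lap[np.arange(n), np.arange(n)] = a.sum(axis=1)
    return lap
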