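"""Isomorph-free exhaustive generation of small graphs.

The enumerator is the in-package replacement for nauty's ``geng``: it
produces exactly one representative per isomorphism class by extending
every class on ``n - 1`` vertices with one new vertex over all possible
neighbourhoods and deduplicating canonical codes (see
:func:`topodisc._kernels.extend_classes`).  Connected 9-vertex graphs —
the 261,080-member collection at the heart of the uniqueness study — take
a few seconds this way.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from . import _kernels
from .graph import Graph, parse_graph6, write_graph6

__all__ = ["GraphCollection", "enumerate_connected", "enumerate_all",
           "read_graph6_file", "write_graph6_file"]

MAX_CONNECTED_N = 10
MAX_ALL_N = 8

# memoised canonical-code arrays of *all* graphs per vertex count,
# the substrate of both enumerators
_ALL_CODES: dict[int, np.ndarray] = {1: np.zeros(1, dtype=np.int64)}


class GraphCollection:
    """An ordered collection of graphs on a common vertex count.

    Graphs are stored compactly as an ``(N, n)`` array of adjacency-row
    bitmasks; :class:`~topodisc.graph.Graph` objects are materialized on
    access.  ``provenance`` records how the collection was produced
    (enumeration or sampling parameters) so runs are auditable.
    """

    def __init__(self, n: int, masks: np.ndarray, provenance: dict | None = None):
        masks = np.asarray(masks, dtype=np.int64)
        if masks.ndim != 2 or masks.shape[1] != n:
            raise ValueError("masks must have shape (N, n)")
        self.n = n
        self.masks = masks
        self.provenance = dict(provenance or {})

    @classmethod
    def from_graphs(cls, graphs: Sequence[Graph], provenance: dict | None = None):
        if not graphs:
            raise ValueError("empty collection")
        n = graphs[0].n
        if any(g.n != n for g in graphs):
            raise ValueError("all graphs must share one vertex count")
        masks = np.array([g.masks for g in graphs], dtype=np.int64)
        return cls(n, masks, provenance)

    def __len__(self) -> int:
        return self.masks.shape[0]

    def __getitem__(self, i: int) -> Graph:
        row = self.masks[i]
        n = self.n
        edges = [
            (u, v)
            for u in range(n)
            for v in range(u + 1, n)
            if (int(row[u]) >> v) & 1
        ]
        return Graph(n, edges)

    def __iter__(self) -> Iterator[Graph]:
        for i in range(len(self)):
            yield self[i]

    def edge_counts(self) -> np.ndarray:
        counts = np.zeros(len(self), dtype=np.int64)
        for v in range(self.n):
            col = self.masks[:, v]
            for b in range(self.n):
                counts += (col >> b) & 1
        return counts // 2


def _all_codes(n: int) -> np.ndarray:
    if n not in _ALL_CODES:
        parents = _all_codes(n - 1)
        _ALL_CODES[n] = _kernels.extend_classes(parents, n, False)
    return _ALL_CODES[n]


def _sorted_by_size(codes: np.ndarray, n: int) -> np.ndarray:
    # deterministic output order: edge count, then canonical code (which
    # for fixed n is the graph6 byte order of the certificate)
    m = np.zeros(len(codes), dtype=np.int64)
    c = codes.copy()
    while c.any():
        m += (c & 1).astype(np.int64)
        c >>= 1
    return codes[np.lexsort((codes, m))]


def enumerate_connected(n: int) -> GraphCollection:
    """All non-isomorphic connected simple graphs on ``n`` vertices.

    ``n`` is capped at 10 (memory/time guard); the n = 9 collection has
    261,080 members.
    """
    if not 1 <= n <= MAX_CONNECTED_N:
        raise ValueError(
            f"enumerate_connected supports 1 <= n <= {MAX_CONNECTED_N}, got {n}"
        )
    if n == 1:
        codes = np.zeros(1, dtype=np.int64)
    else:
        codes = _kernels.extend_classes(_all_codes(n - 1), n, True)
    codes = _sorted_by_size(codes, n)
    masks = _kernels.decode_codes(codes, n)
    return GraphCollection(
        n, masks, {"kind": "enumeration", "n": n, "connected": True}
    )


def enumerate_all(n: int) -> GraphCollection:
    """All isomorphism classes on ``n`` vertices, disconnected included."""
    if not 1 <= n <= MAX_ALL_N:
        raise ValueError(
            f"enumerate_all supports 1 <= n <= {MAX_ALL_N}, got {n}"
        )
    codes = _sorted_by_size(_all_codes(n), n)
    masks = _kernels.decode_codes(codes, n)
    return GraphCollection(
        n, masks, {"kind": "enumeration", "n": n, "connected": False}
    )


# -- graph6 file I/O ------------------------------------------------------


def write_graph6_file(collection: GraphCollection, path: str | Path) -> None:
    """Write one short-form graph6 record per line."""
    with open(path, "w") as fh:
        for g in collection:
            fh.write(write_graph6(g) + "\n")


def read_graph6_file(path: str | Path, provenance: dict | None = None) -> GraphCollection:
    graphs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                graphs.append(parse_graph6(line))
    prov = {"kind": "file", "path": str(path)}
    prov.update(provenance or {})
    return GraphCollection.from_graphs(graphs, prov)
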