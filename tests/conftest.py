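"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's canonical-labeling and
grouping machinery: isomorphism is decided by brute-force permutation
search, isomorphism classes are enumerated by deduplicating *labeled*
graphs under the full symmetric group, and degeneracy counts are recomputed
by quadratic pairwise comparison.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import topodisc as td


# -- brute-force oracles --------------------------------------------------


def perm_isomorphic(g1: td.Graph, g2: td.Graph) -> bool:
    """Permutation-search isomorphism test (exponential; n <= 8)."""
    if g1.n != g2.n or g1.m != g2.m:
        return False
    e2 = g2.edges
    for p in itertools.permutations(range(g1.n)):
        if all(
            ((p[u], p[v]) if p[u] < p[v] else (p[v], p[u])) in e2
            for u, v in g1.edges
        ):
            return True
    return False


def _min_perm_code(n: int, edges: frozenset) -> tuple:
    """Canonical form by explicit minimization over all n! relabelings."""
    best = None
    for p in itertools.permutations(range(n)):
        relabeled = tuple(sorted(
            (p[u], p[v]) if p[u] < p[v] else (p[v], p[u]) for u, v in edges
        ))
        if best is None or relabeled < best:
            best = relabeled
    return best


def _connected_edges(n: int, edges) -> bool:
    if n == 1:
        return True
    adj = {v: set() for v in range(n)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


def brute_force_classes(n: int, connected: bool = False) -> set:
    """All isomorphism classes on n vertices by labeled-graph dedup."""
    pairs = list(itertools.combinations(range(n), 2))
    classes = set()
    for bits in range(1 << len(pairs)):
        edges = frozenset(
            pairs[i] for i in range(len(pairs)) if (bits >> i) & 1
        )
        if connected and not _connected_edges(n, edges):
            continue
        classes.add(_min_perm_code(n, edges))
    return classes


def pairwise_ndv(values) -> int:
    """O(N^2) oracle: count entries equal to at least one other entry."""
    vals = list(values)
    out = 0
    for i, x in enumerate(vals):
        for j, y in enumerate(vals):
            if i != j and x == y:
                out += 1
                break
    return out


# -- fixtures -------------------------------------------------------------


@pytest.fixture(scope="session")
def c5() -> td.GraphCollection:
    return td.enumerate_connected(5)


@pytest.fixture(scope="session")
def c6() -> td.GraphCollection:
    return td.enumerate_connected(6)


@pytest.fixture(scope="session")
def c8() -> td.GraphCollection:
    return td.enumerate_connected(8)


CORE_TABLE4 = {
    # printed reference degeneracy counts for the 9-vertex study
    "wiener": 261072,
    "zagreb1": 261078,
    "zagreb2": 260931,
    "narumiKatayama": 260925,
    "harary": 261018,
    "randic": 243413,
    "balabanJ": 156674,
    "spectralRadius": 48120,
    "laplacianEnergy": 59542,
    "laplacianEstrada": 23393,
}


@pytest.fixture(scope="session")
def n9() -> td.GraphCollection:
    return td.enumerate_connected(9)


@pytest.fixture(scope="session")
def n9_tables(n9) -> dict[str, td.ValueTable]:
    return td.compute_tables(n9, list(CORE_TABLE4))
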