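"""Scalability study on random connected graphs.

The generator follows the classic two-step recipe: draw a uniform random
labeled spanning tree (via a random Prüfer sequence), then add edges
uniformly at random between currently non-adjacent vertex pairs until the
target edge count m is reached.  Valid edge counts for a connected graph
on n vertices satisfy  n - 1 <= m <= n(n-1)/2.  Samples are deduplicated
up to isomorphism with canonical certificates, so a sample is a set of
distinct isomorphism classes, mirroring how the exhaustive collections are
built.

Sensitivity stability is then estimated by *subsampling* ("bootstrapping
without replacement"): repeatedly draw a fixed fraction of the sample
without replacement, compute S on each draw, and report the mean and
variance across replicates.  Defaults: 100 replicates at fraction 0.8,
always recorded in the summary.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .canonical import canonical_code
from .descriptors import ValueTable, available_names
from .enumeration import GraphCollection
from .graph import Graph
from .uniqueness import DEFAULT_POLICY, EqualityPolicy, _labels, sensitivity

__all__ = [
    "RandomSampleSpec",
    "SubsampleSummary",
    "CATEGORIES",
    "random_connected_graph",
    "build_sample",
    "subsample_mean_sensitivity",
    "category_study",
]

#: Descriptor categories used for the category-pair studies.  The full
#: rosters include names whose formulas are not implemented here; studies
#: intersect them with the available registry at run time.
CATEGORIES: dict[str, tuple[str, ...]] = {
    "eigenvalue": (
        "eigenvaladj", "eigenvallaplace", "eigenvaldistance",
        "eigenvaldistancepath", "eigenvalaugement", "eigenvalextadj",
        "eigenvalvertconnect", "eigenvalrandomwalk", "eigenvalweightedlin",
        "eigenvalweightedexp", "laplacianEnergy", "laplacianEstrada",
        "spectralRadius",
    ),
    "information": (
        "infotheolin1", "infotheolin2", "infotheoquad1", "infotheoquad2",
        "infotheoexp1", "infotheoexp2", "infotheoexp3", "infotheolin3",
        "infotheoquad3", "infotheoexp4",
    ),
    "distance": (
        "balabanJ", "balabanlike1", "balabanlike2", "bertz", "bonchev2",
        "bonchev3", "compactness", "complexityIndexB", "wiener", "harary",
        "radialCentric", "meanDistanceDeviation", "hyperDistancePathIndex",
        "topologicalinfocontent", "graphVertexComplexity",
        "graphDistanceComplexity", "symmetryIndex", "productofrowsums",
    ),
    "degree": (
        "augmentedZagreb", "randic", "zagreb1", "zagreb2", "vertexDegree",
        "modifiedZagreb", "narumiKatayama", "offdiagonal", "variableZagreb",
    ),
}


def edge_bounds(n: int) -> tuple[int, int]:
    """Valid edge-count range for a connected graph on n vertices."""
    return n - 1, n * (n - 1) // 2


@dataclass(frozen=True)
class RandomSampleSpec:
    """Parameters of one random-graph sample.

    ``quota`` graphs are kept per target edge size; generation for a size
    stops after ``max_attempts`` draws (isomorphism rejections included)
    and records a shortfall instead of blocking.
    """

    n: int
    edge_sizes: tuple[int, ...]
    quota: int = 50
    max_attempts: int = 1000
    seed: int = 0

    def __post_init__(self):
        lo, hi = edge_bounds(self.n)
        for m in self.edge_sizes:
            if not lo <= m <= hi:
                raise ValueError(
                    f"edge size {m} outside [{lo}, {hi}] for n={self.n}"
                )
        if self.quota < 1:
            raise ValueError("quota must be >= 1")


@dataclass(frozen=True)
class SubsampleSummary:
    """Mean/variance of the sensitivity over subsample replicates."""

    name: str
    reps: int
    fraction: float
    mean_sensitivity: float
    variance: float


def random_connected_graph(n: int, m: int, rng: np.random.Generator) -> Graph:
    """Connected random graph: uniform labeled spanning tree + uniform
    extra edges among non-adjacent pairs."""
    lo, hi = edge_bounds(n)
    if not lo <= m <= hi:
        raise ValueError(f"edge count {m} outside [{lo}, {hi}] for n={n}")
    if n == 1:
        return Graph(1)
    if n == 2:
        return Graph(2, [(0, 1)])
    # random Prüfer sequence -> uniform random labeled tree
    seq = rng.integers(0, n, size=n - 2)
    degree = np.ones(n, dtype=np.int64)
    for x in seq:
        degree[x] += 1
    edges = set()
    leaves = sorted(v for v in range(n) if degree[v] == 1)
    heapq.heapify(leaves)
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.add((min(leaf, int(x)), max(leaf, int(x))))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, int(x))
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.add((min(u, v), max(u, v)))
    extra = m - (n - 1)
    if extra:
        non_edges = [
            (a, b)
            for a in range(n)
            for b in range(a + 1, n)
            if (a, b) not in edges
        ]
        for i in rng.choice(len(non_edges), size=extra, replace=False):
            edges.add(non_edges[i])
    return Graph(n, edges)


def build_sample(spec: RandomSampleSpec) -> GraphCollection:
    """Generate a certificate-deduplicated sample per the spec.

    Pairwise non-isomorphic by construction; per-size shortfalls (sizes
    that exhaust ``max_attempts`` before filling the quota) are recorded
    in the collection provenance.
    """
    rng = np.random.default_rng(spec.seed)
    graphs: list[Graph] = []
    seen: set[tuple[int, int]] = set()  # (m, canonical code)
    shortfall: dict[int, int] = {}
    if spec.n <= _kernels.MAX_FAST_N:
        def cert(g: Graph) -> int:
            return int(_kernels.canon_code(g.n, np.array(g.masks, np.int64)))
    else:
        cert = canonical_code
    for m in spec.edge_sizes:
        kept = 0
        for _ in range(spec.max_attempts):
            if kept >= spec.quota:
                break
            g = random_connected_graph(spec.n, m, rng)
            key = (m, cert(g))
            if key in seen:
                continue
            seen.add(key)
            graphs.append(g)
            kept += 1
        if kept < spec.quota:
            shortfall[m] = spec.quota - kept
    prov = {
        "kind": "random_sample",
        "n": spec.n,
        "edge_sizes": list(spec.edge_sizes),
        "quota": spec.quota,
        "max_attempts": spec.max_attempts,
        "seed": spec.seed,
    }
    if shortfall:
        prov["shortfall"] = shortfall
    return GraphCollection.from_graphs(graphs, prov)


def subsample_mean_sensitivity(
    table: ValueTable,
    reps: int | str = 100,
    fraction: float = 0.8,
    rng: np.random.Generator | None = None,
    policy: EqualityPolicy = DEFAULT_POLICY,
) -> SubsampleSummary:
    """Mean and variance of S over without-replacement subsamples.

    Each replicate draws ``floor(fraction * N)`` entries without
    replacement and evaluates S on the draw.  ``reps="exhaustive"``
    averages over *all* subsets of that size (only sensible for tiny N).
    """
    N = len(table)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(math.floor(fraction * N))
    if k < 2:
        raise ValueError(f"subsample size {k} < 2")
    labels = _labels(table, policy)

    def s_of(idx) -> float:
        sub = labels[np.asarray(idx)]
        _, counts = np.unique(sub, return_counts=True)
        nd = int(counts[counts >= 2].sum())
        return float(sensitivity(k, nd))

    if reps == "exhaustive":
        vals = [s_of(c) for c in itertools.combinations(range(N), k)]
    else:
        if not isinstance(reps, int) or reps < 2:
            raise ValueError("reps must be an integer >= 2 or 'exhaustive'")
        if rng is None:
            rng = np.random.default_rng()
        vals = [
            s_of(rng.choice(N, size=k, replace=False)) for _ in range(reps)
        ]
    arr = np.asarray(vals, dtype=np.float64)
    return SubsampleSummary(
        name=table.name,
        reps=len(vals),
        fraction=fraction,
        mean_sensitivity=float(arr.mean()),
        variance=float(arr.var()),
    )


def category_study(
    collection: GraphCollection,
    category_a: str,
    category_b: str,
    eq_id: str = "S1",
    reps: int = 100,
    fraction: float = 0.8,
    rng: np.random.Generator | None = None,
    policy: EqualityPolicy = DEFAULT_POLICY,
) -> list[SubsampleSummary]:
    """Subsample summaries for all cross-category descriptor pairs.

    Pairs one implemented member of ``category_a`` with one of
    ``category_b`` (all combinations, skipping same-name pairs) under the
    ``eq_id`` combinator.
    """
    from .descriptors import compute_tables
    from .superindices import combine

    if rng is None:
        rng = np.random.default_rng()
    for cat in (category_a, category_b):
        if cat not in CATEGORIES:
            raise ValueError(
                f"unknown category {cat!r}; known: {', '.join(CATEGORIES)}"
            )

    def members(cat: str) -> list[str]:
        avail = set(available_names())
        got = [x for x in CATEGORIES[cat] if x in avail]
        if not got:
            missing = ", ".join(CATEGORIES[cat])
            raise ValueError(
                f"no implemented descriptors in category {cat!r}; "
                f"missing: {missing}"
            )
        return got

    names_a = members(category_a)
    names_b = members(category_b)
    tables = compute_tables(collection, sorted(set(names_a) | set(names_b)))
    out = []
    for a in names_a:
        for b in names_b:
            if a == b:
                continue
            fused = combine(tables[a], tables[b], eq_id)
            out.append(subsample_mean_sensitivity(
                fused, reps=reps, fraction=fraction, rng=rng, policy=policy))
    return out
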