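"""Registry of topological graph descriptors (molecular indices).

Each descriptor maps a connected simple graph to a number.  The registry
splits into a *core* set with precisely pinned formulas — degree-based
(first/second Zagreb, Randić connectivity, Narumi–Katayama), distance-based
(Wiener, Harary, Balaban J), spectrum-based (adjacency spectral radius,
Laplacian energy, Laplacian Estrada) and entropy-based (orbit information
content, radial centric information, parametrized graph-entropy
functionals) — and an *extended* set implemented from the standard index
literature.  Names follow the abbreviations customary in the QSAR
descriptor literature.  Names that are recognized but whose defining
formula we have not certified are registered as unavailable and raise
:class:`DescriptorUnavailable` rather than silently returning anything.

Exactness policy: Wiener and the Zagreb/Narumi–Katayama indices are exact
integers, Harary is an exact rational, everything else is IEEE double.
Integer/rational descriptors carry exact grouping keys in their value
tables so uniqueness counts are free of floating-point ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np

from . import _kernels
from .canonical import certificate
from .enumeration import GraphCollection
from .graph import Graph, distance_data, matrix

__all__ = [
    "DescriptorSpec",
    "ValueTable",
    "DescriptorUnavailable",
    "REGISTRY",
    "available_names",
    "compute",
    "compute_table",
    "compute_tables",
    "degree_core",
    "distance_core",
    "spectral_core",
    "entropy_core",
    "extended_registry",
]


class DescriptorUnavailable(Exception):
    """A known descriptor name whose formula is not implemented here.

    Deliberately distinct from :class:`KeyError` (unknown name) and from
    numeric failure (which yields a non-finite value, never an exception).
    """


@dataclass(frozen=True)
class DescriptorSpec:
    """Registry entry: what a descriptor is and how it is computed."""

    name: str
    category: str  # degree | distance | eigenvalue | information
    value_kind: str  # int | rational | real
    func: Callable[[Graph], object] | None
    provenance: str
    params: dict = field(default_factory=dict)

    @property
    def available(self) -> bool:
        return self.func is not None


@dataclass
class ValueTable:
    """Descriptor (or superindex) values aligned with a GraphCollection.

    ``values`` are float64 for display and combination; ``keys``, when
    present, are exact int64 representatives used for equality grouping
    (e.g. the Harary index times lcm(1..n-1)).  ``kind`` is the value
    kind, or ``"pair"`` for the lossless two-descriptor baseline, in which
    case ``components`` holds the two component tables.
    """

    name: str
    values: np.ndarray | None
    keys: np.ndarray | None = None
    kind: str = "real"
    components: tuple = ()

    def __len__(self) -> int:
        if self.values is not None:
            return len(self.values)
        return len(self.components[0])

    @property
    def nan_count(self) -> int:
        if self.values is None:
            return 0
        return int((~np.isfinite(self.values)).sum())


# ---------------------------------------------------------------------------
# per-graph descriptor functions
# ---------------------------------------------------------------------------


def _require_connected(g: Graph) -> None:
    if not g.connected:
        raise ValueError("descriptor requires a connected graph")


def zagreb1(g: Graph) -> int:
    """First Zagreb index M1 = sum of squared vertex degrees."""
    return sum(d * d for d in g.degree())


def zagreb2(g: Graph) -> int:
    """Second Zagreb index M2 = sum over edges of the degree product."""
    deg = g.degree()
    return sum(deg[u] * deg[v] for u, v in g.edges)


def randic(g: Graph) -> float:
    """Randić connectivity index R = sum over edges of (d_u d_v)^(-1/2)."""
    deg = g.degree()
    return sum(1.0 / math.sqrt(deg[u] * deg[v]) for u, v in g.edges)


def narumi_katayama(g: Graph) -> int:
    """Narumi–Katayama index: product of all vertex degrees."""
    return math.prod(g.degree())


def modified_zagreb(g: Graph) -> float:
    deg = g.degree()
    return sum(1.0 / (deg[u] * deg[v]) for u, v in g.edges)


def augmented_zagreb(g: Graph) -> float:
    """Sum over edges of (d_u d_v / (d_u + d_v - 2))^3; non-finite on K2."""
    deg = g.degree()
    total = 0.0
    for u, v in g.edges:
        s = deg[u] + deg[v] - 2
        if s == 0:
            return math.nan
        total += (deg[u] * deg[v] / s) ** 3
    return total


def wiener(g: Graph) -> int:
    """Wiener index W = sum of all pairwise shortest-path distances."""
    _require_connected(g)
    dd = distance_data(g)
    return int(dd.d.sum()) // 2


def harary(g: Graph) -> Fraction:
    """Harary index H = sum over pairs of reciprocal distances (exact)."""
    _require_connected(g)
    d = distance_data(g).d
    n = g.n
    return sum(
        (Fraction(1, int(d[u, v])) for u in range(n) for v in range(u + 1, n)),
        Fraction(0),
    )


def balaban_j(g: Graph) -> float:
    """Balaban distance-connectivity index J.

    J = m/(mu+1) * sum over edges of (D_u D_v)^(-1/2), with cyclomatic
    number mu = m - n + 1 and distance sums D_v.
    """
    _require_connected(g)
    dd = distance_data(g)
    m = g.m
    mu = m - g.n + 1
    acc = sum(
        1.0 / math.sqrt(dd.rowsum[u] * dd.rowsum[v]) for u, v in g.edges
    )
    return m / (mu + 1) * acc


def product_of_row_sums_log(g: Graph) -> float:
    """log-scaled product of distance-matrix row sums: sum_v ln D_v."""
    _require_connected(g)
    return sum(math.log(s) for s in distance_data(g).rowsum)


def spectral_radius(g: Graph) -> float:
    """Largest adjacency eigenvalue."""
    return float(np.linalg.eigvalsh(matrix(g, "adjacency"))[-1])


def laplacian_energy(g: Graph) -> float:
    """LE = sum_i |mu_i - 2m/n| over Laplacian eigenvalues."""
    mu = np.linalg.eigvalsh(matrix(g, "laplacian"))
    return float(np.abs(mu - 2 * g.m / g.n).sum())


def laplacian_estrada(g: Graph) -> float:
    """LEE = sum_i exp(mu_i) over Laplacian eigenvalues."""
    mu = np.linalg.eigvalsh(matrix(g, "laplacian"))
    return float(np.exp(mu).sum())


def graph_index_complexity(g: Graph) -> float:
    """4c(1-c) with c = (r - 2cos(pi/(n+1))) / (n-1 - 2cos(pi/(n+1)))."""
    n = g.n
    r = spectral_radius(g)
    low = 2 * math.cos(math.pi / (n + 1))  # spectral radius of the path
    c = (r - low) / ((n - 1) - low)
    return 4 * c * (1 - c)


def _entropy(probs: Iterable[float]) -> float:
    return -sum(p * math.log2(p) for p in probs if p > 0)


def topological_info_content(g: Graph) -> float:
    """Orbit entropy: -sum over automorphism orbits of (|O|/n) log2(|O|/n)."""
    _require_connected(g)
    orbs = certificate(g).orbits
    n = g.n
    return _entropy(len(o) / n for o in orbs)


def radial_centric(g: Graph) -> float:
    """Eccentricity-class entropy."""
    _require_connected(g)
    ecc = distance_data(g).ecc
    n = g.n
    counts: dict[int, int] = {}
    for e in ecc:
        counts[e] = counts.get(e, 0) + 1
    return _entropy(c / n for c in counts.values())


def symmetry_index(g: Graph) -> float:
    """Orbit/automorphism symmetry measure.

    S(G) = (n log2 n - sum_i |O_i| log2 |O_i| + log2 |Aut(G)|) / n over the
    automorphism orbits O_i.  Provenance: symmetry-index literature;
    flagged reference-unverified in the registry.
    """
    _require_connected(g)
    cert = certificate(g)
    n = g.n
    s = n * math.log2(n) - sum(
        len(o) * math.log2(len(o)) for o in cert.orbits if len(o) > 1
    )
    return (s + math.log2(cert.aut_order)) / n


_COEFF_SCHEMES = ("lin", "quad", "exp")
_INFO_FUNCTS = ("sphere", "degree")


def _info_functional(g: Graph, infofunct: str, coeff: str) -> list[float]:
    dd = distance_data(g)
    rho = dd.diameter
    if coeff == "lin":
        c = [rho - k + 1 for k in range(1, rho + 1)]
    elif coeff == "quad":
        c = [(rho - k + 1) ** 2 for k in range(1, rho + 1)]
    elif coeff == "exp":
        c = [2.0 ** (rho - k) for k in range(1, rho + 1)]
    else:
        raise ValueError(
            f"unknown coefficient scheme {coeff!r}; supported: "
            f"{', '.join(_COEFF_SCHEMES)}"
        )
    n = g.n
    f = []
    if infofunct == "sphere":
        for v in range(n):
            f.append(sum(
                c[k - 1] * dd.spheres[v][k - 1]
                for k in range(1, dd.ecc[v] + 1)
            ))
    elif infofunct == "degree":
        # degree mass per distance shell, weighted like the sphere counts
        deg = g.degree()
        for v in range(n):
            f.append(sum(
                c[int(dd.d[v, u]) - 1] * deg[u] for u in range(n) if u != v
            ))
    else:
        raise ValueError(
            f"unknown information functional {infofunct!r}; supported: "
            f"{', '.join(_INFO_FUNCTS)}"
        )
    return f


def info_theoretic_gcm(
    g: Graph, coeff: str = "lin", infofunct: str = "sphere",
    lam: float = 1000.0,
) -> float:
    """Parametric graph entropy of Dehmer's information-functional family.

    p(v) = f(v) / sum_u f(u) for the chosen vertex functional f, and the
    value is lam times the Shannon entropy -sum_v p(v) log2 p(v).  The lam
    scaling (and any injective transform) provably leaves uniqueness
    counts unchanged.
    """
    _require_connected(g)
    if g.n == 1:
        return 0.0
    f = _info_functional(g, infofunct, coeff)
    total = sum(f)
    if total <= 0:
        return math.nan
    return lam * _entropy(x / total for x in f)


def _simple_paths_weight_sum(g: Graph, weight: Sequence[float]) -> float:
    """Sum over all simple paths (>= 1 edge) of the product of edge weights
    w(u,v) = (weight[u]*weight[v])^(-1/2).  Exponential in dense graphs."""
    masks = g.masks
    n = g.n
    w = [
        [0.0] * n for _ in range(n)
    ]
    for u, v in g.edges:
        x = 1.0 / math.sqrt(weight[u] * weight[v])
        w[u][v] = w[v][u] = x
    total = 0.0

    def dfs(v: int, visited: int, acc: float) -> None:
        nonlocal total
        rest = masks[v] & ~visited
        while rest:
            u = (rest & -rest).bit_length() - 1
            rest &= rest - 1
            total += acc * w[v][u]
            dfs(u, visited | (1 << u), acc * w[v][u])

    for s in range(n):
        dfs(s, 1 << s, 1.0)
    return total / 2.0  # each path visited from both ends


def min_connectivity_id(g: Graph) -> float:
    """Connectivity-weighted molecular ID number (path-weight sum).

    n + sum over simple paths of prod over path edges (d_u d_v)^(-1/2).
    Provenance: molecular ID-number literature; flagged
    reference-unverified.  Cost grows exponentially with density.
    """
    _require_connected(g)
    return g.n + _simple_paths_weight_sum(g, g.degree())


def min_balaban_id(g: Graph) -> float:
    """Distance-sum-weighted molecular ID number (path-weight sum);
    flagged reference-unverified."""
    _require_connected(g)
    return g.n + _simple_paths_weight_sum(g, distance_data(g).rowsum)


# ---------------------------------------------------------------------------
# the registry
# ---------------------------------------------------------------------------

def _spec(name, category, kind, func, provenance, **params):
    return DescriptorSpec(name, category, kind, func, provenance, params)


REGISTRY: dict[str, DescriptorSpec] = {}

for s in [
    # degree-based
    _spec("zagreb1", "degree", "int", zagreb1, "Gutman–Trinajstić first Zagreb index"),
    _spec("zagreb2", "degree", "int", zagreb2, "Gutman–Trinajstić second Zagreb index"),
    _spec("randic", "degree", "real", randic, "Randić connectivity index"),
    _spec("narumiKatayama", "degree", "int", narumi_katayama, "Narumi–Katayama simple topological index"),
    _spec("modifiedZagreb", "degree", "real", modified_zagreb, "modified Zagreb index, sum over edges of 1/(d_u d_v)"),
    _spec("augmentedZagreb", "degree", "real", augmented_zagreb, "augmented Zagreb index (Furtula et al.)"),
    # distance-based
    _spec("wiener", "distance", "int", wiener, "Wiener index"),
    _spec("harary", "distance", "rational", harary, "Harary index (reciprocal distance sum)"),
    _spec("balabanJ", "distance", "real", balaban_j, "Balaban distance-connectivity J"),
    _spec("productofrowsums", "distance", "real", product_of_row_sums_log, "log product of distance-matrix row sums"),
    _spec("radialCentric", "distance", "real", radial_centric, "radial centric information index (eccentricity-class entropy)"),
    _spec("topologicalinfocontent", "distance", "real", topological_info_content, "Rashevsky–Mowshowitz orbit information content"),
    _spec("symmetryIndex", "distance", "real", symmetry_index, "orbit/automorphism symmetry index; reference-unverified"),
    _spec("minConnectivityID", "degree", "real", min_connectivity_id, "molecular ID number, connectivity path weights; reference-unverified"),
    _spec("minBalabanID", "distance", "real", min_balaban_id, "molecular ID number, distance-sum path weights; reference-unverified"),
    # eigenvalue-based
    _spec("spectralRadius", "eigenvalue", "real", spectral_radius, "largest adjacency eigenvalue"),
    _spec("laplacianEnergy", "eigenvalue", "real", laplacian_energy, "Laplacian energy, sum |mu_i - 2m/n|"),
    _spec("laplacianEstrada", "eigenvalue", "real", laplacian_estrada, "Laplacian Estrada index, sum exp(mu_i)"),
    _spec("graphIndexComplexity", "eigenvalue", "real", graph_index_complexity, "spectral-radius complexity 4c(1-c)"),
    # information-theoretic (parametric entropies, lambda = 1000)
    _spec("infotheolin1", "information", "real",
          lambda g: info_theoretic_gcm(g, "lin", "sphere"),
          "graph entropy, linear sphere functional", coeff="lin", infofunct="sphere", lam=1000),
    _spec("infotheoquad1", "information", "real",
          lambda g: info_theoretic_gcm(g, "quad", "sphere"),
          "graph entropy, quadratic sphere functional", coeff="quad", infofunct="sphere", lam=1000),
    _spec("infotheoexp1", "information", "real",
          lambda g: info_theoretic_gcm(g, "exp", "sphere"),
          "graph entropy, exponential sphere functional", coeff="exp", infofunct="sphere", lam=1000),
    _spec("infotheoexp3", "information", "real",
          lambda g: info_theoretic_gcm(g, "exp", "degree"),
          "graph entropy, exponential degree functional", coeff="exp", infofunct="degree", lam=1000),
]:
    REGISTRY[s.name] = s

# recognized names whose defining formulas are not certified here; they
# raise DescriptorUnavailable so a scan can report them rather than guess
_UNAVAILABLE = {
    "balabanlike1": "distance", "balabanlike2": "distance",
    "bertz": "distance", "bonchev1": "distance", "bonchev2": "distance",
    "bonchev3": "distance", "compactness": "distance",
    "complexityIndexB": "distance", "normalizedEdgeComplexity": "degree",
    "meanDistanceDeviation": "distance", "hyperDistancePathIndex": "distance",
    "vertexDegree": "degree", "graphVertexComplexity": "distance",
    "graphDistanceComplexity": "distance", "informationLayerIndex": "information",
    "mediumArticulation": "distance", "offdiagonal": "degree",
    "spanningTreeSensitivity": "distance", "variableZagreb": "degree",
    "eigenvaladj": "eigenvalue", "eigenvallaplace": "eigenvalue",
    "eigenvaldistance": "eigenvalue", "eigenvaldistancepath": "eigenvalue",
    "eigenvalaugement": "eigenvalue", "eigenvalextadj": "eigenvalue",
    "eigenvalvertconnect": "eigenvalue", "eigenvalrandomwalk": "eigenvalue",
    "eigenvalweightedlin": "eigenvalue", "eigenvalweightedexp": "eigenvalue",
    "infotheolin2": "information", "infotheoquad2": "information",
    "infotheoexp2": "information", "infotheolin3": "information",
    "infotheoquad3": "information", "infotheoexp4": "information",
}
for name, cat in _UNAVAILABLE.items():
    REGISTRY[name] = _spec(name, cat, "real", None,
                           "recognized; defining formula not certified here")


def available_names(category: str | None = None) -> list[str]:
    return [
        s.name for s in REGISTRY.values()
        if s.available and (category is None or s.category == category)
    ]


def _lookup(name: str) -> DescriptorSpec:
    if name not in REGISTRY:
        raise KeyError(f"unknown descriptor {name!r}")
    s = REGISTRY[name]
    if not s.available:
        raise DescriptorUnavailable(
            f"descriptor {name!r} is recognized but not implemented"
        )
    return s


def compute(g: Graph, name: str):
    """Value of one descriptor on one graph (exact kind where declared)."""
    return _lookup(name).func(g)


# spec'd operation surfaces: thin dispatchers over the registry

def degree_core(g: Graph, name: str):
    if name not in ("zagreb1", "zagreb2", "randic", "narumiKatayama"):
        raise KeyError(f"{name!r} is not a core degree descriptor")
    return compute(g, name)


def distance_core(g: Graph, name: str):
    if name not in ("wiener", "harary", "balabanJ"):
        raise KeyError(f"{name!r} is not a core distance descriptor")
    return compute(g, name)


def spectral_core(g: Graph, name: str):
    if name not in ("spectralRadius", "laplacianEnergy", "laplacianEstrada"):
        raise KeyError(f"{name!r} is not a core spectral descriptor")
    return compute(g, name)


def entropy_core(g: Graph, name: str, **params):
    if name == "topologicalinfocontent":
        return topological_info_content(g)
    if name == "radialCentric":
        return radial_centric(g)
    if name == "infotheo_gcm":
        return info_theoretic_gcm(g, **params)
    raise KeyError(f"{name!r} is not a core entropy descriptor")


def extended_registry(g: Graph, name: str):
    return compute(g, name)


# ---------------------------------------------------------------------------
# bulk computation over collections
# ---------------------------------------------------------------------------

_DEGREE_BULK = {"zagreb1", "zagreb2", "randic", "narumiKatayama",
                "modifiedZagreb", "augmentedZagreb"}
_DISTANCE_BULK = {"wiener", "harary", "balabanJ", "productofrowsums"}
_EIG_BULK = {"spectralRadius", "laplacianEnergy", "laplacianEstrada",
             "graphIndexComplexity"}
_EIG_CHUNK = 65536


class _BulkContext:
    """Shared intermediates for computing several descriptors on one
    collection (degree sums, BFS distance sums, eigenvalue stacks)."""

    def __init__(self, collection: GraphCollection):
        self.c = collection
        self._deg = None
        self._dist = None
        self._adj_spec = None
        self._lap_spec = None
        self._m = None

    @property
    def masks(self):
        return self.c.masks

    def degree_stats(self):
        if self._deg is None:
            self._deg = _kernels.degree_stats(self.masks)
        return self._deg

    def distance_stats(self):
        if self._dist is None:
            self._dist = _kernels.distance_stats(self.masks, self._hlcm())
        return self._dist

    def _hlcm(self) -> int:
        n = self.c.n
        l = math.lcm(*range(1, n)) if n > 1 else 1
        # exact scaled Harary must not overflow int64
        return l if l * (n * (n - 1) // 2) < 2**62 else 0

    def edge_totals(self):
        if self._m is None:
            self._m = self.c.edge_counts()
        return self._m

    def _spectra(self, which: str):
        attr = "_adj_spec" if which == "adjacency" else "_lap_spec"
        if getattr(self, attr) is None:
            N = len(self.c)
            n = self.c.n
            out = np.empty((N, n), dtype=np.float64)
            for lo in range(0, N, _EIG_CHUNK):
                hi = min(lo + _EIG_CHUNK, N)
                A = _kernels.dense_adjacency(self.masks[lo:hi])
                if which == "laplacian":
                    deg = A.sum(axis=2)
                    A = -A
                    idx = np.arange(n)
                    A[:, idx, idx] = deg
                out[lo:hi] = np.linalg.eigvalsh(A)
            setattr(self, attr, out)
        return getattr(self, attr)

    def table(self, name: str) -> ValueTable:
        spec = _lookup(name)
        n = self.c.n
        if name in _DEGREE_BULK and n <= 32:
            m1, m2, nk, rn, mz, az = self.degree_stats()
            if name == "zagreb1":
                return ValueTable(name, m1.astype(float), m1, "int")
            if name == "zagreb2":
                return ValueTable(name, m2.astype(float), m2, "int")
            if name == "narumiKatayama":
                return ValueTable(name, nk.astype(float), nk, "int")
            if name == "randic":
                return ValueTable(name, rn, None, "real")
            if name == "modifiedZagreb":
                return ValueTable(name, mz, None, "real")
            return ValueTable(name, az, None, "real")
        if name in _DISTANCE_BULK and n <= 32:
            W, Hs, J, PRS = self.distance_stats()
            if name == "wiener":
                return ValueTable(name, W.astype(float), W, "int")
            if name == "harary":
                hl = self._hlcm()
                if hl:
                    return ValueTable(name, Hs / hl, Hs, "rational")
                # fall through to per-graph floats when lcm overflows
            if name == "balabanJ":
                return ValueTable(name, J, None, "real")
            if name == "productofrowsums":
                return ValueTable(name, PRS, None, "real")
        if name in _EIG_BULK and n <= 32:
            if name == "spectralRadius":
                return ValueTable(name, self._spectra("adjacency")[:, -1].copy(),
                                  None, "real")
            if name == "graphIndexComplexity":
                r = self._spectra("adjacency")[:, -1]
                low = 2 * math.cos(math.pi / (n + 1))
                c = (r - low) / ((n - 1) - low)
                return ValueTable(name, 4 * c * (1 - c), None, "real")
            lev = self._spectra("laplacian")
            if name == "laplacianEnergy":
                mbar = 2 * self.edge_totals() / n
                vals = np.abs(lev - mbar[:, None]).sum(axis=1)
                return ValueTable(name, vals, None, "real")
            return ValueTable(name, np.exp(lev).sum(axis=1), None, "real")
        # generic per-graph fallback (entropy/orbit/ID descriptors, n > 32)
        vals = np.empty(len(self.c), dtype=np.float64)
        keys = (np.empty(len(self.c), dtype=np.int64)
                if spec.value_kind in ("int", "rational") else None)
        denom = 1
        if spec.value_kind == "rational" and name == "harary":
            denom = math.lcm(*range(1, n)) if n > 1 else 1
        for i, g in enumerate(self.c):
            v = spec.func(g)
            if keys is not None:
                keys[i] = int(v * denom)
            vals[i] = float(v)
        return ValueTable(name, vals, keys, spec.value_kind)


def compute_table(collection: GraphCollection, name: str) -> ValueTable:
    """Values of one descriptor over a whole collection."""
    return _BulkContext(collection).table(name)


def compute_tables(
    collection: GraphCollection, names: Sequence[str]
) -> dict[str, ValueTable]:
    """Values of several descriptors, sharing intermediates (distances,
    spectra) across descriptors."""
    ctx = _BulkContext(collection)
    return {name: ctx.table(name) for name in names}
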