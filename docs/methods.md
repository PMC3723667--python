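# Methods

This note documents the algorithms, statistical procedures, parameter
defaults and numerical conventions behind `topodisc`, and the design
choices made where more than one reasonable convention exists.  It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Graphs and canonical labeling

Graphs are simple, undirected, unweighted, on vertices `0..n-1`, stored
as adjacency-row bitmasks.  Distance-based descriptors require connected
input; disconnected graphs are representable but distance operations
raise rather than adopting an infinite-distance convention, because every
study collection here is connected by construction.

Isomorphism classes are identified by a canonical form: the permutation
of the vertices minimizing the packed upper-triangle bit string of the
adjacency matrix (in graph6 column-major bit order), found by iterated
colour refinement (re-partition vertices by the multiset of neighbour
colours until stable) with backtracking individualization over the first
smallest non-singleton cell.  One pruning rule matters in practice: when
a target cell is *interchangeable* — identical adjacency rows outside the
cell and an induced subgraph that is complete or empty — every ordering
of the cell is an automorphism, so the search discretizes it in index
order instead of branching.  Without this rule the search is factorial on
near-complete graphs, empty-heavy colourings and duplicate-vertex
families; with it, all graphs arising in the studies here certify in
microseconds to milliseconds.  Strongly-regular-like worst cases remain
exponential in principle; at the orders used here (n ≤ 30 in routine use)
none occur.

Certificates expose automorphism orbits (two vertices are equivalent iff
individualizing each yields the same canonical code) and the group order
|Aut| via the orbit–stabilizer recursion |Aut| = |orbit(v)| · |Stab(v)|.

Two independent implementations exist: a pure-Python engine valid for any
n (arbitrary-precision masks) behind the public `certificate` API, and a
numba kernel (n ≤ 11, int64-packed codes) behind enumeration and sample
deduplication.  They compute the same canonical form and are
cross-checked in the tests, alongside brute-force permutation search and
networkx VF2 as external oracles.

## Exhaustive enumeration

`enumerate_connected(n)` (n ≤ 10) and `enumerate_all(n)` (n ≤ 8) extend
every isomorphism class on `n-1` vertices by one new vertex over all
2^(n-1) neighbourhoods and deduplicate canonical codes in a hash set.
Completeness follows because deleting any one vertex of a target graph
leaves *some* graph on `n-1` vertices, and all of those are extended.
Output order is deterministic: ascending edge count, then canonical code
(equivalently, certificate bytes).  The connected 9-vertex class —
261,080 graphs — enumerates in roughly ten seconds on one CPU; counts for
n ≤ 8 are verified in the tests against brute-force labeled-graph
deduplication and the classical census values.

## Descriptor registry

Core formulas (M1 = Σ deg², M2 = Σ_E deg·deg, R = Σ_E (d_u d_v)^{-1/2},
NK = Π deg, W = Σ_{u<v} d(u,v), H = Σ_{u<v} 1/d(u,v),
J = m/(μ+1) Σ_E (D_u D_v)^{-1/2} with μ = m−n+1, spectral radius,
LE = Σ |μ_i − 2m/n|, LEE = Σ e^{μ_i}) are exactly as stated in the index
literature.  Value kinds are explicit: W, M1, M2, NK are exact integers;
H is an exact rational (grouped via the common denominator lcm(1..n−1)
when it fits 64 bits); everything else is IEEE double.  Exact kinds carry
integer grouping keys so their uniqueness counts involve no floating
point at all.

Entropy descriptors: the orbit information content is the Shannon entropy
of the automorphism-orbit size distribution; the radial centric index is
the entropy of the eccentricity classes.  The parametric graph entropies
(`infotheo*`) use a vertex functional f and p(v) = f(v)/Σf, value
λ·(−Σ p log₂ p) with λ = 1000.  The sphere functional is
f(v) = Σ_k c_k |S_k(v)| with coefficients c_k = ρ−k+1 (lin), (ρ−k+1)²
(quad) and 2^{ρ−k} (exp, our choice of "exponentially decaying"); the
degree functional replaces the sphere counts by the total degree at each
distance shell, the natural degree analogue.  λ-scaling and any injective
transform provably leave ndv unchanged (tested), so these conventions
cannot affect uniqueness conclusions.

The registry deliberately refuses names whose defining formulas we have
not certified from primary sources (e.g. the `eigenval*` family, `bertz`,
`spanningTreeSensitivity`): they raise a distinct `DescriptorUnavailable`
error and scans report them as unavailable rather than guessing.  The
molecular ID numbers (`minConnectivityID`, `minBalabanID`) are
implemented as simple-path weight sums and flagged reference-unverified;
their cost grows exponentially with density, which is acceptable only on
small or sparse graphs.  The symmetry index
S(G) = (n log₂ n − Σ|O_i| log₂|O_i| + log₂|Aut|)/n is likewise flagged.

## Superindices

The nine combinators are the simplest sum/product/power polynomial
combinations of two indices:

    S1 = I1 + I2          S6 = I1 - I2
    S2 = I1 * I2          S7 = I1^2 + I2
    S3 = I1^2 * I2        S8 = I1 + I2^2
    S4 = I1 * I2^2        S9 = (I1 * I2)^2
    S5 = I1 + I2 + I1*I2

S1–S5 form the first set and S6–S9 the second.  The purely multiplicative
members (S2, S3, S4, S9) annihilate I2 wherever I1 = 0, so pairing them
with a zero-heavy entropy index (orbit entropy on asymmetric graphs,
eccentricity entropy on self-centred graphs) stays degenerate exactly on
the zero set, while the additive members discriminate almost perfectly —
the qualitative signature seen throughout the superindex experiments.
Combinators are registered pure elementwise functions with their formula
strings, so the mapping is auditable; domain violations produce
non-finite entries, never exceptions.

`tuple_baseline` is the lossless ordered pair (I1, I2).  Its ndv is a
floor: any scalar function of the two values induces a coarser or equal
partition.  Note the floor is a theorem only under a *consistent* value
identity — if grouping rounds to 15 digits but combinators consume raw
doubles, two graphs merged by the pair grouping (values differing at
1e-16) can produce combined values that round apart, and the observed
combined ndv can dip below the observed pair ndv.  Comparisons of
combinators against the baseline should therefore be run on the policy's
rounded representatives; the acceptance test and the examples do so.

## The uniqueness statistic and the equality policy

ndv counts members of value-groups of size ≥ 2; S = (N − ndv)/N is
computed in exact rational arithmetic (so S·N + ndv = N exactly) and
reported at full precision plus a 5-decimal rendering.  All non-finite
values are pooled into one shared class — maximally conservative, since
it can only understate uniqueness.

Real-valued grouping needs an equality convention, and the measured ndv
of spectrum-derived descriptors is *very* sensitive to it: on the
9-vertex collection the spectral-radius ndv ranges from ~12k (exact
double comparison — true ties split by eigensolver noise) through ~48k
(15 significant digits) to ~56k (12 digits, which merges genuinely
distinct radii separated by ~1e-8).  The default policy rounds to **15
significant decimal digits** before grouping: that is the precision at
which standard statistics environments serialize doubles to decimal, it
absorbs few-ulp eigensolver noise, and it preserves every distinction
that survives double-precision printing.  The policy is a field of every
report and a CLI flag (`--policy exact | rounded:<digits>`), because
other conventions are defensible and shift real-valued counts by up to a
few hundred out of 261k.

A mathematical aside that the tests exploit: by the
Lindemann–Weierstrass theorem, Σ e^{μ_i} over algebraic eigenvalues is
equal for two graphs iff their Laplacian spectra coincide, so the *exact*
ndv of the Laplacian Estrada index equals the Laplacian-cospectral-mate
count — any finite-precision convention measures something slightly
different, which is why this descriptor's count is the most
convention-sensitive of the core set.

## Random-graph scalability study

`random_connected_graph(n, m)` draws a uniform random labeled spanning
tree via a random Prüfer sequence, then adds `m − (n−1)` edges chosen
uniformly without replacement among the non-adjacent pairs; valid m
satisfies n−1 ≤ m ≤ n(n−1)/2.  Uniformity is over *labeled* trees, not
isomorphism classes — sparse samples are therefore biased toward
path-like trees, which is the standard behaviour of this generator and is
documented rather than corrected.  `build_sample` keeps up to `quota`
graphs per edge size (default 50, the study's sampling density),
rejecting isomorphs by canonical certificate, and records a shortfall for
edge sizes whose class census is smaller than the quota rather than
blocking.

Stability is summarized by subsampling without replacement: each
replicate draws ⌊fraction·N⌋ graphs and evaluates S; the summary reports
the mean and (population) variance across replicates.  Defaults are 100
replicates at fraction 0.8, always recorded; `reps="exhaustive"`
averages over all subsets for tiny N and is checked against a direct
combinatorial oracle.  Category studies pair every implemented member of
one descriptor category (eigenvalue / information / distance / degree,
per the packaged rosters) with every member of another under a chosen
combinator.

The packaged reduced study (tests and examples) uses n ∈ {15, 20, 30}
with quota 10 and strided edge sizes — enough to exhibit the qualitative
finding (superindex sensitivity stays near 1 while, e.g., the Wiener
index collapses on dense diameter-2 graphs, where W = n(n−1) − m is a
function of the edge count alone).  Full-scale runs at n = 50..150 with
quota 50 over the whole edge range are a configurable long-running mode
of the same code path; for n > 63 the bulk numba kernels do not apply and
the per-graph Python paths are used.

## What the generated collections do and do not emulate

The exhaustive collections are *general* simple connected graphs — no
chemical valence constraints, no vertex/edge weights, no degree bounds.
Conclusions about descriptor uniqueness on these collections do not
automatically transfer to molecular graph classes, where degeneracy
behaviour is known to differ; the package measures, it does not
extrapolate.  The random samples likewise cover the full edge-density
range uniformly by size, which no natural graph ensemble does.

## Known limitations

- Canonical labeling has exponential worst cases (mitigated, not
  eliminated, by the interchangeable-cell rule).
- Exhaustive enumeration is capped at n = 10 (memory/time guard);
  graph6 I/O is short-form (n ≤ 62).
- Roughly half of the recognized descriptor names are registered as
  unavailable pending certified formulas; scans report them rather than
  approximate them.
- Real-valued ndv depends on the equality policy by design; compare runs
  only at matching policies (every report carries its policy string).
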