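"""Descriptor formulas: hand-checked values, closed forms on families,
relabeling invariance, and bulk-vs-scalar agreement."""

import math
from fractions import Fraction

import numpy as np
import pytest

import topodisc as td
from topodisc.descriptors import (
    DescriptorUnavailable,
    degree_core,
    distance_core,
    entropy_core,
    extended_registry,
    spectral_core,
)

K3 = td.complete_graph(3)
K4 = td.complete_graph(4)
P3 = td.path_graph(3)
P4 = td.path_graph(4)


class TestHandCheckedValues:
    @pytest.mark.parametrize(
        "g, name, expected",
        [
            (K3, "zagreb1", 12),
            (K3, "zagreb2", 12),
            (K3, "narumiKatayama", 8),
            (K4, "zagreb1", 36),
            (K4, "narumiKatayama", 81),
            (P4, "wiener", 10),
            (P3, "wiener", 4),
        ],
    )
    def test_exact_integers(self, g, name, expected):
        v = td.compute(g, name)
        assert isinstance(v, int)
        assert v == expected

    def test_randic_p3(self):
        assert degree_core(P3, "randic") == pytest.approx(math.sqrt(2))

    def test_harary_exact_rationals(self):
        assert distance_core(K3, "harary") == Fraction(3)
        assert distance_core(P3, "harary") == Fraction(5, 2)

    def test_balaban_j_triangle(self):
        # m=3, mu=1, every distance sum is 2: J = (3/2) * 3/2 = 2.25
        assert distance_core(K3, "balabanJ") == pytest.approx(2.25)

    def test_spectral_trio(self):
        assert spectral_core(K4, "spectralRadius") == pytest.approx(3.0)
        assert spectral_core(K3, "laplacianEnergy") == pytest.approx(4.0)
        assert spectral_core(K3, "laplacianEstrada") == pytest.approx(
            1 + 2 * math.exp(3)
        )

    def test_orbit_entropy(self):
        assert entropy_core(K4, "topologicalinfocontent") == 0.0
        expect = -(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3)
        assert entropy_core(P3, "topologicalinfocontent") == pytest.approx(expect)

    def test_radial_centric(self):
        assert entropy_core(K3, "radialCentric") == 0.0
        # P3: eccentricities (2,1,2) -> classes of sizes 2 and 1
        expect = -(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3)
        assert entropy_core(P3, "radialCentric") == pytest.approx(expect)

    def test_extended_crisp_cases(self):
        assert extended_registry(K3, "modifiedZagreb") == pytest.approx(0.75)
        assert extended_registry(K3, "productofrowsums") == pytest.approx(
            3 * math.log(2)
        )
        # augmented Zagreb on K3: 3 * (4/2)^3 = 24
        assert extended_registry(K3, "augmentedZagreb") == pytest.approx(24.0)

    def test_entropy_bounds(self, c6):
        for g in c6:
            h = td.compute(g, "infotheolin1") / 1000.0
            assert 0 <= h <= math.log2(g.n) + 1e-12

    def test_info_functional_unknown_options(self):
        with pytest.raises(ValueError, match="lin"):
            entropy_core(P4, "infotheo_gcm", coeff="cubic")
        with pytest.raises(ValueError, match="sphere"):
            entropy_core(P4, "infotheo_gcm", infofunct="orbit")


class TestClosedFormsOnFamilies:
    @pytest.mark.parametrize("n", range(3, 10))
    def test_paths_and_cliques(self, n):
        assert td.compute(td.path_graph(n), "wiener") == n * (n * n - 1) // 6
        kn = td.complete_graph(n)
        assert td.compute(kn, "wiener") == n * (n - 1) // 2
        assert td.compute(kn, "laplacianEnergy") == pytest.approx(2 * (n - 1))
        assert td.compute(kn, "randic") == pytest.approx(n / 2)
        assert td.compute(kn, "spectralRadius") == pytest.approx(n - 1)


class TestRegistry:
    def test_unavailable_raises_distinct_error(self):
        with pytest.raises(DescriptorUnavailable):
            td.compute(P4, "bertz")
        with pytest.raises(KeyError):
            td.compute(P4, "noSuchIndex")

    def test_categories_match_rosters(self):
        for cat, names in td.CATEGORIES.items():
            for name in names:
                assert name in td.REGISTRY
                if td.REGISTRY[name].available:
                    assert td.REGISTRY[name].category == cat

    def test_value_kinds(self):
        kinds = {n: td.REGISTRY[n].value_kind for n in td.available_names()}
        assert kinds["wiener"] == "int"
        assert kinds["harary"] == "rational"
        assert kinds["balabanJ"] == "real"


class TestRelabelingInvariance:
    def test_all_available_descriptors(self):
        rng = np.random.default_rng(31)
        names = td.available_names()
        graphs = []
        while len(graphs) < 8:
            n = int(rng.integers(4, 8))
            edges = [
                (u, v)
                for u in range(n)
                for v in range(u + 1, n)
                if rng.random() < 0.5
            ]
            g = td.Graph(n, edges)
            if g.connected:
                graphs.append(g)
        for g in graphs:
            base = {name: td.compute(g, name) for name in names}
            for _ in range(12):
                p = list(rng.permutation(g.n))
                h = g.relabel(p)
                for name in names:
                    v = td.compute(h, name)
                    if isinstance(base[name], (int, Fraction)):
                        assert v == base[name], name
                    else:
                        assert v == pytest.approx(base[name], rel=1e-9), name


class TestBulkAgainstScalar:
    """The vectorized numba pipeline and the per-graph reference functions
    are distinct implementations; they must agree."""

    def test_core_descriptors_on_c6(self, c6):
        names = ["wiener", "harary", "balabanJ", "zagreb1", "zagreb2",
                 "randic", "narumiKatayama", "modifiedZagreb",
                 "augmentedZagreb", "productofrowsums", "spectralRadius",
                 "laplacianEnergy", "laplacianEstrada",
                 "graphIndexComplexity"]
        tables = td.compute_tables(c6, names)
        for i, g in enumerate(c6):
            for name in names:
                ref = td.compute(g, name)
                assert tables[name].values[i] == pytest.approx(
                    float(ref), rel=1e-10
                ), name

    def test_exact_keys_are_exact(self, c6):
        tables = td.compute_tables(c6, ["wiener", "harary"])
        for i, g in enumerate(c6):
            assert tables["wiener"].keys[i] == td.compute(g, "wiener")
            h = td.compute(g, "harary")
            assert Fraction(int(tables["harary"].keys[i]), 60) == h

    def test_nan_count(self):
        t = td.ValueTable("x", np.array([1.0, math.nan, math.inf]))
        assert t.nan_count == 2
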