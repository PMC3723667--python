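"""Canonical certificates: isomorphism iff equal bytes, orbits, |Aut|."""

import itertools

import numpy as np
import pytest

import topodisc as td
from topodisc import _kernels
from topodisc.canonical import canonical_code

from conftest import brute_force_classes, perm_isomorphic


class TestCertificateEquality:
    def test_relabeling_invariance_p3(self):
        base = td.path_graph(3)
        codes = {
            td.certificate(base.relabel(p)).bytes_
            for p in itertools.permutations(range(3))
        }
        assert len(codes) == 1
        assert td.certificate(td.complete_graph(3)).bytes_ not in codes

    def test_certificate_count_on_4_vertices(self):
        # 64 labeled graphs fall into 11 isomorphism classes
        pairs = list(itertools.combinations(range(4), 2))
        certs = set()
        for bits in range(64):
            edges = [pairs[i] for i in range(6) if (bits >> i) & 1]
            certs.add(td.certificate(td.Graph(4, edges)).bytes_)
        assert len(certs) == 11

    def test_equality_iff_isomorphic_exhaustive_n4(self):
        # all pairs of classes on 4 vertices, against permutation search
        reps = [td.Graph(4, list(code)) for code in brute_force_classes(4)]
        for g1, g2 in itertools.combinations(reps, 2):
            assert td.certificate(g1).bytes_ != td.certificate(g2).bytes_
            assert not perm_isomorphic(g1, g2)

    def test_equality_iff_isomorphic_n5_n6(self, c5):
        rng = np.random.default_rng(3)
        # distinct classes get distinct certificates ...
        certs5 = [td.certificate(g).bytes_ for g in c5]
        assert len(set(certs5)) == len(c5)
        # ... and relabelings keep them, for random n=6 graphs
        for _ in range(30):
            n = 6
            edges = [
                (u, v)
                for u in range(n)
                for v in range(u + 1, n)
                if rng.random() < 0.5
            ]
            g = td.Graph(n, edges)
            p = list(rng.permutation(n))
            h = g.relabel(p)
            assert perm_isomorphic(g, h)
            assert td.certificate(g).bytes_ == td.certificate(h).bytes_

    def test_random_n6_pairs_match_permutation_search(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            gs = []
            for _ in range(2):
                edges = [
                    (u, v)
                    for u in range(6)
                    for v in range(u + 1, 6)
                    if rng.random() < 0.5
                ]
                gs.append(td.Graph(6, edges))
            same_cert = td.certificate(gs[0]).bytes_ == td.certificate(gs[1]).bytes_
            assert same_cert == perm_isomorphic(gs[0], gs[1])


class TestOrbitsAndAut:
    def test_star_orbits(self):
        cert = td.certificate(td.star_graph(4))
        assert cert.orbits == ((0,), (1, 2, 3))
        assert cert.aut_order == 6

    @pytest.mark.parametrize(
        "g, order",
        [
            (td.complete_graph(4), 24),
            (td.cycle_graph(5), 10),  # dihedral group
            (td.path_graph(4), 2),
            (td.star_graph(6), 120),
        ],
    )
    def test_known_automorphism_orders(self, g, order):
        cert = td.certificate(g)
        assert cert.aut_order == order
        import math

        assert math.factorial(g.n) % cert.aut_order == 0

    def test_orbits_partition_vertices(self, c5):
        for g in c5:
            cert = td.certificate(g)
            flat = sorted(v for orb in cert.orbits for v in orb)
            assert flat == list(range(g.n))

    def test_aut_order_by_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 6))
            edges = [
                (u, v)
                for u in range(n)
                for v in range(u + 1, n)
                if rng.random() < 0.5
            ]
            g = td.Graph(n, edges)
            brute = sum(
                1
                for p in itertools.permutations(range(n))
                if g.relabel(list(p)).edges == g.edges
            )
            assert td.certificate(g).aut_order == brute


class TestFastKernelAgreement:
    """The numba canonical code and the pure-Python engine are independent
    implementations of the same canonical form."""

    def test_same_code_on_random_graphs(self):
        rng = np.random.default_rng(23)
        for _ in range(150):
            n = int(rng.integers(2, 10))
            edges = [
                (u, v)
                for u in range(n)
                for v in range(u + 1, n)
                if rng.random() < 0.5
            ]
            g = td.Graph(n, edges)
            adj = np.array(g.masks, dtype=np.int64)
            assert _kernels.canon_code(n, adj) == canonical_code(g)

    def test_highly_symmetric_graphs(self):
        for g in [td.complete_graph(7), td.star_graph(8), td.cycle_graph(8)]:
            adj = np.array(g.masks, dtype=np.int64)
            assert _kernels.canon_code(g.n, adj) == canonical_code(g)
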