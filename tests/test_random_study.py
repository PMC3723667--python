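"""Random connected graph generation and subsampled sensitivity."""

import itertools
import math

import numpy as np
import pytest

import topodisc as td
from topodisc.random_study import edge_bounds

from conftest import perm_isomorphic


class TestRandomConnectedGraph:
    def test_forced_extremes(self):
        rng = np.random.default_rng(0)
        g = td.random_connected_graph(2, 1, rng)
        assert g.edges == {(0, 1)}
        for seed in range(5):
            g = td.random_connected_graph(5, 10, np.random.default_rng(seed))
            assert g.edges == td.complete_graph(5).edges

    def test_trees_at_minimum_edge_count(self):
        rng = np.random.default_rng(61)
        for _ in range(2000):
            g = td.random_connected_graph(6, 5, rng)
            assert g.connected and g.m == 5  # connected + n-1 edges = tree

    def test_bounds_enforced(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            td.random_connected_graph(5, 3, rng)
        with pytest.raises(ValueError):
            td.random_connected_graph(5, 11, rng)

    def test_prufer_trees_uniform_over_labeled_trees(self):
        # n=4: 16 labeled trees; chi^2-style sanity band on frequencies
        rng = np.random.default_rng(67)
        counts = {}
        draws = 4800
        for _ in range(draws):
            g = td.random_connected_graph(4, 3, rng)
            counts[tuple(sorted(g.edges))] = counts.get(tuple(sorted(g.edges)), 0) + 1
        assert len(counts) == 16
        expected = draws / 16
        for c in counts.values():
            assert abs(c - expected) < 5 * math.sqrt(expected)


class TestBuildSample:
    def test_tree_quota_capped_by_census(self):
        # only 2 trees on 4 vertices up to isomorphism
        spec = td.RandomSampleSpec(n=4, edge_sizes=(3,), quota=50,
                                   max_attempts=500, seed=1)
        sample = td.build_sample(spec)
        assert len(sample) == 2
        assert sample.provenance["shortfall"] == {3: 48}

    def test_members_match_requested_sizes(self):
        spec = td.RandomSampleSpec(n=9, edge_sizes=tuple(range(8, 37, 7)),
                                   quota=3, seed=2)
        sample = td.build_sample(spec)
        sizes = sorted(set(int(m) for m in sample.edge_counts()))
        assert set(sizes) <= set(range(8, 37, 7))
        for g in sample:
            assert g.connected

    def test_no_isomorphic_pairs_by_permutation_oracle(self):
        spec = td.RandomSampleSpec(n=7, edge_sizes=(6, 9, 12), quota=6, seed=3)
        sample = td.build_sample(spec)
        graphs = list(sample)
        for g1, g2 in itertools.combinations(graphs, 2):
            assert not perm_isomorphic(g1, g2)

    def test_same_seed_reproduces_sample(self):
        spec = td.RandomSampleSpec(n=8, edge_sizes=(7, 14, 21), quota=4, seed=9)
        a, b = td.build_sample(spec), td.build_sample(spec)
        assert np.array_equal(a.masks, b.masks)

    def test_invalid_edge_size(self):
        with pytest.raises(ValueError):
            td.RandomSampleSpec(n=5, edge_sizes=(2,))


class TestSubsampling:
    def test_fraction_one_equals_full_sample(self, c6):
        t = td.compute_table(c6, "wiener")
        full = float(td.sensitivity(len(c6), td.ndv(t)))
        s = td.subsample_mean_sensitivity(t, reps=5, fraction=1.0,
                                          rng=np.random.default_rng(0))
        assert s.mean_sensitivity == pytest.approx(full)
        assert s.variance == 0.0

    def test_all_distinct_values(self):
        t = td.ValueTable("x", np.arange(40, dtype=float))
        s = td.subsample_mean_sensitivity(t, reps=10, fraction=0.5,
                                          rng=np.random.default_rng(1))
        assert s.mean_sensitivity == 1.0
        assert s.variance == 0.0

    def test_exhaustive_matches_combination_oracle(self):
        vals = np.array([1, 1, 2, 3, 3, 3, 4, 5, 6, 6, 7, 8], dtype=float)
        t = td.ValueTable("x", vals)
        got = td.subsample_mean_sensitivity(t, reps="exhaustive", fraction=0.5)
        k = 6
        accs = []
        for idx in itertools.combinations(range(12), k):
            sub = vals[list(idx)]
            nd = sum(1 for x in sub if (sub == x).sum() >= 2)
            accs.append((k - nd) / k)
        assert got.reps == math.comb(12, 6)
        assert got.mean_sensitivity == pytest.approx(np.mean(accs))
        assert got.variance == pytest.approx(np.var(accs))

    def test_subsample_too_small(self):
        t = td.ValueTable("x", np.arange(10, dtype=float))
        with pytest.raises(ValueError):
            td.subsample_mean_sensitivity(t, reps=3, fraction=0.1)

    def test_mean_converges_to_full_sample_value(self, c6):
        t = td.compute_table(c6, "zagreb1")
        full = float(td.sensitivity(len(c6), td.ndv(t)))
        devs = []
        for frac in (0.4, 0.7, 1.0):
            s = td.subsample_mean_sensitivity(
                t, reps=200, fraction=frac, rng=np.random.default_rng(5))
            devs.append(abs(s.mean_sensitivity - full))
        assert devs[2] == 0.0
        assert devs[2] <= devs[1] <= devs[0] + 1e-9


class TestCategoryStudy:
    def test_rosters_cover_all_categories(self):
        assert set(td.CATEGORIES) == {"eigenvalue", "information",
                                      "distance", "degree"}
        for names in td.CATEGORIES.values():
            assert len(names) > 0

    def test_unknown_category_rejected(self, c5):
        with pytest.raises(ValueError, match="unknown category"):
            td.category_study(c5, "spectral", "degree")

    def test_cross_category_pairs(self, c6):
        out = td.category_study(
            c6, "eigenvalue", "degree", eq_id="S1", reps=4, fraction=0.8,
            rng=np.random.default_rng(11))
        n_eig = len([x for x in td.CATEGORIES["eigenvalue"]
                     if x in td.available_names()])
        n_deg = len([x for x in td.CATEGORIES["degree"]
                     if x in td.available_names()])
        assert len(out) == n_eig * n_deg
        for s in out:
            assert 0 <= s.mean_sensitivity <= 1
            assert s.variance >= 0
            assert s.reps == 4
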