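"""Graph metrics against hand counts, algebraic identities and oracles."""

import networkx as nx
import numpy as np
import pytest

import hemimorph as hm
from hemimorph.metrics import (RandomizationConfig, all_pairs_distances,
                               characteristic_path_length,
                               clustering_coefficient, degree_centrality,
                               global_efficiency, local_efficiency,
                               nodal_efficiency, normalize_and_sigma,
                               rewire_random, _local_efficiency_numpy)


def adj(*edges, n=None):
    n = n or (max(max(e) for e in edges) + 1)
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


PATH3 = adj((0, 1), (1, 2))
TRIANGLE = adj((0, 1), (1, 2), (0, 2))


def floyd_warshall(a):
    n = len(a)
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


class TestDistances:
    def test_path_graph_distances(self):
        d = all_pairs_distances(PATH3)
        assert d[0, 1] == 1 and d[1, 2] == 1 and d[0, 2] == 2

    def test_disconnected_pairs_infinite(self):
        a = adj((0, 1), (2, 3))
        d = all_pairs_distances(a)
        assert np.isinf(d[0, 2]) and np.isinf(d[1, 3])

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = nx.gnp_random_graph(20, float(rng.uniform(0.05, 0.5)),
                                    seed=int(rng.integers(1 << 30)))
            a = nx.to_numpy_array(g).astype(np.uint8)
            np.testing.assert_array_equal(all_pairs_distances(a),
                                          floyd_warshall(a))


class TestCharacteristicPathLength:
    def test_complete_graph_is_one(self):
        assert characteristic_path_length(
            all_pairs_distances(adj(*[(i, j) for i in range(5)
                                      for j in range(i + 1, 5)]))) == 1.0

    def test_path3_harmonic_mean(self):
        assert characteristic_path_length(
            all_pairs_distances(PATH3)) == pytest.approx(1.2)

    def test_product_with_global_efficiency_is_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1 << 30)))
            a = nx.to_numpy_array(g).astype(np.uint8)
            d = all_pairs_distances(a)
            if global_efficiency(d) == 0:
                continue
            assert characteristic_path_length(d) * global_efficiency(d) \
                == pytest.approx(1.0, abs=1e-12)


class TestClustering:
    def test_triangle_is_one(self):
        assert clustering_coefficient(TRIANGLE) == 1.0

    def test_path_has_no_triangles(self):
        assert clustering_coefficient(PATH3) == 0.0

    def test_triangle_with_pendant(self):
        a = adj((0, 1), (1, 2), (0, 2), (0, 3))
        assert clustering_coefficient(a) == pytest.approx(7 / 12)


class TestEfficiencies:
    def test_complete_graph_unit_efficiency(self):
        a = adj(*[(i, j) for i in range(4) for j in range(i + 1, 4)])
        assert global_efficiency(all_pairs_distances(a)) == 1.0

    def test_path3_global_efficiency(self):
        assert global_efficiency(all_pairs_distances(PATH3)) \
            == pytest.approx(5 / 6)

    def test_empty_graph_zero(self):
        assert global_efficiency(all_pairs_distances(np.zeros((4, 4),
                                                              np.uint8))) == 0

    def test_local_efficiency_triangle_one_star_zero(self):
        assert local_efficiency(TRIANGLE) == 1.0
        star = adj((0, 1), (0, 2), (0, 3))
        assert local_efficiency(star) == 0.0

    def test_local_efficiency_matches_subgraph_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            g = nx.gnp_random_graph(15, float(rng.uniform(0.15, 0.6)),
                                    seed=int(rng.integers(1 << 30)))
            a = nx.to_numpy_array(g).astype(np.uint8)
            # independent oracle: networkx subgraph efficiency
            assert local_efficiency(a) == pytest.approx(
                nx.local_efficiency(g), abs=1e-12)
            assert _local_efficiency_numpy(a) == pytest.approx(
                nx.local_efficiency(g), abs=1e-12)

    def test_nodal_efficiency_path3_and_mean_identity(self):
        e = nodal_efficiency(all_pairs_distances(PATH3))
        np.testing.assert_allclose(e, [0.75, 1.0, 0.75])
        rng = np.random.default_rng(3)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 30)))
            d = all_pairs_distances(nx.to_numpy_array(g).astype(np.uint8))
            assert nodal_efficiency(d).mean() == pytest.approx(
                global_efficiency(d), abs=1e-12)


class TestDegree:
    def test_path3_degrees(self):
        np.testing.assert_array_equal(degree_centrality(PATH3), [1, 2, 1])

    def test_handshake_identity(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(18, 0.25, seed=7)
        a = nx.to_numpy_array(g).astype(np.uint8)
        assert degree_centrality(a).sum() == 2 * g.number_of_edges()


class TestRewiring:
    def test_degree_sequence_preserved(self):
        g = nx.gnp_random_graph(30, 0.2, seed=9)
        a = nx.to_numpy_array(g).astype(np.uint8)
        for r in rewire_random(a, RandomizationConfig(n_random=5, seed=1)):
            np.testing.assert_array_equal(r.sum(1), a.sum(1))
            np.testing.assert_array_equal(r, r.T)
            assert (np.diag(r) == 0).all()

    def test_triangle_only_graph_with_its_degrees(self):
        outs = rewire_random(TRIANGLE, RandomizationConfig(n_random=3, seed=2))
        for r in outs:
            np.testing.assert_array_equal(r, TRIANGLE)

    def test_requested_number_of_surrogates(self):
        g = nx.gnp_random_graph(12, 0.4, seed=3)
        a = nx.to_numpy_array(g).astype(np.uint8)
        outs = rewire_random(a, RandomizationConfig(n_random=100, seed=0))
        assert len(outs) == 100

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(25, 0.3, seed=5)
        a = nx.to_numpy_array(g).astype(np.uint8)
        r1 = rewire_random(a, RandomizationConfig(n_random=2, seed=12))
        r2 = rewire_random(a, RandomizationConfig(n_random=2, seed=12))
        for x, y in zip(r1, r2):
            np.testing.assert_array_equal(x, y)


class TestSigma:
    def test_self_normalization_gives_sigma_one(self):
        a = nx.to_numpy_array(nx.gnp_random_graph(15, 0.3, seed=6)).astype(np.uint8)
        d = all_pairs_distances(a)
        lp = characteristic_path_length(d)
        cp = clustering_coefficient(a)
        lam, gam, sigma, _, _ = normalize_and_sigma(lp, cp, [a, a])
        assert sigma == pytest.approx(1.0, abs=1e-12)

    def test_sigma_equals_gamma_over_lambda(self):
        a = nx.to_numpy_array(nx.gnp_random_graph(20, 0.3, seed=8)).astype(np.uint8)
        d = all_pairs_distances(a)
        lam, gam, sigma, _, _ = normalize_and_sigma(
            characteristic_path_length(d), clustering_coefficient(a),
            rewire_random(a, RandomizationConfig(n_random=5, seed=0)))
        assert sigma == pytest.approx(gam / lam, abs=1e-12)

    def test_ring_lattice_is_small_world_after_rewiring(self):
        ws = nx.watts_strogatz_graph(100, 8, 0.05, seed=2)
        a = nx.to_numpy_array(ws).astype(np.uint8)
        gm = hm.compute_global_metrics(
            a, randomization=RandomizationConfig(n_random=20, seed=4))
        assert gm.sigma > 1.0


class TestMonotonicity:
    def test_efficiency_monotone_in_sparsity(self, tiny_cohort,
                                             tiny_parcellation):
        tables, _ = tiny_cohort
        nets = hm.subject_networks(tables[1], tiny_parcellation)
        for h in ("L", "R"):
            eg, lp = [], []
            for k in sorted(nets[h].binaries):
                d = all_pairs_distances(nets[h].binaries[k], validate=False)
                eg.append(global_efficiency(d))
                lp.append(characteristic_path_length(d))
            assert all(x <= y + 1e-12 for x, y in zip(eg, eg[1:]))
            assert all(x >= y - 1e-12 for x, y in zip(lp, lp[1:]))
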