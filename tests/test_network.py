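"""Jensen-Shannon edge weights and sparsity binarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import jensenshannon

import hemimorph as hm
from hemimorph.network import (LN2, SparsityGrid, binarize,
                               build_weight_matrix, jsd, jsd_matrix, jss)

from conftest import random_density_pair


def two_point(p0: float) -> hm.RegionDensity:
    return hm.RegionDensity(0, np.array([1.0, 2.0]),
                            np.array([p0, 1.0 - p0]))


class TestJSD:
    def test_identical_distributions_give_zero(self):
        p, _ = random_density_pair(0)
        assert jsd(p, p) == 0.0

    def test_hand_evaluated_two_point_example(self):
        # p=(0.75, 0.25), q=(0.25, 0.75): 0.75 ln 1.5 + 0.25 ln 0.5
        assert jsd(two_point(0.75), two_point(0.25)) == pytest.approx(
            0.1308, abs=5e-5)

    def test_disjoint_support_limit_is_ln2(self):
        eps = 1e-12
        p = hm.RegionDensity(0, np.array([1.0, 2.0]), np.array([1 - eps, eps]))
        q = hm.RegionDensity(1, np.array([1.0, 2.0]), np.array([eps, 1 - eps]))
        assert jsd(p, q) == pytest.approx(LN2, abs=1e-9)

    def test_mismatched_grids_rejected(self):
        p, _ = random_density_pair(1)
        q = hm.RegionDensity(1, p.grid + 0.1, p.mass)
        with pytest.raises(ValueError, match="grid"):
            jsd(p, q)

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_metric_like_and_matches_scipy(self, seed):
        p, q = random_density_pair(seed)
        val = jsd(p, q)
        assert 0.0 <= val <= LN2 + 1e-12
        assert jsd(q, p) == pytest.approx(val, abs=1e-15)
        ref = jensenshannon(p.mass, q.mass) ** 2  # scipy returns sqrt(JSD)
        assert val == pytest.approx(ref, abs=1e-12)

    def test_direct_elementwise_oracle(self):
        for seed in range(20):
            p, q = random_density_pair(seed)
            m = (p.mass + q.mass) / 2
            direct = 0.5 * float(np.sum(p.mass * np.log(p.mass / m))) \
                + 0.5 * float(np.sum(q.mass * np.log(q.mass / m)))
            assert jsd(p, q) == pytest.approx(direct, abs=1e-12)


class TestJSS:
    def test_self_similarity_is_one(self):
        p, _ = random_density_pair(2)
        assert jss(p, p) == 1.0

    def test_maximal_divergence_maps_to_half(self):
        eps = 1e-13
        p = hm.RegionDensity(0, np.array([1.0, 2.0]), np.array([1 - eps, eps]))
        q = hm.RegionDensity(1, np.array([1.0, 2.0]), np.array([eps, 1 - eps]))
        assert jss(p, q) == pytest.approx(0.5, abs=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry(self, seed):
        p, q = random_density_pair(seed)
        assert abs(jss(p, q) - jss(q, p)) < 1e-12


class TestWeightMatrix:
    def test_three_densities_symmetric_zero_diagonal(self):
        ds = [random_density_pair(i)[0] for i in range(3)]
        for i, d in enumerate(ds):
            object.__setattr__(d, "subregion_id", i)
        w = build_weight_matrix(ds)
        assert w.shape == (3, 3)
        np.testing.assert_array_equal(w, w.T)
        assert (np.diag(w) == 0).all()

    def test_duplicated_densities_give_unit_offdiagonal(self):
        p, _ = random_density_pair(4)
        w = build_weight_matrix([p, p, p])
        off = w[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0, atol=1e-12)

    def test_matrix_agrees_with_pairwise_jsd(self):
        ds = [random_density_pair(i)[0] for i in range(5)]
        w = build_weight_matrix(ds)
        for i in range(5):
            for j in range(i + 1, 5):
                assert w[i, j] == pytest.approx(jss(ds[i], ds[j]), abs=1e-12)


class TestBinarize:
    def test_sparsity_grid_default_14_levels(self):
        grid = SparsityGrid()
        assert len(grid) == 14
        assert grid.values[0] == pytest.approx(0.10)
        assert grid.values[-1] == pytest.approx(0.36)

    def test_edge_count_at_ten_percent_on_256_nodes(self):
        rng = np.random.default_rng(0)
        w = np.triu(rng.random((256, 256)), 1)
        w = w + w.T
        b = binarize(w, SparsityGrid((0.10,)))[0.10]
        assert b.sum() // 2 == 3264  # floor(0.10 * 256*255/2)

    def test_top_edges_kept_against_sort_oracle(self):
        rng = np.random.default_rng(1)
        w = np.triu(rng.random((5, 5)), 1)
        w = w + w.T
        b = binarize(w, SparsityGrid((0.4,)))[0.4]
        ii, jj = np.triu_indices(5, 1)
        top4 = sorted(zip(w[ii, jj], ii, jj), reverse=True)[:4]
        expect = np.zeros((5, 5), dtype=np.uint8)
        for _, i, j in top4:
            expect[i, j] = expect[j, i] = 1
        np.testing.assert_array_equal(b, expect)

    def test_edge_sets_nested_across_levels(self):
        rng = np.random.default_rng(2)
        w = np.triu(rng.random((40, 40)), 1)
        w = w + w.T
        bins = binarize(w, SparsityGrid())
        levels = sorted(bins)
        for lo, hi in zip(levels, levels[1:]):
            assert np.all(bins[lo] <= bins[hi])

    def test_full_sparsity_gives_complete_graph(self):
        rng = np.random.default_rng(3)
        w = np.triu(rng.random((6, 6)), 1)
        w = w + w.T
        b = binarize(w, SparsityGrid((0.999999,)))[0.999999]
        assert b.sum() == 6 * 5 - 2  # floor(K*15)=14 edges of 15

    def test_zero_edge_level_rejected(self):
        w = np.zeros((4, 4))
        with pytest.raises(ValueError, match="zero edges"):
            binarize(w, SparsityGrid((0.01,)))


class TestSubjectNetworks:
    def test_tiny_pipeline_shapes_and_bounds(self, tiny_cohort,
                                             tiny_parcellation):
        tables, _ = tiny_cohort
        nets = hm.subject_networks(tables[0], tiny_parcellation,
                                   grid=SparsityGrid((0.2, 0.3)))
        for h in ("L", "R"):
            w = nets[h].weights
            assert w.shape == (24, 24)
            off = w[~np.eye(24, dtype=bool)]
            assert ((off > 0.5 - 1e-12) & (off <= 1.0)).all()
            for k, a in nets[h].binaries.items():
                m = 24 * 23 // 2
                assert a.sum() // 2 == int(np.floor(k * m))
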