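import numpy as np
import pytest

import dynor as dy
from dynor.graphs import MULTISCALE_SIZES

from conftest import random_connected


class TestGenerators:
    def test_complete_blocks_give_k4(self):
        g, part = dy.generate_sbm([2, 2], np.ones((2, 2)), seed=0)
        assert g.n_nodes == 4 and g.n_edges == 6
        assert g.is_connected

    def test_disconnected_blocks_flagged(self):
        g, _ = dy.generate_sbm([2, 2], [[1, 0], [0, 1]], seed=0)
        assert g.n_edges == 2
        assert not g.is_connected

    def test_edge_counts_match_binomial_means(self):
        """Within/between edge counts match binomial expectations (100 seeds)."""
        n_within = n_between = 0
        seeds = 100
        for s in range(seeds):
            g, part = dy.generate_ssbm(100, 0.5, 0.1, seed=s)
            same = part.labels[g.edges[:, 0]] == part.labels[g.edges[:, 1]]
            n_within += same.sum()
            n_between += (~same).sum()
        mw, mb = 2 * 1225 * 0.5, 2500 * 0.1
        sw = np.sqrt(2 * 1225 * 0.5 * 0.5 / seeds)
        sb = np.sqrt(2500 * 0.1 * 0.9 / seeds)
        assert abs(n_within / seeds - mw) < 4 * sw
        assert abs(n_between / seeds - mb) < 4 * sb

    def test_ssbm_records_degree_and_ratio(self):
        _, part = dy.generate_ssbm(100, 8 / 100, 0.5 / 100, seed=0)
        assert part.k_bar == pytest.approx(4.25)
        _, part = dy.generate_ssbm(100, 0.5, 0.1, seed=0)
        assert part.r == pytest.approx(0.2)

    def test_ssbm_rejects_odd_n(self):
        with pytest.raises(ValueError):
            dy.generate_ssbm(101, 0.5, 0.1)

    def test_sbm_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            dy.generate_sbm([5, 5], [[1.2, 0], [0, 1.2]])
        with pytest.raises(ValueError):
            dy.generate_sbm([5, 0], [[0.5, 0.1], [0.1, 0.5]])

    def test_multiscale_sbm_structure(self):
        g, fine, coarse = dy.generate_multiscale_sbm(seed=0)
        assert g.n_nodes == sum(MULTISCALE_SIZES) == 155
        assert fine.n_blocks == 4 and coarse.n_blocks == 2
        # coarse labels are a coarsening of the fine ones
        for c in range(4):
            blk = coarse.labels[fine.labels == c]
            assert len(np.unique(blk)) == 1
        # block-1 within-edge count near binomial mean C(30,2)*0.7
        counts = []
        for s in range(10):
            gg, ff, _ = dy.generate_multiscale_sbm(seed=s)
            in1 = (ff.labels[gg.edges[:, 0]] == 0) & (ff.labels[gg.edges[:, 1]] == 0)
            counts.append(in1.sum())
        mean, sd = 435 * 0.7, np.sqrt(435 * 0.7 * 0.3 / 10)
        assert abs(np.mean(counts) - mean) < 4 * sd

    @pytest.mark.parametrize("kind,params,n_edges", [
        ("clique", {"n": 3}, 3),
        ("cycle", {"n": 100}, 100),
        ("path", {"n": 5}, 4),
        ("balanced_tree", {"depth": 3}, 14),
    ])
    def test_canonical_sizes(self, kind, params, n_edges):
        g = dy.generate_canonical(kind, **params)
        assert g.n_edges == n_edges

    def test_cycle_is_two_regular(self):
        g = dy.generate_canonical("cycle", n=100)
        assert np.all(g.degrees == 2)

    def test_er_mean_degree(self):
        degs = []
        for s in range(20):
            g = dy.generate_canonical("erdos_renyi", n=1000, p=8.5 / 2000, seed=s)
            degs.append(g.degrees.mean())
        assert np.mean(degs) == pytest.approx(999 * 8.5 / 2000, rel=0.05)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            dy.generate_canonical("petersen", n=10)


class TestSimilarity:
    def test_exponential(self):
        assert dy.to_similarity(np.array([np.log(2)]), "exponential")[0] == pytest.approx(0.5)
        assert dy.to_similarity(np.array([1e-12]), "exponential")[0] == pytest.approx(1.0)

    def test_shifted_and_degeneracy_warning(self):
        with pytest.warns(UserWarning):
            a = dy.to_similarity(np.array([1.0, 2.0]), "shifted")
        assert np.allclose(a, [1.0, 0.0])

    def test_unit(self):
        assert np.allclose(dy.to_similarity(np.array([3.0, 7.0]), "unit"), 1.0)


class TestGeodesics:
    def test_path_distance(self, path3):
        geo = dy.geodesics(path3)
        assert geo.d[0, 2] == 2
        assert geo.d0 == 1

    def test_heavy_edge_bypassed(self):
        g = dy.WeightedGraph(3, [[0, 1], [0, 2], [1, 2]], [1.0, 1.0, 3.0],
                             [1.0, 1.0, 1.0])
        geo = dy.geodesics(g)
        assert geo.d[1, 2] == 2  # through node 0, not the weight-3 edge
        assert geo.d0 == 1

    def test_single_edge(self):
        g = dy.WeightedGraph(2, [[0, 1]], [2.5], [1.0])
        geo = dy.geodesics(g)
        assert geo.d[0, 1] == 2.5 and geo.d0 == 2.5

    def test_triangle_inequality_exhaustive(self):
        g = random_connected(30, 0.15, seed=7)
        d = dy.geodesics(g).d
        for i in range(30):
            for j in range(30):
                assert np.all(d[i, j] <= d[i, :] + d[:, j] + 1e-12)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        # d_ij <= w_ij on edges
        u, v = g.edges[:, 0], g.edges[:, 1]
        assert np.all(d[u, v] <= g.w + 1e-12)

    def test_disconnected_rejected(self):
        g = dy.WeightedGraph(4, [[0, 1], [2, 3]], [1, 1], [1, 1])
        with pytest.raises(dy.DisconnectedGraphError):
            dy.geodesics(g)


class TestFeatureGraphs:
    def test_jaccard_values(self):
        B = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 0]])
        g = dy.jaccard_graph(B)
        adj = g.adjacency().toarray()
        assert adj[0, 2] == pytest.approx(1.0)   # identical rows
        assert adj[0, 1] == pytest.approx(1 / 3)

    def test_disjoint_rows_carry_no_edge(self):
        B = np.array([[1, 0], [0, 1]])
        g = dy.jaccard_graph(B)
        assert g.n_edges == 0

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError):
            dy.jaccard_graph(np.array([[1, 0], [0, 0]]))

    def test_jaccard_symmetry_random(self):
        rng = np.random.default_rng(0)
        B = (rng.random((20, 15)) < 0.4).astype(int)
        B[B.sum(axis=1) == 0, 0] = 1
        g = dy.jaccard_graph(B)
        adj = g.adjacency().toarray()
        assert np.allclose(adj, adj.T)

    def test_filter_features(self):
        B = np.zeros((20, 4), dtype=int)
        B[:, 1] = 1           # 100% expressed -> dropped
        B[:19, 2] = 1         # 95% -> dropped at 0.9
        B[:10, 3] = 1         # 50% -> kept
        red, kept = dy.filter_features(B, upper_frac=0.9)
        assert list(kept) == [3]
        red2, kept2 = dy.filter_features(red, upper_frac=0.9)
        assert red2.shape == red.shape  # idempotent

    def test_filter_all_dropped_rejected(self):
        with pytest.raises(ValueError):
            dy.filter_features(np.zeros((5, 3), dtype=int))


class TestSparsify:
    def test_gamma_one_keeps_graph(self):
        g = random_connected(20, 0.3, seed=1)
        out = dy.simple_sparsify(g, 1.0)
        assert out.n_edges == g.n_edges

    def test_tree_unchanged(self):
        g = dy.generate_canonical("balanced_tree", depth=3)
        out = dy.simple_sparsify(g, 0.1)
        assert out.n_edges == g.n_edges

    def test_k4_reduces_to_spanning_tree(self):
        g = dy.generate_canonical("clique", n=4)
        out = dy.simple_sparsify(g, 0.01)
        assert out.n_edges == 3 and out.is_connected

    def test_output_connected(self):
        for s in range(5):
            g = random_connected(25, 0.25, seed=100 + s)
            out = dy.simple_sparsify(g, 0.3)
            assert out.is_connected

    def test_bad_gamma(self):
        g = dy.generate_canonical("clique", n=4)
        with pytest.raises(ValueError):
            dy.simple_sparsify(g, 0.0)
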