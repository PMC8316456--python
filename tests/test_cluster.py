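import numpy as np
import pytest

import dynor as dy
from dynor.cluster import ModularityContext, canonical_labels


def _context(edges, kappa, n, kappa0=None):
    kappa = np.asarray(kappa, dtype=float)
    if kappa0 is None:
        kappa0 = kappa.max()
    return ModularityContext(edges=np.asarray(edges), kappa_slice=kappa,
                             kappa0=kappa0, n_nodes=n)


class TestGeometricModularity:
    def test_singletons_score_zero(self):
        ctx = _context([[0, 1], [1, 2]], [0.5, -0.2], 3, kappa0=0.0)
        assert dy.geometric_modularity(ctx, np.arange(3)) == 0.0

    def test_all_in_one_nonpositive_at_tau_min(self):
        """With kappa0 = max kappa every edge weight is <= 0, so merging
        everything cannot beat singletons."""
        rng = np.random.default_rng(0)
        kappa = rng.uniform(-0.5, 0.3, size=6)
        ctx = _context([[i, j] for i in range(4) for j in range(i + 1, 4)],
                       kappa, 4)
        assert dy.geometric_modularity(ctx, np.zeros(4)) <= 0.0

    def test_two_cliques_prefer_two_communities(self):
        edges, kappa = [], []
        for base in (0, 3):
            for i in range(3):
                for j in range(i + 1, 3):
                    edges.append([base + i, base + j])
                    kappa.append(0.9)
        edges.append([2, 3]); kappa.append(0.05)
        ctx = _context(edges, kappa, 6, kappa0=0.1)
        two = dy.geometric_modularity(ctx, np.array([0, 0, 0, 1, 1, 1]))
        assert two > dy.geometric_modularity(ctx, np.arange(6))
        assert two > dy.geometric_modularity(ctx, np.zeros(6))

    def test_relabelling_invariance(self):
        ctx = _context([[0, 1], [1, 2], [2, 3]], [0.4, -0.1, 0.6], 4, kappa0=0.1)
        a = dy.geometric_modularity(ctx, np.array([0, 0, 1, 1]))
        b = dy.geometric_modularity(ctx, np.array([5, 5, 2, 2]))
        assert a == pytest.approx(b)

    def test_zero_normaliser_rejected(self):
        ctx = _context([[0, 1]], [0.0], 2, kappa0=0.0)
        with pytest.raises(ValueError):
            dy.geometric_modularity(ctx, np.zeros(2))


class TestLouvainSigned:
    def test_all_negative_yields_singletons(self):
        edges = [[0, 1], [1, 2], [0, 2]]
        best, _, _ = dy.louvain_signed(edges, [-1.0, -1.0, -1.0], 3, seed=0, n_runs=5)
        assert best.n_communities == 3

    def test_all_positive_yields_single_community(self):
        edges = [[0, 1], [1, 2], [2, 3]]
        best, _, _ = dy.louvain_signed(edges, [1.0, 1.0, 1.0], 4, seed=0, n_runs=5)
        assert best.n_communities == 1

    def test_two_cliques_with_negative_bridge(self):
        """Two K5s joined by a repulsive bridge split cleanly for every seed."""
        edges, b = [], []
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    edges.append([base + i, base + j])
                    b.append(1.0)
        edges.append([4, 5]); b.append(-1.0)
        expected = np.array([0] * 5 + [1] * 5)
        for seed in range(10):
            best, _, _ = dy.louvain_signed(edges, b, 10, seed=seed, n_runs=3)
            assert dy.partition_agreement(best.labels, expected) == 1.0

    def test_objective_nondecreasing_in_runs(self):
        rng = np.random.default_rng(7)
        edges = [[i, j] for i in range(12) for j in range(i + 1, 12)
                 if rng.random() < 0.4]
        b = rng.normal(0, 1, size=len(edges))
        _, _, obj1 = dy.louvain_signed(edges, b, 12, seed=0, n_runs=1)
        _, _, obj20 = dy.louvain_signed(edges, b, 12, seed=0, n_runs=20)
        assert obj20.max() >= obj1.max() - 1e-12

    def test_nonfinite_weights_rejected(self):
        with pytest.raises(ValueError):
            dy.louvain_signed([[0, 1]], [np.nan], 2)


class TestVariationOfInformation:
    def test_identical_partitions(self):
        assert dy.variation_of_information([0, 0, 1, 1], [1, 1, 0, 0]) == 0.0

    def test_independent_halves(self):
        got = dy.variation_of_information([0, 0, 1, 1], [0, 1, 0, 1])
        assert got == pytest.approx(2 * np.log(2))

    def test_refinement(self):
        got = dy.variation_of_information([0, 0, 1, 1], [0, 1, 2, 3])
        assert got == pytest.approx(np.log(2))

    def test_triangle_inequality_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            p1, p2, p3 = (rng.integers(0, 3, size=n) for _ in range(3))
            d12 = dy.variation_of_information(p1, p2)
            d23 = dy.variation_of_information(p2, p3)
            d13 = dy.variation_of_information(p1, p3)
            assert d13 <= d12 + d23 + 1e-10

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        p1 = rng.integers(0, 4, size=30)
        p2 = rng.integers(0, 3, size=30)
        assert dy.variation_of_information(p1, p2) == pytest.approx(
            dy.variation_of_information(p2, p1))


class TestPartitionHelpers:
    def test_canonical_labels_dense(self):
        assert list(canonical_labels([7, 7, 3, 9, 3])) == [0, 0, 1, 2, 1]

    def test_agreement_under_permutation(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([2, 2, 0, 0, 1, 1])
        assert dy.partition_agreement(a, b) == 1.0

    def test_partial_agreement(self):
        a = np.array([0, 0, 0, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 1, 1])
        assert dy.partition_agreement(a, b) == pytest.approx(5 / 6)


class TestScanEndpoints:
    def test_end_of_range_partitions(self):
        """Smallest scale: all singletons; largest: one community."""
        g, fine, _ = dy.generate_multiscale_sbm(seed=0)
        grid = dy.ScaleGrid(np.array([0.01, 2.0, 60.0]))
        scan = dy.scale_scan(g, grid, n_runs=8, n_vi=5, seed=0,
                             method="sinkhorn")
        assert scan.n_communities[0] == g.n_nodes
        assert scan.n_communities[-1] == 1
        assert np.allclose(np.diag(scan.vi_cross), 0)
        assert np.allclose(scan.vi_cross, scan.vi_cross.T)

    def test_single_clique_merges_past_first_scales(self):
        g = dy.generate_canonical("clique", n=10)
        grid = dy.ScaleGrid(np.array([0.01, 1.0, 5.0]))
        scan = dy.scale_scan(g, grid, n_runs=5, n_vi=3, seed=1, method="lp")
        assert scan.n_communities[-1] == 1
        assert scan.n_communities[1] == 1

    def test_robust_scales_strict_tolerance_empty(self):
        g = dy.generate_canonical("clique", n=8)
        grid = dy.ScaleGrid(np.array([0.01, 0.5, 1.0, 5.0]))
        scan = dy.scale_scan(g, grid, n_runs=5, n_vi=3, seed=0, method="lp")
        strict = dy.robust_scales(scan, vi_tol=-1.0)
        assert strict == []
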