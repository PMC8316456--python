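import numpy as np
import pytest

import dynor as dy
from dynor.diffusion import spectral_measures

from conftest import random_connected


class TestOperator:
    def test_k2_laplacian(self, k2):
        op = dy.build_operator(k2)
        assert np.allclose(op.L.toarray(), [[1, -1], [-1, 1]])

    def test_row_sums_zero(self):
        g = random_connected(30, 0.2, seed=3)
        op = dy.build_operator(g)
        assert np.allclose(np.asarray(op.L.sum(axis=1)).ravel(), 0, atol=1e-12)
        off = op.L.toarray() - np.diag(np.diag(op.L.toarray()))
        assert np.all(off <= 1e-12)

    def test_path_stationary(self, path3):
        op = dy.build_operator(path3)
        assert np.allclose(op.pi, [0.25, 0.5, 0.25])
        assert op.pi.sum() == pytest.approx(1.0)

    def test_stationary_is_invariant(self, path3):
        op = dy.build_operator(path3)
        grid = dy.ScaleGrid(np.array([0.7]))
        # pi as initial mixture stays fixed: pi^T e^{-tau L} = pi^T
        ms = dy.diffuse(op, grid, [0, 1, 2])
        mixed = (op.pi[:, None] * ms.p[:, 0, :]).sum(axis=0)
        assert np.allclose(mixed, op.pi, atol=1e-10)

    def test_disconnected_rejected(self):
        g = dy.WeightedGraph(4, [[0, 1], [2, 3]], [1, 1], [1, 1])
        with pytest.raises(dy.DisconnectedGraphError):
            dy.build_operator(g)


class TestDiffuse:
    def test_k2_closed_form(self, k2):
        op = dy.build_operator(k2)
        taus = np.logspace(-2, 1, 20)
        ms = dy.diffuse(op, dy.ScaleGrid(taus), [0])
        expected = np.stack([(1 + np.exp(-2 * taus)) / 2,
                             (1 - np.exp(-2 * taus)) / 2], axis=1)
        assert np.allclose(ms.p[0], expected, atol=1e-9)

    def test_small_tau_is_near_delta(self, path3):
        op = dy.build_operator(path3)
        ms = dy.diffuse(op, dy.ScaleGrid(np.array([1e-8])), [1])
        assert ms.p[0, 0, 1] > 1 - 1e-6

    def test_large_tau_reaches_stationarity(self):
        g = random_connected(15, 0.3, seed=5)
        op = dy.build_operator(g)
        ms = dy.diffuse(op, dy.ScaleGrid(np.array([50.0])), [0, 7])
        assert np.abs(ms.p[:, 0, :] - op.pi).max() < 1e-6

    def test_mass_conservation(self):
        g = random_connected(40, 0.15, seed=11)
        op = dy.build_operator(g)
        grid = dy.ScaleGrid.logspace(0.01, 30, 15)
        ms = dy.diffuse(op, grid, np.arange(10))
        assert np.abs(ms.p.sum(axis=-1) - 1).max() < 1e-9
        assert ms.p.min() >= 0

    def test_semigroup(self):
        g = random_connected(12, 0.4, seed=2)
        op = dy.build_operator(g)
        one = dy.diffuse(op, dy.ScaleGrid(np.array([0.9])), [3]).p[0, 0]
        two = dy.diffuse(op, dy.ScaleGrid(np.array([0.4, 0.9])), [3]).p[0, 1]
        assert np.abs(one - two).max() < 1e-7

    def test_tv_to_stationarity_monotone(self):
        g = random_connected(20, 0.25, seed=9)
        op = dy.build_operator(g)
        grid = dy.ScaleGrid.logspace(0.05, 40, 25)
        ms = dy.diffuse(op, grid, np.arange(5))
        tv = 0.5 * np.abs(ms.p - op.pi).sum(axis=-1)
        assert np.all(np.diff(tv, axis=1) <= 1e-9)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            dy.ScaleGrid(np.array([-1.0, 2.0]))


class TestTrim:
    def test_cutoff_zero_unchanged(self, path3):
        op = dy.build_operator(path3)
        ms = dy.diffuse(op, dy.ScaleGrid(np.array([1.0])), [0])
        assert np.allclose(dy.trim(ms, 0.0).p, ms.p)

    def test_renormalisation_arithmetic(self):
        ms = dy.MeasureSet(p=np.array([[[0.5, 0.3, 0.15, 0.05]]]),
                           seeds=[0], grid=dy.ScaleGrid(np.array([1.0])))
        out = dy.trim(ms, 0.1)
        assert np.allclose(out.p[0, 0], np.array([0.5, 0.3, 0.15, 0]) / 0.95)
        assert out.removed_mass[0, 0] == pytest.approx(0.05)

    def test_cutoff_removing_everything_rejected(self):
        ms = dy.MeasureSet(p=np.full((1, 1, 4), 0.25), seeds=[0],
                           grid=dy.ScaleGrid(np.array([1.0])))
        with pytest.raises(ValueError):
            dy.trim(ms, 0.9)


class TestSpectral:
    def test_k2_eigenvalues(self, k2):
        basis = dy.spectral(dy.build_operator(k2))
        assert np.allclose(basis.lambdas, [0, 2], atol=1e-12)
        assert np.allclose(basis.phis[:, 0], basis.phis[0, 0])

    def test_eigenvalue_range(self):
        for s in range(3):
            g = random_connected(60, 0.1, seed=20 + s)
            basis = dy.spectral(dy.build_operator(g))
            assert basis.lambdas[0] == pytest.approx(0, abs=1e-10)
            assert basis.lambdas.max() <= 2 + 1e-10

    def test_spectral_reconstruction_matches_exponential(self):
        """Full-basis spectral expansion reproduces expm-based measures."""
        g = random_connected(50, 0.12, seed=31)
        op = dy.build_operator(g)
        grid = dy.ScaleGrid.logspace(0.1, 10, 5)
        basis = dy.spectral(op)
        exact = dy.diffuse(op, grid, [0, 5, 9])
        spec = spectral_measures(basis, grid, [0, 5, 9])
        assert np.abs(exact.p - spec.p).max() < 1e-7

    def test_sign_convention(self):
        g = random_connected(20, 0.3, seed=4)
        basis = dy.spectral(dy.build_operator(g))
        for s in range(basis.phis.shape[1]):
            col = basis.phis[:, s]
            assert col[np.abs(col).argmax()] > 0


class TestDeltaPhi:
    def test_constant_eigenvector_gives_zero(self, path3):
        basis = dy.spectral(dy.build_operator(path3))
        dphi = dy.delta_phi(basis, path3)
        assert dphi[0] == pytest.approx(0, abs=1e-10)

    def test_orientation_convention(self, path3):
        """With the fixed u < v orientation the statistic is reproducible."""
        basis = dy.spectral(dy.build_operator(path3))
        a = dy.delta_phi(basis, path3)
        b = dy.delta_phi(basis, path3)
        assert np.allclose(a, b)
        assert np.all(a >= 0)


class TestLabelCorrelation:
    def test_perfect_and_null(self):
        labels = np.array([0, 0, 1, 1])
        assert dy.label_correlation(np.array([1, 1, -1, -1.0]), labels) == pytest.approx(1.0)
        assert dy.label_correlation(np.ones(4), labels) == 0.0
        assert dy.label_correlation(np.array([1, -1, 1, -1.0]), labels) == pytest.approx(0.0)

    def test_requires_two_blocks(self):
        with pytest.raises(ValueError):
            dy.label_correlation(np.ones(3), np.array([0, 1, 2]))
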