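"""SHORE basis construction, weighted regularized fit, prediction."""

import numpy as np
import pytest

import dwimoco as dm
from dwimoco.shore import (
    ShoreCoefficients,
    build_basis,
    fit_shore,
    predict_signal,
    regularization_operators,
    shore_index_set,
    shore_radial,
)

ZETA = 700.0


@pytest.fixture(scope="module")
def basis6(dense_q_points):
    return build_basis(shore_index_set(6), dense_q_points, ZETA)


class TestIndexSet:
    @pytest.mark.parametrize("order,count", [(0, 1), (2, 8), (4, 29),
                                             (6, 72)])
    def test_cardinality(self, order, count):
        idx = shore_index_set(order)
        assert len(idx) == count
        # matches the closed-form count
        assert count == sum(
            (order - l + 1) * (2 * l + 1) for l in range(0, order + 1, 2)
        )

    def test_index_constraints(self):
        for n, l, m in shore_index_set(6):
            assert l % 2 == 0 and 0 <= l <= 6
            assert l <= n <= 6
            assert -l <= m <= l

    @pytest.mark.parametrize("bad", [-2, 3, 5])
    def test_invalid_order_rejected(self, bad):
        with pytest.raises(ValueError):
            shore_index_set(bad)


class TestBasisMatrix:
    def test_q0_rows_zero_for_l_positive(self):
        idx = shore_index_set(6)
        b = build_basis(idx, np.zeros((2, 3)), ZETA)
        ls = np.array([l for (_, l, _) in idx])
        assert np.all(b.design_matrix[:, ls > 0] == 0)
        assert np.all(b.design_matrix[:, ls == 0] != 0)

    def test_antipodal_symmetry(self, dense_q_points):
        idx = shore_index_set(4)
        b_plus = build_basis(idx, dense_q_points, ZETA)
        b_minus = build_basis(idx, -dense_q_points, ZETA)
        np.testing.assert_allclose(b_plus.design_matrix,
                                   b_minus.design_matrix, atol=1e-12)

    def test_radial_orthonormality_quadrature(self):
        """Gram matrix of X_nl under the measure q^2 dq is the identity
        (Gauss-Legendre quadrature oracle)."""
        nodes, wts = np.polynomial.legendre.leggauss(400)
        qmax = 8 * np.sqrt(ZETA)
        q = 0.5 * qmax * (nodes + 1.0)
        w = 0.5 * qmax * wts * q * q
        for l in (0, 2, 4, 6):
            X = np.stack([shore_radial(n, l, q, ZETA)
                          for n in range(l, 7)])
            gram = (X * w) @ X.T
            np.testing.assert_allclose(gram, np.eye(len(X)), atol=1e-3)

    def test_full_gram_identity_quadrature(self):
        """3D orthonormality of Phi_nlm under q^2 dq dOmega: product
        Gauss-Legendre (radius, polar) x trapezoid (azimuth) quadrature."""
        idx = shore_index_set(4)
        rn, rw = np.polynomial.legendre.leggauss(120)
        qmax = 8 * np.sqrt(ZETA)
        q = 0.5 * qmax * (rn + 1.0)
        qw = 0.5 * qmax * rw * q * q
        cn, cw = np.polynomial.legendre.leggauss(40)
        phi = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        pw = 2 * np.pi / 80
        theta = np.arccos(cn)
        pts, wts = [], []
        for qi, qwi in zip(q, qw):
            for ti, twi in zip(theta, cw):
                for pj in phi:
                    u = np.array([np.sin(ti) * np.cos(pj),
                                  np.sin(ti) * np.sin(pj), np.cos(ti)])
                    pts.append(qi * u)
                    wts.append(qwi * twi * pw)
        basis = build_basis(idx, np.array(pts), ZETA)
        M = basis.design_matrix
        gram = (M * np.array(wts)[:, None]).T @ M
        assert np.max(np.abs(gram - np.eye(len(idx)))) < 1e-3

    def test_invalid_zeta_rejected(self, dense_q_points):
        with pytest.raises(ValueError):
            build_basis(shore_index_set(2), dense_q_points, 0.0)


class TestRegularization:
    def test_diagonal_values(self):
        idx = shore_index_set(6)
        reg = regularization_operators(idx, 1.0, 1.0)
        lookup = dict(zip(idx, zip(reg.L_diag, reg.N_diag)))
        assert lookup[(0, 0, 0)] == (0.0, 0.0)
        assert lookup[(2, 2, 1)] == (6.0, 6.0)
        assert lookup[(6, 6, -3)] == (42.0, 42.0)
        assert lookup[(6, 0, 0)] == (0.0, 42.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            regularization_operators(shore_index_set(2), -1.0, 0.0)

    def test_increasing_lambda_l_never_increases_Lc_norm(self, basis6):
        rng = np.random.default_rng(8)
        signal = basis6.design_matrix @ rng.standard_normal(72)
        prev = np.inf
        for lam in (0.0, 1e-8, 1e-4, 1e-2, 1.0):
            reg = regularization_operators(basis6.index_set, lam, 1e-8)
            c = fit_shore(signal, basis6, reg=reg)
            norm = np.linalg.norm(reg.L_diag * c.values)
            assert norm <= prev + 1e-9
            prev = norm


class TestFitPredict:
    def test_noiseless_recovery_unregularized(self, basis6):
        rng = np.random.default_rng(0)
        c_true = rng.standard_normal(72)
        signal = basis6.design_matrix @ c_true
        c = fit_shore(signal, basis6)
        assert (np.linalg.norm(c.values - c_true)
                / np.linalg.norm(c_true)) < 1e-8

    def test_zero_signal_zero_coefficients(self, basis6):
        c = fit_shore(np.zeros(basis6.design_matrix.shape[0]), basis6)
        np.testing.assert_array_equal(c.values, 0.0)

    def test_zero_weight_equals_clean_subset_refit(self, basis6):
        """Zeroing the weights of corrupted rows reproduces the fit on
        the clean rows alone."""
        rng = np.random.default_rng(1)
        Q = basis6.design_matrix.shape[0]
        c_true = rng.standard_normal(72)
        signal = basis6.design_matrix @ c_true
        bad = rng.choice(Q, size=40, replace=False)
        corrupted = signal.copy()
        corrupted[bad] += rng.uniform(50, 100, size=40)
        w = np.ones(Q)
        w[bad] = 0.0
        c_weighted = fit_shore(corrupted, basis6, w)
        keep = np.setdiff1d(np.arange(Q), bad)
        sub = dm.ShoreBasis(6, ZETA, basis6.index_set,
                            basis6.design_matrix[keep])
        c_clean = fit_shore(signal[keep], sub)
        np.testing.assert_allclose(c_weighted.values, c_clean.values,
                                   atol=1e-10)

    def test_fit_predict_round_trip(self, basis6, dense_q_points):
        rng = np.random.default_rng(2)
        c_true = rng.standard_normal(72)
        signal = basis6.design_matrix @ c_true
        c = fit_shore(signal, basis6)
        pred = predict_signal(c, dense_q_points)
        np.testing.assert_allclose(pred, signal, atol=1e-8 * np.abs(
            signal).max())

    def test_zero_coefficients_zero_prediction(self, basis6,
                                               dense_q_points):
        c = ShoreCoefficients(np.zeros(72), basis6)
        np.testing.assert_array_equal(
            predict_signal(c, dense_q_points), 0.0)

    def test_rank_deficiency_without_regularization_raises(self):
        # two shells only: radial rank < 72 at order 6
        rng = np.random.default_rng(3)
        dirs = rng.standard_normal((30, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        q = np.concatenate([np.sqrt(400) * dirs, np.sqrt(900) * dirs])
        basis = build_basis(shore_index_set(6), q, ZETA)
        signal = rng.uniform(0, 1, q.shape[0])
        with pytest.raises(np.linalg.LinAlgError, match="regulariz"):
            fit_shore(signal, basis)

    def test_rotation_equivariance_l0_invariant(self, dense_q_points):
        """Fitting a rotated acquisition with the correspondingly rotated
        gradient table leaves the isotropic (l=0) coefficients unchanged."""
        from scipy.spatial.transform import Rotation

        idx = shore_index_set(4)
        rng = np.random.default_rng(4)
        c_true = rng.standard_normal(len(idx))
        basis = build_basis(idx, dense_q_points, ZETA)
        signal = basis.design_matrix @ c_true
        R = Rotation.from_euler("ZYX", [40, -25, 65],
                                degrees=True).as_matrix()
        basis_rot = build_basis(idx, dense_q_points @ R.T, ZETA)
        # same physical signal samples, rotated coordinates
        c_rot = fit_shore(signal, basis_rot)
        l0 = np.array([l == 0 for (_, l, _) in idx])
        np.testing.assert_allclose(c_rot.values[l0], c_true[l0],
                                   atol=1e-6)

    def test_per_voxel_weights_match_loop(self, basis6):
        """The batched per-voxel weighted path equals voxel-by-voxel
        fits."""
        rng = np.random.default_rng(5)
        Q = basis6.design_matrix.shape[0]
        E = rng.uniform(0, 1, (4, Q))
        W = rng.uniform(0.1, 1, (4, Q))
        reg = regularization_operators(basis6.index_set, 1e-8, 1e-8)
        batched = fit_shore(E, basis6, W, reg)
        for v in range(4):
            single = fit_shore(E[v], basis6, W[v], reg)
            np.testing.assert_allclose(batched.values[v], single.values,
                                       rtol=1e-8, atol=1e-10)
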