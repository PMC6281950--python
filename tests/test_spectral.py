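"""SVD/GSVD bundles and spectral curves against dense linear-algebra oracles."""

import numpy as np
import pytest

from ecgikit.spectral import (
    compute_gsvd,
    compute_svd,
    filter_trace,
    influence_trace,
    lambda_grid,
    residual_curve,
    seminorm_curve,
)


def dense_tikhonov(A, L, b, lam):
    n = A.shape[1]
    return np.linalg.solve(A.T @ A + lam**2 * (L.T @ L), A.T @ b)


class TestSvdBundle:
    def test_identity_matrix(self):
        b = np.arange(5.0)
        bu = compute_svd(np.eye(5), b)
        np.testing.assert_allclose(bu.sigma, 1.0)
        # mu carries b's coefficients in some orthonormal basis of directions
        np.testing.assert_allclose(
            np.sort(np.abs(bu.mu[:, 0])), np.sort(np.abs(b)), atol=1e-12
        )
        np.testing.assert_allclose(bu.U @ bu.mu[:, 0], b, atol=1e-12)

    def test_diagonal_singular_values_sorted(self):
        bu = compute_svd(np.diag([1.0, 3.0, 2.0]), np.ones(3))
        np.testing.assert_allclose(bu.sigma, [3, 2, 1])

    def test_reconstruction_and_orthogonality(self, rng):
        A = rng.normal(size=(20, 10))
        bu = compute_svd(A, rng.normal(size=20))
        rel = np.linalg.norm(A - bu.U @ np.diag(bu.sigma) @ bu.V.T) / np.linalg.norm(A)
        assert rel <= 1e-10
        assert np.linalg.norm(bu.U.T @ bu.U - np.eye(10)) <= 1e-10
        assert np.linalg.norm(bu.V.T @ bu.V - np.eye(10)) <= 1e-10

    def test_residual_floor_is_lss_residual(self, rng):
        A = rng.normal(size=(12, 5))
        b = rng.normal(size=12)
        bu = compute_svd(A, b)
        x_lss, *_ = np.linalg.lstsq(A, b, rcond=None)
        assert bu.rperp2[0] == pytest.approx(np.sum((A @ x_lss - b) ** 2), rel=1e-9)

    def test_shape_and_finiteness_guards(self, rng):
        with pytest.raises(ValueError, match="m >= n"):
            compute_svd(rng.normal(size=(3, 5)), np.ones(3))
        A = np.ones((4, 2))
        A[0, 0] = np.inf
        with pytest.raises(ValueError):
            compute_svd(A, np.ones(4))


class TestGsvdBundle:
    def check_contract(self, A, L, b):
        g = compute_gsvd(A, L, b)
        n = A.shape[1]
        Zinv = np.linalg.inv(g.Z)
        assert np.linalg.norm(A - g.P @ np.diag(g.sigma) @ Zinv) / np.linalg.norm(A) <= 1e-8
        assert np.linalg.norm(L - g.Q @ np.diag(g.nu) @ Zinv) / (np.linalg.norm(L) + 1e-30) <= 1e-8
        assert np.linalg.norm(g.sigma**2 + g.nu**2 - 1.0) <= 1e-8
        assert np.all(np.diff(g.gsv[g.finite]) >= -1e-12)  # nondecreasing
        return g

    def test_random_pairs_reconstruct(self, rng):
        for _ in range(5):
            A = rng.normal(size=(15, 8))
            L = rng.normal(size=(8, 8))
            self.check_contract(A, L, rng.normal(size=15))

    def test_identity_L_matches_svd(self, rng):
        A = rng.normal(size=(12, 6))
        b = rng.normal(size=12)
        g = compute_gsvd(A, np.eye(6), b)
        bu = compute_svd(A, b)
        np.testing.assert_allclose(np.sort(g.gsv), np.sort(bu.sigma), rtol=1e-8)

    def test_identity_pair_symmetric(self):
        g = compute_gsvd(np.eye(4), np.eye(4), np.ones(4))
        np.testing.assert_allclose(g.sigma, 1 / np.sqrt(2), rtol=1e-12)
        np.testing.assert_allclose(g.nu, 1 / np.sqrt(2), rtol=1e-12)
        np.testing.assert_allclose(g.gsv, 1.0, rtol=1e-12)

    def test_singular_L_gives_infinite_gsv(self, rng):
        """A rank-deficient L (constant null vector, as for the
        Dirichlet-to-Neumann operator) yields an infinite generalized
        singular value with filter factor 1."""
        A = rng.normal(size=(10, 5))
        L = np.diag([1.0, 1.0, 1.0, 1.0, 0.0])
        g = compute_gsvd(A, L, rng.normal(size=10))
        assert np.sum(~g.finite) == 1
        assert g.filters(0.7)[~g.finite] == pytest.approx(1.0)

    def test_rank_deficient_stack_rejected(self):
        A = np.zeros((6, 3))
        L = np.zeros((3, 3))
        with pytest.raises(ValueError, match="rank"):
            compute_gsvd(A, L, np.ones(6))

    def test_out_of_range_term(self, rng):
        A = rng.normal(size=(9, 4))
        L = rng.normal(size=(4, 4))
        b = rng.normal(size=9)
        g = compute_gsvd(A, L, b)
        assert g.extra2[0] == pytest.approx(
            np.sum(b**2) - np.sum((g.P.T @ b) ** 2), rel=1e-9, abs=1e-9
        )


class TestCurves:
    @pytest.mark.parametrize("lam", [0.03, 0.3, 3.0])
    def test_rho_eta_match_dense_solve_svd(self, rng, lam):
        A = rng.normal(size=(12, 7))
        b = rng.normal(size=12)
        bu = compute_svd(A, b)
        x = dense_tikhonov(A, np.eye(7), b, lam)
        assert residual_curve(bu, lam) == pytest.approx(np.sum((A @ x - b) ** 2), rel=1e-9)
        assert seminorm_curve(bu, lam) == pytest.approx(np.sum(x**2), rel=1e-9)

    @pytest.mark.parametrize("lam", [0.05, 0.5])
    def test_rho_eta_match_dense_solve_gsvd(self, rng, lam):
        A = rng.normal(size=(13, 6))
        L = rng.normal(size=(6, 6))
        b = rng.normal(size=13)
        g = compute_gsvd(A, L, b)
        x = dense_tikhonov(A, L, b, lam)
        assert residual_curve(g, lam) == pytest.approx(np.sum((A @ x - b) ** 2), rel=1e-8)
        assert seminorm_curve(g, lam) == pytest.approx(np.sum((L @ x) ** 2), rel=1e-8)

    def test_unregularized_limit_square_full_rank(self, rng):
        A = rng.normal(size=(6, 6))
        b = rng.normal(size=6)
        bu = compute_svd(A, b)
        assert residual_curve(bu, 0.0) == pytest.approx(0.0, abs=1e-16)
        assert seminorm_curve(bu, 0.0) == pytest.approx(
            np.sum(np.linalg.solve(A, b) ** 2), rel=1e-8
        )

    def test_infinite_lambda_limits(self, rng):
        A = rng.normal(size=(10, 4))
        b = rng.normal(size=10)
        bu = compute_svd(A, b)
        big = 1e9
        assert seminorm_curve(bu, big) <= 1e-12
        assert residual_curve(bu, big) == pytest.approx(np.sum(b**2), rel=1e-6)

    def test_influence_trace_dense_oracle(self, rng):
        A = rng.normal(size=(11, 6))
        bu = compute_svd(A, np.ones(11))
        lam = 0.4
        infl = A @ np.linalg.solve(A.T @ A + lam**2 * np.eye(6), A.T)
        assert influence_trace(bu, lam) == pytest.approx(np.trace(infl @ infl), rel=1e-9)
        assert filter_trace(bu, lam) == pytest.approx(np.trace(infl), rel=1e-9)

    def test_influence_trace_range(self, rng):
        A = rng.normal(size=(9, 5))
        bu = compute_svd(A, np.ones(9))
        assert influence_trace(bu, 0.0) == pytest.approx(5.0)  # xi(0) = n
        assert influence_trace(bu, 1e12) <= 1e-12

    def test_monotonicity_on_grid(self, rng):
        """rho nondecreasing, eta nonincreasing in lambda."""
        for _ in range(3):
            A = rng.normal(size=(14, 9))
            b = rng.normal(size=14)
            bu = compute_svd(A, b)
            grid = lambda_grid(bu, 200)
            rho = residual_curve(bu, grid)
            eta = seminorm_curve(bu, grid)
            assert np.all(np.diff(rho) >= -1e-10 * rho.max())
            assert np.all(np.diff(eta) <= 1e-10 * eta.max())

    def test_lambda_grid_bounds(self, rng):
        A = rng.normal(size=(8, 5))
        bu = compute_svd(A, np.ones(8))
        grid = lambda_grid(bu, 300)
        assert len(grid) == 300
        assert grid[0] == pytest.approx(1e-8 * bu.sigma[0])
        assert grid[-1] == pytest.approx(10 * bu.sigma[0])
        assert np.all(np.diff(np.log(grid)) > 0)
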