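"""Forward models against the analytic annulus oracle."""

import numpy as np
import pytest

from ecgikit.forward_models import (
    TransferSystem,
    analytic_annulus_forward,
    annulus_oracle_matrix,
    build_dtn_operator,
    build_fem_transfer,
    build_mfs_forward,
    build_mfs_transfer,
    choose_mfs_sources,
    mfs_reconstruct_epicardial,
    real_spherical_harmonics,
)
from ecgikit.geometry import icosphere


def harmonic_re(A, heart, torso, l, a, b):
    """RE of a forward map against the analytic annulus solution for Y_l0."""
    Yh, _ = real_spherical_harmonics(heart.vertices, l)
    Yt, _ = real_spherical_harmonics(torso.vertices, l)
    col = l * l + l
    truth = analytic_annulus_forward(l, a, b).radial(b) * Yt[:, col]
    pred = A @ Yh[:, col]
    return np.linalg.norm(pred - truth) / np.linalg.norm(truth)


class TestAnalyticAnnulus:
    def test_degree_zero_is_constant(self):
        h = analytic_annulus_forward(0, 1.0, 2.0)
        assert h.radial([1.0, 1.5, 2.0]) == pytest.approx([1, 1, 1])
        assert h.radial_derivative(1.7) == 0.0

    @pytest.mark.parametrize("l", [1, 2, 3, 5])
    def test_boundary_conditions(self, l):
        h = analytic_annulus_forward(l, 1.0, 2.0)
        assert h.radial(1.0) == pytest.approx(1.0)
        assert h.radial_derivative(2.0) == pytest.approx(0.0, abs=1e-12)

    def test_degree_one_attenuation_matches_direct_solve(self):
        """Frozen oracle: solve the 2x2 coefficient system independently."""
        a, b, l = 1.0, 2.0, 1
        M = np.array([[a, a**-2], [1.0, -2.0 * b**-3]])
        A1, B1 = np.linalg.solve(M, [1.0, 0.0])
        h = analytic_annulus_forward(l, a, b)
        assert (h.A_l, h.B_l) == pytest.approx((A1, B1))
        assert h.radial(b) == pytest.approx(A1 * b + B1 / b**2)

    def test_invalid_radii(self):
        with pytest.raises(ValueError):
            analytic_annulus_forward(1, 2.0, 1.0)


class TestFemTransfer:
    def test_constant_propagates_unchanged(self, fem_system, heart):
        out = fem_system.A @ np.full(heart.n_vertices, 3.0)
        assert np.abs(out - 3.0).max() <= 1e-6 * 3.0

    def test_degree_one_harmonic_within_two_percent(self, fem_system, heart, torso):
        re = harmonic_re(fem_system.A, heart, torso, 1, 50.0, 70.0)
        assert re <= 0.02

    def test_error_decreases_with_refinement(self):
        h, t = icosphere(1.0, 2), icosphere(1.5, 2)
        res = [
            harmonic_re(build_fem_transfer(h, t, refinement=r).A, h, t, 2, 1.0, 1.5)
            for r in (2, 8)
        ]
        assert res[1] < res[0]

    def test_heart_outside_torso_rejected(self):
        h, t = icosphere(2.0, 1), icosphere(1.0, 1)
        with pytest.raises(ValueError, match="inside"):
            build_fem_transfer(h, t, refinement=2)

    def test_full_column_rank(self, fem_system):
        s = np.linalg.svd(fem_system.A, compute_uv=False)
        assert s[-1] > 0


class TestDtnOperator:
    def test_constant_maps_to_zero(self, dtn, heart):
        out = dtn.D @ np.ones(heart.n_vertices)
        assert np.abs(out).max() <= 1e-8 * np.abs(dtn.D).max()

    @pytest.mark.parametrize("l,tol", [(1, 0.05), (2, 0.05), (3, 0.10)])
    def test_harmonic_normal_derivative(self, dtn, heart, l, tol):
        """D approximates the analytic radial derivative at r = a.

        The tolerance loosens with degree: at the 162-vertex surface
        resolution the flux recovery error grows roughly with l^2."""
        Yh, _ = real_spherical_harmonics(heart.vertices, l)
        col = l * l + l
        truth = analytic_annulus_forward(l, 50.0, 70.0).radial_derivative(50.0) * Yh[:, col]
        pred = dtn.D @ Yh[:, col]
        assert np.linalg.norm(pred - truth) / np.linalg.norm(truth) <= tol

    def test_refinement_convergence(self):
        """Joint radial + angular refinement reduces the flux error."""
        h, t = icosphere(1.0, 2), icosphere(1.5, 2)
        Yh, _ = real_spherical_harmonics(h.vertices, 2)
        truth = analytic_annulus_forward(2, 1.0, 1.5).radial_derivative(1.0) * Yh[:, 6]
        errs = []
        for r, ar in ((2, 0), (8, 1)):
            D = build_dtn_operator(h, t, refinement=r, angular_refine=ar).D
            errs.append(np.linalg.norm(D @ Yh[:, 6] - truth) / np.linalg.norm(truth))
        assert errs[1] < errs[0]


class TestMfs:
    def test_single_source_kernel_value(self):
        """One electrode at distance r from one source: potential 1/(4 pi r)."""
        h, t = icosphere(1.0, 0), icosphere(2.0, 1)
        sys_ = build_mfs_transfer(h, t)
        j = 3  # any source
        r = np.linalg.norm(t.vertices[0] - sys_.sources[j])
        coeff = np.zeros(sys_.n_unknowns)
        coeff[1 + j] = 1.0
        pred = sys_.A[0] @ coeff
        assert pred == pytest.approx(1.0 / (4 * np.pi * r))

    def test_rhs_structure(self, mfs_system, torso):
        b = mfs_system.stack_rhs(np.ones(mfs_system.n_dirichlet))
        assert len(b) == mfs_system.m_total
        assert np.all(b[mfs_system.n_dirichlet :] == 0.0)

    def test_sources_on_surface_rejected(self):
        h, t = icosphere(1.0, 1), icosphere(2.0, 1)
        with pytest.raises(ValueError):
            build_mfs_transfer(h, t, inflation=1.0001, deflation=0.8)

    def test_underdetermined_rejected_and_thinning_restores(self):
        h, t = icosphere(1.0, 1), icosphere(1.5, 1)
        with pytest.raises(ValueError, match="underdetermined"):
            build_mfs_transfer(h, t)  # 84 rows < 85 unknowns
        idx = choose_mfs_sources(h, t, 2 * t.n_vertices)
        sys_ = build_mfs_transfer(h, t, heart_source_idx=idx)
        assert sys_.m_total >= sys_.n_unknowns

    def test_reconstruct_trivial_coefficients(self, mfs_system, heart):
        ns = len(mfs_system.sources)
        zero = mfs_reconstruct_epicardial(mfs_system, np.zeros(ns + 1))
        assert np.all(zero == 0)
        const = np.zeros(ns + 1)
        const[0] = 2.5
        np.testing.assert_allclose(mfs_reconstruct_epicardial(mfs_system, const), 2.5)
        one = np.zeros(ns + 1)
        one[5] = 1.0
        r = np.linalg.norm(heart.vertices - mfs_system.sources[4], axis=1)
        np.testing.assert_allclose(
            mfs_reconstruct_epicardial(mfs_system, one), 1 / (4 * np.pi * r)
        )

    def test_coefficient_length_checked(self, mfs_system):
        with pytest.raises(ValueError, match="coefficients"):
            mfs_reconstruct_epicardial(mfs_system, np.zeros(3))

    @pytest.mark.parametrize("l", [1, 2, 3, 4])
    def test_forward_solve_within_one_percent(self, l):
        h, t = icosphere(50.0, 2), icosphere(70.0, 2)
        Af, _ = build_mfs_forward(h, t, inflation=1.5, deflation=0.6)
        assert harmonic_re(Af, h, t, l, 50.0, 70.0) <= 0.01


class TestTransferSystemContract:
    def test_m_ge_n_enforced(self):
        with pytest.raises(ValueError, match="underdetermined"):
            TransferSystem(
                A=np.ones((2, 3)), method="FEM", heart_vertices=np.zeros((3, 3)), n_dirichlet=2
            )

    def test_nonfinite_rejected(self):
        A = np.ones((3, 2))
        A[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            TransferSystem(A=A, method="FEM", heart_vertices=np.zeros((2, 3)), n_dirichlet=3)


class TestOracleMatrix:
    def test_constant_gain_is_unity(self, heart, torso):
        Ao = annulus_oracle_matrix(heart, torso)
        out = Ao @ np.ones(heart.n_vertices)
        np.testing.assert_allclose(out, 1.0, atol=1e-9)

    def test_matches_per_degree_attenuation(self, heart, torso):
        Ao = annulus_oracle_matrix(heart, torso, l_max=6)
        for l in (1, 3):
            assert harmonic_re(Ao, heart, torso, l, 50.0, 70.0) <= 1e-8
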