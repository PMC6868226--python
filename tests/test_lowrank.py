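"""Low-rank + sparse decomposition: proximal operators and ALM solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from seedgrader import lowrank


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x, tau, want",
        [(1.5, 1.0, 0.5), (-0.3, 1.0, 0.0), (-2.0, 0.5, -1.5), (0.7, 0.0, 0.7)],
    )
    def test_scalar_cases(self, x, tau, want):
        assert lowrank.soft_threshold(np.array([x]), tau)[0] == pytest.approx(want)

    def test_zero_tau_is_identity(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((6, 4))
        np.testing.assert_array_equal(lowrank.soft_threshold(M, 0.0), M)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            lowrank.soft_threshold(np.ones(3), -0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(np.float64, (4, 3), elements=st.floats(-50, 50)),
        st.floats(0, 10),
    )
    def test_shrinkage_contract_property(self, M, tau):
        out = lowrank.soft_threshold(M, tau)
        # never increases magnitude, shrinks by exactly tau when nonzero,
        # and preserves sign
        assert np.all(np.abs(out) <= np.abs(M) + 1e-12)
        nz = out != 0
        np.testing.assert_allclose(
            np.abs(out[nz]), np.abs(M[nz]) - tau, atol=1e-12
        )
        assert np.all(out * M >= 0)


class TestSingularValueThreshold:
    def test_diagonal_closed_form(self):
        M = np.diag([3.0, 1.0, 0.2])
        out = lowrank.singular_value_threshold(M, 0.5)
        np.testing.assert_allclose(np.diag(out), [2.5, 0.5, 0.0], atol=1e-12)

    def test_large_tau_gives_zero(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((5, 5))
        tau = np.linalg.norm(M, 2) + 1e-9
        np.testing.assert_allclose(
            lowrank.singular_value_threshold(M, tau), 0.0, atol=1e-12
        )

    def test_matches_explicit_svd_oracle(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((10, 7))
        u, s, vt = np.linalg.svd(M, full_matrices=False)
        want = u @ np.diag(np.maximum(s - 0.8, 0)) @ vt
        np.testing.assert_allclose(
            lowrank.singular_value_threshold(M, 0.8), want, atol=1e-9
        )

    def test_nonfinite_rejected(self):
        M = np.ones((3, 3))
        M[0, 0] = np.nan
        with pytest.raises(ValueError):
            lowrank.singular_value_threshold(M, 0.1)


def _planted(seed, d=200, r=5, frac=0.05):
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((d, r)) @ rng.standard_normal((d, r)).T
    S = np.zeros((d, d))
    mask = rng.random((d, d)) < frac
    S[mask] = rng.choice([-1.0, 1.0], mask.sum())
    return L, S


class TestRpcaDecompose:
    def test_zero_matrix_trivial(self):
        dec = lowrank.rpca_decompose(np.zeros((4, 6)))
        assert dec.iterations == 1
        assert dec.residual == 0.0
        np.testing.assert_array_equal(dec.X, 0.0)
        np.testing.assert_array_equal(dec.E, 0.0)

    def test_converged_run_meets_residual_contract(self):
        rng = np.random.default_rng(3)
        dec = lowrank.rpca_decompose(rng.standard_normal((30, 20)))
        assert dec.converged
        assert dec.residual <= 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_recovery(self, seed):
        """Rank-5 + 5%-sparse 200x200 recovery at lambda = 1/sqrt(200)."""
        L, S = _planted(seed)
        dec = lowrank.rpca_decompose(L + S, lam=1.0 / np.sqrt(200))
        relerr = np.linalg.norm(dec.X - L) / np.linalg.norm(L)
        assert relerr < 1e-3
        model = lowrank.fit_lowrank_basis(dec.X, energy=0.99)
        assert model.rank == 5

    def test_converged_objective_beats_feasible_references(self):
        # the solution must beat the trivial feasible points (Y, 0), (0, Y)
        # and, on a planted instance, the planted pair itself
        L, S = _planted(4, d=80)
        Y = L + S
        lam = 1.0 / np.sqrt(80)
        dec = lowrank.rpca_decompose(Y, lam=lam)
        obj = lowrank.nuclear_l1_objective(dec.X, dec.E, lam)
        slack = 1e-5 * obj  # convergence is on the residual, not the objective
        assert obj <= lowrank.nuclear_l1_objective(Y, np.zeros_like(Y), lam) + slack
        assert obj <= lowrank.nuclear_l1_objective(np.zeros_like(Y), Y, lam) + slack
        assert obj <= lowrank.nuclear_l1_objective(L, S, lam) + slack

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((25, 18))
        lam = 1.0 / np.sqrt(25)
        d1 = lowrank.rpca_decompose(Y, lam=lam)
        d2 = lowrank.rpca_decompose(3.0 * Y, lam=lam)
        np.testing.assert_allclose(d2.X, 3.0 * d1.X, atol=1e-6)
        np.testing.assert_allclose(d2.E, 3.0 * d1.E, atol=1e-6)

    def test_nonconvergence_flagged(self):
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((15, 15))
        with pytest.warns(UserWarning):
            dec = lowrank.rpca_decompose(Y, max_iter=2)
        assert not dec.converged

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lowrank.rpca_decompose(np.ones((3, 3)), lam=-1.0)
        with pytest.raises(ValueError):
            lowrank.rpca_decompose(np.full((3, 3), np.inf))


class TestLowRankBasis:
    def test_known_planted_rank(self):
        L, S = _planted(7)
        dec = lowrank.rpca_decompose(L + S, lam=1.0 / np.sqrt(200))
        model = lowrank.fit_lowrank_basis(dec.X, energy=0.99)
        assert model.rank == 5
        eye = model.basis.T @ model.basis
        np.testing.assert_allclose(eye, np.eye(5), atol=1e-9)

    def test_full_energy_gives_numerical_rank(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 3)) @ rng.standard_normal((3, 15))
        model = lowrank.fit_lowrank_basis(X, energy=1.0)
        assert model.rank == 3

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            lowrank.fit_lowrank_basis(np.zeros((5, 5)))

    def test_projection_round_trip_error_bounded(self):
        L, S = _planted(9, d=60, r=4)
        model = lowrank.fit_lowrank_basis(L, energy=0.99)
        Z = lowrank.project_descriptors(model, L)
        recon = model.basis @ Z
        rel = np.linalg.norm(recon - L) / np.linalg.norm(L)
        assert rel <= np.sqrt(1 - 0.99) + 1e-6

    def test_projection_shapes_and_zero(self):
        L, _ = _planted(10, d=30, r=2)
        model = lowrank.fit_lowrank_basis(L, energy=0.99)
        Z = lowrank.project_descriptors(model, np.zeros((30, 4)))
        assert Z.shape == (model.rank, 4)
        np.testing.assert_array_equal(Z, 0.0)
        with pytest.raises(ValueError):
            lowrank.project_descriptors(model, np.zeros((31, 4)))
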