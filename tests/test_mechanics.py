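"""Lagrangian/Hamiltonian identities, action stationarity, Euler-Lagrange
recovery, and the real-variable non-uniqueness demonstration."""

import numpy as np
import pytest

import neulag as nl
from neulag.errors import ShapeError, ValidationError


def random_hermitian(n, rng):
    M = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    return 0.5 * (M + M.conj().T)


class TestLagrangianValue:
    def test_zero_phase_point_gives_zero(self, three_node_modified):
        L = nl.lagrangian_value(
            np.zeros(3), np.zeros(3), three_node_modified, [0.0], np.zeros(3)
        )
        assert L == 0

    def test_onshell_lagrangian_vanishes_pointwise(self):
        """Substituting zdot = -iAz (non-dissipative solution) cancels the
        kinetic term against the potential exactly, for any Hermitian A."""
        rng = np.random.default_rng(3)
        A = random_hermitian(3, rng)
        spec = nl.LinearModelSpec(
            A=A, C=np.zeros((3, 1)), variant="modified",
            symmetric_real=False, non_dissipative=True,
        )
        for _ in range(5):
            z = rng.standard_normal(3) + 1j * rng.standard_normal(3)
            zdot = -1j * (A @ z)
            L = nl.lagrangian_value(z, zdot, spec, [0.0], np.zeros(3))
            assert abs(L) < 1e-12

    def test_real_for_hermitian_A_real_inputs(self):
        rng = np.random.default_rng(4)
        A = random_hermitian(3, rng)
        spec = nl.LinearModelSpec(
            A=A, C=rng.standard_normal((3, 2)), variant="modified",
            symmetric_real=False,
        )
        z = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        zdot = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        L = nl.lagrangian_value(z, zdot, spec, rng.standard_normal(2), rng.standard_normal(3))
        assert abs(L.imag) < 1e-12

    def test_shape_mismatch_raises(self, three_node_modified):
        with pytest.raises(ShapeError):
            nl.lagrangian_value(np.zeros(2), np.zeros(2), three_node_modified,
                                [0.0], np.zeros(3))


class TestHamiltonianValue:
    def test_zero_state_zero_energy(self, three_node_modified):
        assert nl.hamiltonian_value(np.zeros(3), three_node_modified) == 0.0

    def test_direct_quadratic_form(self):
        spec = nl.LinearModelSpec(
            A=np.diag([2.0, 3.0]), C=np.zeros((2, 1)), variant="modified",
            non_dissipative=True,
        )
        assert nl.hamiltonian_value([1.0, 0.0], spec) == pytest.approx(2.0)

    def test_legendre_transform_consistency(self):
        """H recomputed as sum_k (dL/dzdot_k) zdot_k + (dL/dzdot*_k) zdot*_k - L
        (with dL/dzdot = (i/2) z*, dL/dzdot* = -(i/2) z) agrees with the
        direct formula on random inputs."""
        rng = np.random.default_rng(11)
        A = random_hermitian(3, rng)
        C = rng.standard_normal((3, 2))
        spec = nl.LinearModelSpec(A=A, C=C, variant="modified", symmetric_real=False)
        for _ in range(5):
            z = rng.standard_normal(3) + 1j * rng.standard_normal(3)
            zdot = rng.standard_normal(3) + 1j * rng.standard_normal(3)
            v = rng.standard_normal(2)
            w = rng.standard_normal(3)
            L = nl.lagrangian_value(z, zdot, spec, v, w)
            legendre = np.sum((0.5j * z.conj()) * zdot + (-0.5j * z) * zdot.conj())
            H_indirect = (legendre - L).real
            H_direct = nl.hamiltonian_value(z, spec, v, w)
            assert abs(H_indirect - H_direct) < 1e-10

    def test_non_hermitian_rejected(self):
        spec = nl.LinearModelSpec(A=[[0.0, 1.0], [0.0, 0.0]], C=np.zeros((2, 1)))
        with pytest.raises(ValidationError):
            nl.hamiltonian_value([1.0, 0.0], spec)


class TestHamiltonianDrift:
    def test_constant_state_zero_drift(self):
        spec = nl.LinearModelSpec(A=np.zeros((2, 2)), C=np.zeros((2, 1)),
                                  variant="modified", non_dissipative=True)
        traj = nl.simulate_modified(spec, [1.0, 2.0], None, nl.NoiseSpec(), T=64, dt=0.1)
        assert nl.hamiltonian_drift(traj, spec) == 0.0

    def test_non_dissipative_modified_conserves_energy(self, three_node_modified):
        spec = three_node_modified.with_(non_dissipative=True)
        traj = nl.simulate_modified(
            spec, np.array([1.0, 0.5j, -0.2]), None, nl.NoiseSpec(), T=129, dt=0.05
        )
        assert nl.hamiltonian_drift(traj, spec) < 1e-6

    def test_original_equation_violates_conservation(self):
        """For dz/dt = z the energy z*Az = e^{2t} grows; conservation is a
        property of the modified equation only."""
        spec = nl.LinearModelSpec(A=[[1.0]], C=[[0.0]])
        traj = nl.simulate_original(spec, [1.0], None, nl.NoiseSpec(), T=101, dt=0.01)
        drift = nl.hamiltonian_drift(traj, spec)
        assert drift > 1.0
        assert drift == pytest.approx(np.exp(2.0) - 1.0, rel=1e-6)


class TestActionAndStationarity:
    def test_zero_trajectory_zero_action(self, three_node_modified):
        traj = nl.Trajectory(np.arange(8.0), np.zeros((8, 3), complex), np.zeros((8, 3)))
        assert nl.action_value(traj, three_node_modified) == 0.0

    def test_too_short_grid_rejected(self, three_node_modified):
        traj = nl.Trajectory(np.arange(2.0), np.zeros((2, 3), complex), np.zeros((2, 3)))
        with pytest.raises(ValidationError):
            nl.action_value(traj, three_node_modified)

    def test_onshell_action_near_zero(self, onshell_fine):
        traj, spec = onshell_fine
        assert abs(nl.action_value(traj, spec)) < 1e-5

    def test_onshell_first_order_variation_vanishes(self, onshell_fine):
        traj, spec = onshell_fine
        first, second = nl.action_stationarity_check(
            traj, spec, perturbation_scale=1e-3, seed=0
        )
        assert first < 1e-8
        assert second > 0

    def test_offshell_trajectory_is_not_stationary(self, onshell_fine):
        _, spec = onshell_fine
        orig = nl.make_three_node_network()
        bump = nl.gaussian_bump(1025, dt=0.002)
        tr = nl.simulate_original(orig, np.array([1.0, 0.5, -0.2], dtype=complex),
                                  bump, nl.NoiseSpec(), T=1025, dt=0.002)
        off = nl.Trajectory(tr.times, tr.states, tr.observations)
        first, _ = nl.action_stationarity_check(off, spec, perturbation_scale=1e-3, seed=0)
        assert first > 1e-4

    def test_zero_perturbation_gives_zero(self, onshell_fine):
        traj, spec = onshell_fine
        eta = np.zeros_like(traj.states)
        first, second = nl.action_stationarity_check(
            traj, spec, perturbation_scale=1e-3, perturbations=eta
        )
        assert first == 0.0 and second == 0.0

    def test_stationarity_separation_ratio(self):
        """On-shell first/second-order ratio is tiny; off-shell it is large."""
        spec = nl.make_three_node_network(variant="modified").with_(non_dissipative=True)
        z0 = np.array([1.0, 0.5j, -0.2])
        traj = nl.simulate_modified(spec, z0, None, nl.NoiseSpec(), T=2049, dt=0.001)
        first, second = nl.action_stationarity_check(traj, spec, perturbation_scale=1e-3, seed=0)
        assert first / second < 1e-4
        orig = nl.make_three_node_network()
        tr = nl.simulate_original(orig, np.array([1.0, 0.5, -0.2], dtype=complex),
                                  None, nl.NoiseSpec(), T=2049, dt=0.001)
        off = nl.Trajectory(tr.times, tr.states, tr.observations)
        f_off, s_off = nl.action_stationarity_check(off, spec, perturbation_scale=1e-3, seed=0)
        assert f_off / s_off > 1e-1

    def test_invalid_scale_rejected(self, onshell_fine):
        traj, spec = onshell_fine
        with pytest.raises(ValidationError):
            nl.action_stationarity_check(traj, spec, perturbation_scale=0.0)


class TestEulerLagrange:
    def test_exact_solution_has_small_residual(self, onshell_fine):
        traj, spec = onshell_fine
        r = nl.euler_lagrange_residual(traj, spec)
        assert np.max(np.abs(r)) < 1e-5

    def test_adjoint_is_conjugate_for_hermitian_A(self, onshell_fine):
        traj, spec = onshell_fine
        assert nl.adjoint_conjugacy_deviation(traj, spec) < 1e-12

    def test_zero_trajectory_zero_residual(self, three_node_modified):
        traj = nl.Trajectory(np.arange(8.0), np.zeros((8, 3), complex), np.zeros((8, 3)))
        r = nl.euler_lagrange_residual(traj, three_node_modified)
        assert np.all(r == 0)

    def test_onshell_lagrangian_pointwise_null(self, onshell_fine):
        traj, spec = onshell_fine
        rep = nl.mechanics_report(traj, spec)
        assert np.max(np.abs(rep.lagrangian)) < 1e-6
        assert rep.max_imag_lagrangian < 1e-10


class TestSecondOrderEmbedding:
    def test_identity_embedding(self):
        emb = nl.second_order_embedding(np.eye(2), [1.0, 1.0])
        assert np.array_equal(emb.E, np.eye(2))
        assert np.array_equal(emb.f, [1.0, 1.0])

    def test_scalar_arithmetic(self):
        emb = nl.second_order_embedding([[2.0]], [3.0])
        assert emb.E[0, 0] == 4.0 and emb.f[0] == 6.0

    def test_first_order_solutions_satisfy_embedded_equation(self):
        """Any solution of dz/dt = Az + d also solves d2z/dt2 = Ez + f,
        verified by numerical differentiation of the propagator solution."""
        from scipy.linalg import expm

        rng = np.random.default_rng(5)
        A = rng.standard_normal((3, 3)) * 0.5
        d = rng.standard_normal(3)
        emb = nl.second_order_embedding(A, d)
        z0 = rng.standard_normal(3)
        dt = 1e-3
        ts = np.arange(-2, 3) * dt + 0.7

        def z(t):
            # variation of constants with constant input d
            Ainv_d = np.linalg.solve(A, d)
            return expm(A * t) @ (z0 + Ainv_d) - Ainv_d

        zs = np.array([z(t) for t in ts])
        zdd = (zs[0] - 2 * zs[2] + zs[4]) / (2 * dt) ** 2
        assert np.max(np.abs(zdd - (emb.E @ zs[2] + emb.f))) < 1e-6

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            nl.second_order_embedding(np.eye(2), [1.0, 2.0, 3.0])


class TestSpuriousSolutions:
    def test_first_order_family_survives(self):
        for k1, a, d in [(1.0, 0.5, 2.0), (-3.0, 1.5, 0.0), (0.0, -1.0, 1.0)]:
            assert nl.spurious_solution_residual(a, d, k1, 0.0, 0.8) == pytest.approx(0.0, abs=1e-12)

    def test_second_branch_fails_first_order_equation(self):
        assert nl.spurious_solution_residual(1.0, 0.0, 0.0, 1.0, 0.0) == pytest.approx(-2.0)

    def test_analytic_form_of_residual(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a, d, k1, k2, t = rng.standard_normal(5)
            if abs(a) < 1e-3:
                continue
            r = nl.spurious_solution_residual(a, d, k1, k2, t)
            assert r == pytest.approx(-2 * a * k2 * np.exp(-a * t), rel=1e-9, abs=1e-12)

    def test_both_branches_solve_second_order_equation(self):
        """The embedded scalar equation d2z/dt2 = a^2 z + a d accepts both
        exponentials, which is exactly the non-uniqueness problem."""
        a, d = 0.7, 1.3
        dt = 1e-4
        for k1, k2 in [(1.0, 0.0), (0.0, 1.0), (0.5, -2.0)]:
            z = lambda t: k1 * np.exp(a * t) + k2 * np.exp(-a * t) - d / a
            t0 = 0.4
            zdd = (z(t0 - dt) - 2 * z(t0) + z(t0 + dt)) / dt**2
            assert zdd == pytest.approx(a**2 * z(t0) + a * d, rel=1e-5, abs=1e-5)

    def test_degenerate_a_rejected(self):
        with pytest.raises(ValidationError):
            nl.spurious_solution_residual(0.0, 1.0, 1.0, 1.0, 0.0)


class TestRealLagrangian:
    def test_zero_inputs_zero_value(self):
        assert nl.real_lagrangian_value(np.zeros(2), np.zeros(2), np.eye(2), np.zeros(2)) == 0.0

    def test_quadratic_form_at_rest(self):
        rng = np.random.default_rng(8)
        M = rng.standard_normal((3, 3))
        E = 0.5 * (M + M.T)
        z = rng.standard_normal(3)
        val = nl.real_lagrangian_value(z, np.zeros(3), E, np.zeros(3))
        assert val == pytest.approx(0.5 * z @ E @ z)

    def test_asymmetric_E_rejected(self):
        with pytest.raises(ValidationError):
            nl.real_lagrangian_value([0.0, 0.0], [0.0, 0.0],
                                     [[0.0, 1.0], [0.0, 0.0]], [0.0, 0.0])

    def test_non_unique_recovery_demonstration(self):
        """z = e^{-at} satisfies the Euler-Lagrange equation of the embedded
        real Lagrangian (numeric residual ~ 0) while failing the first-order
        equation — first-order dynamics cannot be recovered uniquely from
        the real-variable Lagrangian."""
        a = 0.9
        E = np.array([[a**2]])
        f = np.zeros(1)
        dt = 1e-4
        t0 = 0.3
        z = lambda t: np.exp(-a * t)
        # d/dt (dL/dzdot) - dL/dz = zdd - E z - f for this Lagrangian
        zdd = (z(t0 - dt) - 2 * z(t0) + z(t0 + dt)) / dt**2
        el_residual = zdd - E[0, 0] * z(t0) - f[0]
        assert abs(el_residual) < 1e-6
        first_order = nl.spurious_solution_residual(a, 0.0, 0.0, 1.0, t0)
        assert abs(first_order) > 0.1

    def test_el_equation_derives_from_lagrangian_gradients(self):
        """Finite-difference gradients of the real Lagrangian reproduce the
        embedded equation of motion: d/dt(dL/dzdot) = dL/dz."""
        rng = np.random.default_rng(9)
        M = rng.standard_normal((2, 2))
        E = 0.5 * (M + M.T)
        f = rng.standard_normal(2)
        z = rng.standard_normal(2)
        zdot = rng.standard_normal(2)
        h = 1e-6
        grad_z = np.array([
            (nl.real_lagrangian_value(z + h * e, zdot, E, f)
             - nl.real_lagrangian_value(z - h * e, zdot, E, f)) / (2 * h)
            for e in np.eye(2)
        ])
        grad_zdot = np.array([
            (nl.real_lagrangian_value(z, zdot + h * e, E, f)
             - nl.real_lagrangian_value(z, zdot - h * e, E, f)) / (2 * h)
            for e in np.eye(2)
        ])
        assert np.allclose(grad_z, E @ z + f, atol=1e-5)
        assert np.allclose(grad_zdot, zdot, atol=1e-5)


class TestNormHermiticityLink:
    def test_non_hermitian_perturbation_breaks_norm_conservation(self):
        """Replacing Hermitian A by A + eps*N (N random non-Hermitian) makes
        the norm drift by more than 1e-3 on the same grid — Hermiticity is
        what guarantees unitary dynamics."""
        rng = np.random.default_rng(12)
        spec = nl.make_three_node_network(variant="modified").with_(non_dissipative=True)
        N = rng.standard_normal((3, 3))
        N = N - N.T  # antisymmetric => maximally non-Hermitian real part
        A_bad = spec.A.real + 0.1 * N
        z0 = np.array([1.0, 0.5j, -0.2])
        # integrate the perturbed generator through the original-variant path
        # with the -i factor applied manually: dz/dt = -i A_bad z
        bad = nl.LinearModelSpec(A=-1j * A_bad, C=np.zeros((3, 1)), variant="original",
                                 non_dissipative=True)
        traj = nl.simulate_original(bad, z0, None, nl.NoiseSpec(), T=513, dt=0.02)
        norms = np.sum(np.abs(traj.states) ** 2, axis=1)
        assert np.max(np.abs(norms / norms[0] - 1.0)) > 1e-3
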