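"""Force evaluation and the overdamped velocity solve."""

import numpy as np
import pytest

from actoflow import (ModelParams, NetworkState, OverlapSet, elastic_forces,
                      find_overlaps, generate_mikado, motor_forces,
                      mu_of_gamma, assemble_velocity_system, solve_velocities)
from actoflow.mechanics import constraint_forces
from actoflow.oracles import dense_oracle, make_micro_suite


def _single(prm, stretch=1.0, angle=0.0):
    L = prm.L * stretch
    d = L * np.array([np.cos(angle), np.sin(angle)])
    return NetworkState(np.zeros((1, 2)), d[None, :], prm,
                        periodic_x=False, periodic_y=False)


def _manual_overlap(q=1.0, lam_i=0.5, lam_j=0.5, s=1.0):
    return OverlapSet(np.array([0]), np.array([1]), np.zeros((1, 2)),
                      np.array([lam_i]), np.array([lam_j]),
                      np.array([float(q)]), np.array([s]), {})


class TestElasticForces:
    def test_zero_strain_zero_force(self):
        prm = ModelParams()
        f = elastic_forces(_single(prm, stretch=1.0))
        assert np.allclose(f, 0.0)

    def test_extension_pulls_pointed_end_toward_barbed(self):
        prm = ModelParams(mu_e=100.0)
        f = elastic_forces(_single(prm, stretch=1.1))
        # gamma=0.1, mu_e=100 -> 10 pN on the pointed end along +x
        assert f[0] == pytest.approx([10.0, 0.0], abs=1e-9)
        assert f[1] == pytest.approx([-10.0, 0.0], abs=1e-9)

    def test_compression_uses_soft_modulus(self):
        prm = ModelParams(mu_e=100.0, mu_c=1.0)
        f = elastic_forces(_single(prm, stretch=0.9))
        assert np.linalg.norm(f[0]) == pytest.approx(0.1, rel=1e-9)
        assert f[0][0] < 0  # pushes the pointed end away from the barbed end

    def test_blend_is_continuous(self):
        prm = ModelParams(eps_gamma=0.005)
        g = np.linspace(-0.02, 0.02, 2001)
        force = mu_of_gamma(g, prm) * g
        jumps = np.abs(np.diff(force))
        assert jumps.max() < 5e-3  # no discontinuity across gamma = 0


class TestMotorForces:
    def test_parallel_filaments_cancel(self):
        prm = ModelParams(upsilon=10.0)
        state = NetworkState(np.array([[0.0, 0.0], [0.0, 1.0]]),
                             np.array([[4.0, 0.0], [4.0, 1.0]]),
                             ModelParams(L=4.0, l_c=1.0, upsilon=10.0,
                                         D_x=20, D_y=20),
                             periodic_x=False, periodic_y=False)
        f = motor_forces(state, _manual_overlap())
        assert np.allclose(f, 0.0)

    def test_antiparallel_midpoint_magnitude(self):
        prm = ModelParams(L=4.0, l_c=1.0, upsilon=10.0, D_x=20, D_y=20)
        state = NetworkState(np.array([[0.0, 0.0], [4.0, 0.1]]),
                             np.array([[4.0, 0.0], [0.0, 0.1]]),
                             prm, periodic_x=False, periodic_y=False)
        f = motor_forces(state, _manual_overlap())
        # |u_j - u_i| = 2, (1 - lambda) = 0.5 -> 10 pN on each pointed end
        assert np.linalg.norm(f[0]) == pytest.approx(10.0, rel=1e-12)
        assert np.linalg.norm(f[2]) == pytest.approx(10.0, rel=1e-12)
        # directed toward each filament's own pointed end
        assert f[0][0] < 0 and f[2][0] > 0

    def test_phi_zero_means_no_motors(self, rng):
        prm = ModelParams(D_x=15, D_y=10, L=4.0, l_c=0.8, phi=0.0)
        state = generate_mikado(prm, rng=rng)
        ov = find_overlaps(state, rng=rng)
        assert np.allclose(motor_forces(state, ov), 0.0)

    def test_newtons_third_law_network_totals(self, rng):
        prm = ModelParams(D_x=15, D_y=10, L=4.0, l_c=0.8, phi=0.7)
        state = generate_mikado(prm, rng=rng)
        state.p += rng.normal(0, 0.05, state.p.shape)
        ov = find_overlaps(state, rng=rng)
        assert np.abs(elastic_forces(state).sum(axis=0)).max() < 1e-10
        assert np.abs(motor_forces(state, ov).sum(axis=0)).max() < 1e-10


class TestVelocitySolve:
    def test_zero_forces_zero_velocities(self, small_network, rng):
        ov = find_overlaps(small_network, rng=rng)
        sys = assemble_velocity_system(small_network, ov,
                                       np.zeros((2 * small_network.n, 2)))
        assert np.allclose(solve_velocities(sys), 0.0)

    def test_diagonal_system_without_overlaps(self):
        prm = ModelParams(L=4.0, zeta=0.05, l_c=1.0, D_x=20, D_y=20)
        state = NetworkState(np.array([[0.0, 0.0], [10.0, 10.0]]),
                             np.array([[4.0, 0.0], [14.0, 10.0]]),
                             prm, periodic_x=False, periodic_y=False)
        from actoflow.network import empty_overlap_set
        f = np.zeros((4, 2))
        f[1] = [3.0, -1.0]
        v = solve_velocities(assemble_velocity_system(state,
                                                      empty_overlap_set(), f))
        assert np.allclose(v[1], f[1] / (prm.zeta * prm.L / 2.0))
        assert np.allclose(v[0], 0.0)

    def test_crosslink_row_sums_vanish(self, small_network, rng):
        # drag couplings are internal: each column block of A sums to the
        # solvent drag alone, so uniform translation feels only solvent drag
        ov = find_overlaps(small_network, rng=rng)
        sys = assemble_velocity_system(small_network, ov,
                                       np.zeros((2 * small_network.n, 2)))
        ones = np.ones(2 * small_network.n)
        prm = small_network.params
        assert np.allclose(sys.A @ ones, prm.zeta * prm.L / 2.0 * ones)

    def test_constrained_endpoints_have_zero_velocity(self, small_network, rng):
        ov = find_overlaps(small_network, rng=rng)
        n2 = 2 * small_network.n
        f = rng.normal(0, 1.0, (n2, 2))
        pin = np.zeros(n2, dtype=bool)
        pin[:6] = True
        v = solve_velocities(assemble_velocity_system(small_network, ov, f,
                                                      constrained=pin))
        assert np.allclose(v[pin], 0.0)

    def test_global_force_balance_with_constraints(self, small_network, rng):
        ov = find_overlaps(small_network, rng=rng)
        n2 = 2 * small_network.n
        f = elastic_forces(small_network)
        fext = np.zeros((n2, 2))
        fext[-4:, 0] = 0.5
        pin = np.zeros(n2, dtype=bool)
        pin[:6] = True
        sys = assemble_velocity_system(small_network, ov, f + fext,
                                       constrained=pin)
        v = solve_velocities(sys)
        reaction = constraint_forces(sys, v)
        prm = small_network.params
        solvent = prm.zeta * prm.L / 2.0 * v
        # internal forces cancel pairwise, so the constraint force equals
        # total solvent drag minus the applied external force
        total = reaction.sum(axis=0) - (solvent.sum(axis=0) - fext.sum(axis=0))
        assert np.abs(total).max() < 1e-8


class TestDenseOracleEquivalence:
    def test_micro_suite(self, rng):
        for case in make_micro_suite():
            ov = find_overlaps(case.state, rng=np.random.default_rng(0))
            f = elastic_forces(case.state) + motor_forces(case.state, ov)
            if case.f_ext is not None:
                f = f + case.f_ext
            sys = assemble_velocity_system(case.state, ov, f,
                                           constrained=case.pinned)
            v = solve_velocities(sys)
            vo = dense_oracle(case.state, ov, case.f_ext, case.pinned)
            scale = np.abs(vo).max() or 1.0
            assert np.abs(v - vo).max() / scale < 1e-8, case.name

    def test_random_networks(self):
        prm = ModelParams(D_x=12, D_y=12, L=4.0, l_c=1.0, phi=0.5)
        for trial in range(5):
            r = np.random.default_rng(100 + trial)
            state = generate_mikado(prm, rng=r, n_override=20)
            state.p += r.normal(0, 0.1, state.p.shape)
            state.b += r.normal(0, 0.1, state.b.shape)
            ov = find_overlaps(state, rng=r)
            f = elastic_forces(state) + motor_forces(state, ov)
            v = solve_velocities(assemble_velocity_system(state, ov, f))
            vo = dense_oracle(state, ov)
            assert np.abs(v - vo).max() / np.abs(vo).max() < 1e-8


def test_passive_network_dissipates_elastic_energy(rng):
    """Without motors or external forces, total elastic energy decreases."""
    from actoflow.dynamics import rk4_step
    from actoflow.scenarios import free

    prm = ModelParams(D_x=14, D_y=14, L=4.0, l_c=0.8, phi=0.0, upsilon=0.0,
                      zeta=0.2, seed=11)
    state = generate_mikado(prm, rng=rng)
    state.p += rng.normal(0, 0.08, state.p.shape)  # strain it
    sc = free()

    def energy(st):
        g = st.strain
        return float(np.sum(0.5 * mu_of_gamma(g, prm) * g ** 2 * prm.L))

    energies = [energy(state)]
    dt = 0.6 * prm.zeta * prm.L ** 2 / prm.mu_e / 4.0
    for _ in range(60):
        state, info = rk4_step(state, dt, sc, rng=rng)
        assert info.accepted
        energies.append(energy(state))
    diffs = np.diff(energies)
    assert (diffs <= 1e-10 * max(energies[0], 1.0)).all()
    assert energies[-1] < energies[0]
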