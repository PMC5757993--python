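"""Mikado generation, geometry queries and overlap detection."""

import numpy as np
import pytest

from actoflow import (Filament, ModelParams, NetworkState, filament_strain,
                      find_overlaps, generate_mikado, length_density)
from conftest import brute_force_overlaps


class TestModelParams:
    def test_reference_defaults(self):
        prm = ModelParams()
        assert (prm.mu_e, prm.mu_c, prm.xi, prm.zeta) == (100.0, 1.0, 100.0, 0.05)
        assert (prm.L, prm.l_c, prm.upsilon) == (5.0, 0.5, 10.0)
        assert (prm.D_x, prm.D_y) == (50.0, 20.0)

    @pytest.mark.parametrize("bad", [
        dict(mu_e=1.0, mu_c=10.0),     # softer in extension than compression
        dict(phi=1.5),
        dict(l_c=-0.5),
        dict(tau_r=10.0, tau_s=0.5),   # tau_s not < 0.01*tau_r
        dict(dt=-1e-3),
    ])
    def test_invariant_violations_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)

    def test_with_turnover_matches_density(self):
        prm = ModelParams().with_turnover(50.0)
        area = prm.D_x * prm.D_y
        assert prm.k_app * 50.0 * area == pytest.approx(prm.n_filaments, rel=1e-9)
        assert prm.tau_s < 0.01 * prm.tau_r


class TestMikado:
    @pytest.mark.parametrize("dims,expected", [
        ((50.0, 20.0, 5.0, 0.5), 800),
        ((6.6, 4.0, 1.0, 0.3), 176),
    ])
    def test_filament_count_formula(self, dims, expected):
        dx, dy, L, lc = dims
        prm = ModelParams(D_x=dx, D_y=dy, L=L, l_c=lc)
        state = generate_mikado(prm)
        assert state.n == expected == prm.n_filaments

    def test_created_at_rest_length(self, small_params, rng):
        state = generate_mikado(small_params, rng=rng)
        assert np.allclose(state.lengths, small_params.L)
        assert np.allclose(state.strain, 0.0)

    def test_reproducible_from_seed(self):
        prm = ModelParams(D_x=15, D_y=8, seed=42)
        a, b = generate_mikado(prm), generate_mikado(prm)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.b, b.b)

    def test_region_smaller_than_L_rejected(self):
        prm = ModelParams(D_x=3.0, D_y=8.0, L=5.0)
        with pytest.raises(ValueError):
            generate_mikado(prm, periodic_x=False, periodic_y=False)

    @pytest.mark.parametrize("l_c,expected", [(0.5, 4.0), (0.3, 2.0 / 0.3)])
    def test_length_density_is_2_over_lc(self, l_c, expected):
        prm = ModelParams(D_x=30, D_y=15, l_c=l_c)
        state = generate_mikado(prm)
        assert length_density(state) == pytest.approx(expected, rel=0.01)

    def test_length_density_empty(self, small_params):
        empty = NetworkState(np.zeros((0, 2)), np.zeros((0, 2)), small_params)
        assert length_density(empty) == 0.0


class TestFilamentStrain:
    def test_values(self):
        f = Filament(np.array([0.0, 0.0]), np.array([5.0, 0.0]))
        assert filament_strain(f, 5.0) == pytest.approx(0.0)
        f = Filament(np.array([0.0, 0.0]), np.array([5.5, 0.0]))
        assert filament_strain(f, 5.0) == pytest.approx(0.1)
        f = Filament(np.array([0.0, 0.0]), np.array([0.0, 4.5]))
        assert filament_strain(f, 5.0) == pytest.approx(-0.1)

    def test_requires_positive_rest_length(self):
        f = Filament(np.zeros(2), np.ones(2))
        with pytest.raises(ValueError):
            filament_strain(f, 0.0)


class TestFindOverlaps:
    def test_midpoint_crossing(self, small_params):
        L = small_params.L
        state = NetworkState(np.array([[0.0, 0.0], [L / 2, -L / 2]]),
                             np.array([[L, 0.0], [L / 2, L / 2]]),
                             small_params, periodic_x=False, periodic_y=False)
        ov = find_overlaps(state)
        assert ov.k == 1
        assert ov.lam_i[0] == pytest.approx(0.5)
        assert ov.lam_j[0] == pytest.approx(0.5)
        assert np.allclose(ov.x[0], [L / 2, 0.0])

    def test_parallel_filaments_no_overlap(self, small_params):
        L = small_params.L
        state = NetworkState(np.array([[0.0, 0.0], [0.0, 1.0]]),
                             np.array([[L, 0.0], [L, 1.0]]),
                             small_params, periodic_x=False, periodic_y=False)
        assert find_overlaps(state).k == 0

    @pytest.mark.parametrize("periodic", [(False, False), (False, True),
                                          (True, True)])
    def test_matches_brute_force(self, periodic, rng):
        prm = ModelParams(D_x=10.0, D_y=10.0, L=3.0, l_c=1.0)
        state = generate_mikado(prm, rng=rng, n_override=40,
                                periodic_x=periodic[0], periodic_y=periodic[1])
        ov = find_overlaps(state, rng=rng)
        expected = brute_force_overlaps(state)
        got = {tuple(sorted((int(i), int(j)))) for i, j in zip(ov.i, ov.j)}
        want = {tuple(sorted((i, j))) for i, j, _, _ in expected}
        assert got == want
        lam = {tuple(sorted((int(i), int(j)))): (li, lj)
               for i, j, li, lj in
               zip(ov.i, ov.j, ov.lam_i, ov.lam_j)}
        for i, j, t, u in expected:
            li, lj = lam[(i, j)]
            assert li == pytest.approx(t, abs=1e-9)
            assert lj == pytest.approx(u, abs=1e-9)

    def test_periodic_wrap_crossing_found(self):
        prm = ModelParams(D_x=20.0, D_y=8.0, L=4.0, l_c=1.0)
        # horizontal filament near y=0; vertical one reaching across the seam
        state = NetworkState(np.array([[8.0, 0.3], [10.0, 6.5]]),
                             np.array([[12.0, 0.3], [10.0, 10.5]]),
                             prm, periodic_x=False, periodic_y=True)
        state.wrap()
        ov = find_overlaps(state)
        assert ov.k == 1

    def test_crossings_per_filament_near_geometric_density(self, rng):
        # mean crossings per filament for the mikado recipe: the geometric
        # expectation is (4/pi)*L/l_c * (1 - edge corrections); the model's
        # own coarse approximation is L/l_c - 1.
        prm = ModelParams(D_x=30.0, D_y=20.0, L=5.0, l_c=0.5)
        state = generate_mikado(prm, rng=rng, periodic_x=True, periodic_y=True)
        ov = find_overlaps(state, rng=rng)
        per_fil = 2.0 * ov.k / state.n
        geometric = 4.0 * prm.L / (np.pi * prm.l_c)
        assert per_fil == pytest.approx(geometric, rel=0.08)
        coarse = prm.L / prm.l_c - 1.0
        assert 0.5 * coarse < per_fil < 2.0 * coarse

    def test_motor_fraction_converges_to_phi(self, rng):
        prm = ModelParams(D_x=20.0, D_y=12.0, L=4.0, l_c=0.5, phi=0.3)
        fractions = []
        for k in range(8):
            r = np.random.default_rng(k)
            state = generate_mikado(prm, rng=r)
            ov = find_overlaps(state, rng=r)
            fractions.append(ov.q.mean())
        n_total = 8 * 2000  # ~2k overlaps per draw
        assert np.mean(fractions) == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / n_total) + 0.01)

    def test_motor_flags_persist_for_persisting_pairs(self, rng):
        prm = ModelParams(D_x=15.0, D_y=10.0, L=4.0, l_c=1.0, phi=0.5)
        state = generate_mikado(prm, rng=rng)
        ov1 = find_overlaps(state, rng=rng)
        # tiny displacement: same topology, flags must carry over
        state.p += 1e-6
        state.b += 1e-6
        ov2 = find_overlaps(state, previous=ov1, rng=rng)
        keys = set(ov1.motor_assignments) & set(ov2.motor_assignments)
        assert keys
        for key in keys:
            assert ov1.motor_assignments[key] == ov2.motor_assignments[key]
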