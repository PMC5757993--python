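"""Stress, strain-rate and rheology extraction."""

import math

import numpy as np
import pandas as pd
import pytest

from actoflow import ModelParams, NetworkState, generate_mikado, find_overlaps
from actoflow import measure


def _state(p, b, prm, **kw):
    return NetworkState(np.asarray(p, float), np.asarray(b, float), prm, **kw)


class TestStressProfile:
    def test_unstrained_network_zero_everywhere(self, small_network):
        xs = np.linspace(0, small_network.params.D_x, 7)
        assert np.allclose(measure.stress_profile(small_network, xs), 0.0)

    def test_single_horizontal_filament(self):
        # gamma=0.1, mu_e=100, D_y=4 -> tension 10 pN -> sigma = 2.5 pN/um
        prm = ModelParams(mu_e=100.0, L=5.0, D_x=20, D_y=4.0, l_c=1.0)
        st = _state([[2.0, 2.0]], [[7.5, 2.0]], prm,
                    periodic_x=False, periodic_y=True)
        assert measure.stress_profile(st, [5.0])[0] == pytest.approx(2.5)
        assert measure.stress_profile(st, [10.0])[0] == 0.0

    def test_oblique_filament_axial_projection(self):
        prm = ModelParams(mu_e=100.0, L=5.0, D_x=20, D_y=4.0, l_c=1.0)
        ang = np.deg2rad(60.0)
        d = 5.5 * np.array([np.cos(ang), np.sin(ang)])
        st = _state([[2.0, 0.5]], [list(2.0 + d[:1]) + [0.5 + d[1]]], prm,
                    periodic_x=False, periodic_y=True)
        sigma = measure.stress_profile(st, [3.0])[0]
        assert sigma == pytest.approx(10.0 * np.cos(ang) / 4.0, rel=1e-9)

    def test_decomposition_sums(self, rng):
        prm = ModelParams(D_x=16, D_y=10, L=4, l_c=0.6)
        st = generate_mikado(prm, rng=rng)
        st.p += rng.normal(0, 0.1, st.p.shape)
        total, ext, comp = measure.mean_stresses(st)
        assert total == pytest.approx(ext + comp, abs=1e-12)
        assert ext >= 0.0 >= comp


class TestStrainRate:
    def _grid_state(self, prm):
        x = np.linspace(1.0, prm.D_x - 1.0, 30)
        p = np.column_stack([x - 1.0, np.full(30, 5.0)])
        b = np.column_stack([x + 1.0, np.full(30, 5.0)])
        return _state(p, b, prm, periodic_x=False, periodic_y=True)

    def test_uniform_translation_zero(self):
        prm = ModelParams(D_x=30, D_y=10, L=2, l_c=1.0)
        st = self._grid_state(prm)
        v = np.tile([0.7, 0.0], (2 * st.n, 1))
        # co-moving reference: uniform motion carries no deformation signal
        rate, nw = measure.strain_rate_slope(st, v)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_affine_flow_exact(self):
        prm = ModelParams(D_x=30, D_y=10, L=2, l_c=1.0)
        st = self._grid_state(prm)
        c = 3.4e-3
        v = np.zeros((2 * st.n, 2))
        v[0::2, 0] = c * st.p[:, 0]
        v[1::2, 0] = c * st.b[:, 0]
        rate, _ = measure.strain_rate(st, v)
        assert rate == pytest.approx(c, rel=1e-9)
        slope, _ = measure.strain_rate_slope(st, v)
        assert slope == pytest.approx(c, rel=1e-9)

    def test_estimators_agree_with_noise(self, rng):
        prm = ModelParams(D_x=30, D_y=10, L=2, l_c=1.0)
        st = self._grid_state(prm)
        c = 2.0e-3
        v = np.zeros((2 * st.n, 2))
        for sl, pos in ((slice(0, None, 2), st.p), (slice(1, None, 2), st.b)):
            v[sl, 0] = c * pos[:, 0] * (1 + rng.normal(0, 0.05, st.n))
        r1, _ = measure.strain_rate(st, v)
        r2, _ = measure.strain_rate_slope(st, v)
        assert r1 == pytest.approx(r2, rel=0.1)


class TestCumulativeStrain:
    def test_zero_rate(self):
        t = np.linspace(0, 10, 50)
        assert np.allclose(measure.cumulative_strain(t, np.zeros(50)), 0.0)

    def test_constant_rate(self):
        t = np.linspace(0, 10, 50)
        g = measure.cumulative_strain(t, np.full(50, 0.3))
        assert g[-1] == pytest.approx(3.0)


def _manufactured_traj(a, tau, eta, sigma, t_end=400.0, n=400):
    """gamma(t) = a(1-exp(-t/tau)) + (sigma/eta) t with its exact rate."""
    t = np.linspace(0, t_end, n)
    g = a * (1 - np.exp(-t / tau)) + sigma / eta * t
    rate = a / tau * np.exp(-t / tau) + sigma / eta
    return pd.DataFrame({"time": t, "cumulative_strain": g,
                         "strain_rate": rate,
                         "mean_total_stress": np.full(n, sigma)})


class TestRheologyExtraction:
    def test_manufactured_viscosity_recovery(self):
        # the n>0.8 constant-rate criterion fires once viscous strain
        # dominates the elastic plateau, i.e. near t* = 4*a*eta/sigma
        sigma, tau, a = 0.5, 30.0, 1.2e-3
        c = a / (10.0 * tau)     # slow creep: clear viscoelastic dip
        eta = sigma / c
        t_star = 4.0 * a / c
        fr = _manufactured_traj(a, tau, eta, sigma, t_end=3 * t_star, n=600)
        out = measure.effective_viscosity(fr, sigma)
        assert out["eta"] == pytest.approx(eta, rel=0.05)
        assert 0.5 * t_star < out["tau_c"] < 2.0 * t_star

    def test_manufactured_modulus_recovery(self):
        sigma, eta, tau, a = 0.5, 2.0e4, 30.0, 1.2e-3
        fr = _manufactured_traj(a, tau, eta, sigma)
        out = measure.elastic_modulus(fr, sigma)
        assert out["G0"] == pytest.approx(sigma / a, rel=0.02)

    def test_vanishing_stress_vanishing_plateau(self):
        fr = _manufactured_traj(1e-9, 30.0, 2.0e4, 1e-6)
        out = measure.elastic_modulus(fr, 1e-6)
        assert out["plateau"] == pytest.approx(1e-9, abs=1e-7)

    def test_failure_onset_detection(self):
        sigma, eta, tau, a = 0.5, 1.0e4, 20.0, 1.0e-3
        fr = _manufactured_traj(a, tau, eta, sigma, t_end=600.0, n=600)
        t = fr["time"].to_numpy()
        boost = np.where(t > 400, np.exp((t - 400) / 40.0), 1.0)
        fr["strain_rate"] *= boost
        from scipy.integrate import cumulative_trapezoid
        fr["cumulative_strain"] = np.r_[0.0, cumulative_trapezoid(
            fr["strain_rate"], t)]
        hit = measure.failure_onset(fr)
        assert hit is not None
        g_fail, t_fail = hit
        assert 400.0 < t_fail < 520.0
        # strain at onset ~ viscous creep accumulated by t_fail
        assert g_fail == pytest.approx(sigma / eta * t_fail + a, rel=0.2)

    def test_stress_buildup_summary_shapes(self):
        t = np.linspace(0, 100, 300)
        # saturating stress: sigma_ss equals the plateau
        s1 = 2.0 * (1 - np.exp(-t / 5.0))
        fr = pd.DataFrame({"time": t, "mean_total_stress": s1})
        out = measure.stress_buildup_summary(fr)
        assert out["sigma_m"] == pytest.approx(2.0, rel=0.02)
        assert out["sigma_ss"] == pytest.approx(2.0, rel=0.02)
        # peak-and-decay: sigma_ss < sigma_m, tau_m at the peak
        s2 = 3.0 * (t / 10.0) * np.exp(1 - t / 10.0)
        fr2 = pd.DataFrame({"time": t, "mean_total_stress": s2})
        out2 = measure.stress_buildup_summary(fr2)
        assert out2["sigma_m"] == pytest.approx(3.0, rel=0.05)
        # tau_m is a rise-time estimate (80% of peak): before the argmax
        assert 3.0 < out2["tau_m"] <= 11.0
        assert out2["sigma_ss"] < 0.2 * out2["sigma_m"]


class TestSpansAxis:
    def test_chain_spans_and_breaks(self):
        prm = ModelParams(D_x=10.0, D_y=6.0, L=4.0, l_c=1.0)
        p = np.array([[0.0, 3.0], [3.5, 3.5], [6.8, 2.2]])
        b = np.array([[4.0, 3.4], [7.5, 2.3], [10.8, 3.4]])
        st = _state(p, b, prm, periodic_x=False, periodic_y=True)
        ov = find_overlaps(st, rng=np.random.default_rng(0))
        assert measure.spans_axis(st, ov)
        # remove the middle filament: the chain no longer percolates
        st2 = _state(p[[0, 2]], b[[0, 2]], prm,
                     periodic_x=False, periodic_y=True)
        ov2 = find_overlaps(st2, rng=np.random.default_rng(0))
        assert not measure.spans_axis(st2, ov2)
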