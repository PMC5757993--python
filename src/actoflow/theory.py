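"""Closed-form predictions, phenomenological collapse curves, flow-regime
composition, and the coarse-grained density model.

Scaling results implemented here:

* effective viscosity of a crosslink-friction network,
  eta_c = C * xi * (L/l_c - 1)^2 (C a geometry prefactor, default 4/pi);
* elastic modulus G0 ~ 2*mu/l_c and the viscoelastic-to-viscous transition
  time tau_c ~ L^2*xi/(l_c*mu);
* turnover collapse of effective viscosity,
  eta = eta_c / (1 + (tau_c/tau_r)^m) with m = 3/4;
* turnover collapse of steady-state active stress,
  sigma_ss = sigma_m / ((tau_r/tau_m)^n + tau_m/tau_r) with n = 1;
* steady flow composition gammadot = sigma_ss/eta, which in the fast
  turnover regime (tau_r < min(tau_m, tau_c)) reduces to
  gammadot = (upsilon/(xi*L)) * tau_r^(1/4);
* empirical active-stress scales sigma_m ~ mu_e*upsilon/l_c and
  tau_m ~ L*xi/(mu_e*upsilon);
* a coarse-grained density balance for uniaxial extension with turnover,
  d rho/dt = (rho_0 - rho)/tau_r - rho*gammadot(rho), whose loss of a
  stable fixed point defines the critical turnover time tau_crit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .network import ModelParams

__all__ = [
    "ETA_PREFACTOR", "CollapseFit", "CoarseGrainedResult",
    "predict_eta_c", "predict_tau_c", "predict_g0",
    "predict_sigma_m_scale", "predict_tau_m_scale",
    "eta_of_turnover", "sigma_ss_of_turnover", "flow_strain_rate",
    "strain_rate_scaling", "tau_crit", "coarse_grained_density_ode",
    "fit_collapse_exponent",
]

#: Geometry prefactor of the effective-viscosity formula; the derivation
#: fixes it only up to an O(1) constant, so it is exposed as a module
#: constant and all scaling tests probe the functional form, not C.
ETA_PREFACTOR = 4.0 / math.pi

#: Collapse exponents of the phenomenological fits.
M_VISCOSITY = 0.75
N_STRESS = 1.0


# ---------------------------------------------------------------------------
# Closed-form predictions
# ---------------------------------------------------------------------------

def predict_eta_c(params: ModelParams, prefactor: float = ETA_PREFACTOR) -> float:
    """Effective viscosity C*xi*(L/l_c - 1)^2 of the crosslink-slip regime
    (pN s/um); zero when filaments carry no crossings (L = l_c)."""
    if params.L < params.l_c:
        raise ValueError("require L >= l_c")
    return prefactor * params.xi * (params.L / params.l_c - 1.0) ** 2


def predict_tau_c(params: ModelParams) -> float:
    """Viscoelastic-to-viscous transition time L^2*xi/(l_c*mu_e) (s)."""
    return params.L ** 2 * params.xi / (params.l_c * params.mu_e)


def predict_g0(params: ModelParams) -> float:
    """Elastic modulus 2*mu_e/l_c of the rigidly crosslinked network."""
    return 2.0 * params.mu_e / params.l_c


def predict_sigma_m_scale(params: ModelParams) -> float:
    """Empirical peak-stress scale mu_e*upsilon/l_c (pN/um, up to an O(1)
    prefactor)."""
    return params.mu_e * params.upsilon / params.l_c


def predict_tau_m_scale(params: ModelParams) -> float:
    """Empirical time-to-peak-stress scale L*xi/(mu_e*upsilon) (s, up to an
    O(1) prefactor)."""
    return params.L * params.xi / (params.mu_e * params.upsilon)


# ---------------------------------------------------------------------------
# Phenomenological collapse forms
# ---------------------------------------------------------------------------

def eta_of_turnover(tau_r, eta_c: float, tau_c: float,
                    m: float = M_VISCOSITY):
    """eta = eta_c / (1 + (tau_c/tau_r)^m): monotone in tau_r, half the
    asymptotic viscosity at tau_r = tau_c, ~eta_c*(tau_r/tau_c)^m for fast
    turnover."""
    tau_r = np.asarray(tau_r, dtype=float)
    out = eta_c / (1.0 + (tau_c / tau_r) ** m)
    return out if out.ndim else float(out)


def sigma_ss_of_turnover(tau_r, sigma_m: float, tau_m: float,
                         n: float = N_STRESS):
    """sigma_ss = sigma_m / ((tau_r/tau_m)^n + tau_m/tau_r): rises linearly
    for fast turnover, peaks near tau_r = tau_m, decays as tau_r^-n
    beyond."""
    tau_r = np.asarray(tau_r, dtype=float)
    out = sigma_m / ((tau_r / tau_m) ** n + tau_m / tau_r)
    return out if out.ndim else float(out)


def flow_strain_rate(sigma_ss, eta):
    """Steady flow rate gammadot = sigma_ss / eta (1/s)."""
    sigma_ss = np.asarray(sigma_ss, dtype=float)
    out = sigma_ss / np.asarray(eta, dtype=float)
    return out if out.ndim else float(out)


def strain_rate_scaling(params: ModelParams, tau_r):
    """Fast-turnover flow law gammadot = (upsilon/(xi*L)) * tau_r^(1/4).

    Phenomenological: tau_r enters through its numerical value in seconds
    (the collapse normalization used for the activity-gradient flows)."""
    tau_r = np.asarray(tau_r, dtype=float)
    out = params.upsilon / (params.xi * params.L) * tau_r ** 0.25
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Coarse-grained density model
# ---------------------------------------------------------------------------

def _eta_of_rho(rho, params: ModelParams, prefactor: float) -> np.ndarray:
    """Viscosity closure: l_c = 2/rho, so eta(rho) = C*xi*(L*rho/2 - 1)^2."""
    z = np.maximum(params.L * np.asarray(rho, dtype=float) / 2.0 - 1.0, 0.0)
    return prefactor * params.xi * z ** 2


@dataclass
class CoarseGrainedResult:
    """Density trajectory of the coarse-grained extension model."""

    t: np.ndarray
    rho: np.ndarray
    tau_crit: float
    failed: bool
    rho_ss: Optional[float]


def tau_crit(params: ModelParams, sigma: float,
             prefactor: float = ETA_PREFACTOR,
             rho_floor_frac: float = 0.0) -> float:
    """Largest turnover time that still admits a stable steady density.

    A fixed point solves (rho_0 - rho)/tau_r = rho*sigma/eta(rho); the
    marginal (tangency) condition gives
    tau_crit = max_rho (rho_0 - rho)*eta(rho)/(rho*sigma) over densities
    above the connectivity floor rho > 2/L.
    """
    if sigma <= 0:
        return math.inf
    rho0 = params.rho_0
    floor = 2.0 / params.L * (1.0 + rho_floor_frac)
    if rho0 <= floor:
        return 0.0
    rho = np.linspace(floor * (1.0 + 1e-6), rho0 * (1.0 - 1e-9), 20001)
    tau = (rho0 - rho) * _eta_of_rho(rho, params, prefactor) / (rho * sigma)
    return float(tau.max())


def coarse_grained_density_ode(params: ModelParams, tau_r: float,
                               sigma: float, t_end: Optional[float] = None,
                               rho_init: Optional[float] = None,
                               prefactor: float = ETA_PREFACTOR,
                               ) -> CoarseGrainedResult:
    """Integrate d rho/dt = (rho_0 - rho)/tau_r - rho*sigma/eta(rho).

    Density decreases under extension at the density-dependent flow rate
    and relaxes toward rho_0 through turnover.  Below tau_crit the two
    balance at a stable density; above it the density runs away toward the
    connectivity floor (reported as ``failed``).
    """
    from scipy.integrate import solve_ivp

    rho0 = params.rho_0
    if rho_init is None:
        rho_init = rho0
    floor = 2.0 / params.L
    tc = tau_crit(params, sigma, prefactor)

    def rhs(_t, y):
        rho = y[0]
        eta = _eta_of_rho(rho, params, prefactor)
        shear = rho * sigma / eta if eta > 0 else math.inf
        relax = (rho0 - rho) / tau_r if math.isfinite(tau_r) else 0.0
        return [relax - min(shear, 1e6)]

    def hit_floor(_t, y):
        return y[0] - floor * 1.001
    hit_floor.terminal = True
    hit_floor.direction = -1

    if t_end is None:
        t_end = 20.0 * (tau_r if math.isfinite(tau_r) else predict_tau_c(params))
    sol = solve_ivp(rhs, (0.0, t_end), [rho_init], events=hit_floor,
                    max_step=t_end / 200.0, rtol=1e-8, atol=1e-12)
    rho = sol.y[0]
    failed = bool(sol.t_events[0].size) or rho[-1] <= floor * 1.01
    rho_ss = None
    if not failed and len(rho) > 10:
        tail = rho[-len(rho) // 10:]
        if abs(tail[-1] - tail[0]) < 1e-4 * rho0:
            rho_ss = float(tail.mean())
    return CoarseGrainedResult(sol.t, rho, tc, failed, rho_ss)


# ---------------------------------------------------------------------------
# Collapse-exponent fitting
# ---------------------------------------------------------------------------

@dataclass
class CollapseFit:
    """Power-law fit in log-log space restricted to a regime mask."""

    exponent: float
    prefactor: float
    residual_rms: float
    n_points: int
    mask: np.ndarray


def fit_collapse_exponent(x_norm, y_norm, regime_mask=None,
                          min_points: int = 5) -> CollapseFit:
    """Least-squares slope of log y against log x over the masked regime.

    Raises ValueError with fewer than ``min_points`` usable points.
    """
    x = np.asarray(x_norm, dtype=float)
    y = np.asarray(y_norm, dtype=float)
    mask = np.ones(len(x), dtype=bool) if regime_mask is None \
        else np.asarray(regime_mask, dtype=bool)
    mask = mask & np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    if mask.sum() < min_points:
        raise ValueError(f"need >= {min_points} points in regime, "
                         f"have {int(mask.sum())}")
    lx, ly = np.log(x[mask]), np.log(y[mask])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    return CollapseFit(float(slope), float(math.exp(intercept)),
                       float(np.sqrt(np.mean(resid ** 2))), int(mask.sum()),
                       mask)
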