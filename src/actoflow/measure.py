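"""Observables: stress profiles and decompositions, filament vs network
strain, strain rate, cumulative strain, effective viscosity, elastic
modulus, transition time, and active-stress summaries.

Stress is a 2D force per unit length (pN/um): at an axial position x it is
the sum over all filaments crossing the vertical line at x of the axial
component of their tension, divided by the network height D_y.  Network
strain rate is estimated per filament as (1/X)dX/dt relative to the
reference boundary and averaged over an analysis window that excludes the
constrained boundary bands; cumulative network strain is its time
integral.  These definitions deliberately distinguish network strain from
the mean strain of individual filaments: the two differ whenever filaments
slide past one another or strained filaments are replaced by unstrained
ones through turnover.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .mechanics import mu_of_gamma
from .network import NetworkState, OverlapSet

__all__ = [
    "stress_profile", "mean_stresses", "strain_rate", "strain_rate_slope",
    "cumulative_strain", "effective_viscosity", "elastic_modulus",
    "stress_buildup_summary", "failure_onset", "record_frame", "spans_axis",
    "RheologySummary",
]

#: Fraction of D_x excluded at each constrained boundary in strain-rate
#: analysis windows.
WINDOW_FRAC = 0.05

#: A strain-rate estimate from fewer than this many filaments is flagged
#: low-confidence.
MIN_WINDOW_FILAMENTS = 10


# ---------------------------------------------------------------------------
# Instantaneous observables
# ---------------------------------------------------------------------------

def _tensions(state: NetworkState):
    gamma = state.strain
    t_ax = mu_of_gamma(gamma, state.params) * gamma * np.abs(state.uhat[:, 0])
    return gamma, t_ax


def stress_profile(state: NetworkState, x_positions: Sequence[float]) -> np.ndarray:
    """sigma(x): axial tension per unit height summed over filaments whose
    x-extent covers each position (pN/um).  Extension counts positive."""
    xs = np.atleast_1d(np.asarray(x_positions, dtype=float))
    if state.n == 0:
        return np.zeros(len(xs))
    gamma, t_ax = _tensions(state)
    lo = np.minimum(state.p[:, 0], state.b[:, 0])
    hi = np.maximum(state.p[:, 0], state.b[:, 0])
    out = np.empty(len(xs))
    Dx = state.params.D_x
    for k, x in enumerate(xs):
        if state.periodic_x:
            # a filament may straddle the seam; test x and its images
            cross = ((lo <= x) & (x <= hi)) | ((lo <= x + Dx) & (x + Dx <= hi)) \
                | ((lo <= x - Dx) & (x - Dx <= hi))
        else:
            cross = (lo <= x) & (x <= hi)
        out[k] = t_ax[cross].sum() / state.params.D_y
    return out


def mean_stresses(state: NetworkState) -> tuple[float, float, float]:
    """(total, extensional, compressional) stress averaged over x in
    [0, D_x]; the x-average of the line sum weights each filament by its
    axial extent, giving the closed form sum_i T_i |u_x| w_i / (D_x D_y)."""
    if state.n == 0:
        return 0.0, 0.0, 0.0
    gamma, t_ax = _tensions(state)
    w = np.minimum(np.abs(state.b[:, 0] - state.p[:, 0]), state.params.D_x)
    contrib = t_ax * w / (state.params.D_x * state.params.D_y)
    ext = float(contrib[gamma > 0].sum())
    comp = float(contrib[gamma < 0].sum())
    return ext + comp, ext, comp


def _centroid_velocities(v_end: np.ndarray) -> np.ndarray:
    return 0.5 * (v_end[0::2] + v_end[1::2])


def strain_rate(state: NetworkState, velocities: np.ndarray,
                x_ref: float = 0.0,
                window: Optional[tuple[float, float]] = None,
                mask: Optional[np.ndarray] = None,
                ) -> tuple[float, int]:
    """Mean of the per-filament estimates (1/X)dX/dt (1/s).

    X is each filament centroid's axial distance from the reference
    boundary; the default window excludes the pinned and forced bands, and
    ``mask`` optionally restricts to a filament subset (e.g. the
    load-bearing cluster).  Returns (rate, number of filaments used);
    callers treat counts below ``MIN_WINDOW_FILAMENTS`` as low-confidence.
    """
    prm = state.params
    if window is None:
        window = (WINDOW_FRAC * prm.D_x, (1.0 - WINDOW_FRAC) * prm.D_x)
    X = state.mid[:, 0] - x_ref
    v = _centroid_velocities(velocities)[:, 0]
    sel = (X > window[0]) & (X < window[1])
    if mask is not None:
        sel &= mask
    if sel.sum() < MIN_WINDOW_FILAMENTS:
        sel = X > 0.02 * prm.D_x
        if mask is not None:
            sel &= mask
    if not sel.any():
        return 0.0, 0
    return float(np.mean(v[sel] / X[sel])), int(sel.sum())


def strain_rate_slope(state: NetworkState, velocities: np.ndarray,
                      window: Optional[tuple[float, float]] = None,
                      ) -> tuple[float, int]:
    """Least-squares slope of centroid v_x against centroid x (1/s): the
    affine-flow estimator, exact for v(X) = c X."""
    prm = state.params
    if window is None:
        window = (WINDOW_FRAC * prm.D_x, (1.0 - WINDOW_FRAC) * prm.D_x)
    x = state.mid[:, 0]
    v = _centroid_velocities(velocities)[:, 0]
    sel = (x > window[0]) & (x < window[1])
    if sel.sum() < 2:
        return 0.0, int(sel.sum())
    slope = np.polyfit(x[sel], v[sel], 1)[0]
    return float(slope), int(sel.sum())


def _gyration_rate(state: NetworkState, velocities: np.ndarray) -> float:
    """(1/R)dR/dt of the centroid cloud: isotropic strain rate of a freely
    contracting patch (negative while contracting)."""
    c = state.mid
    v = _centroid_velocities(velocities)
    dc = c - c.mean(axis=0)
    dv = v - v.mean(axis=0)
    r2 = float((dc * dc).sum())
    if r2 <= 0:
        return 0.0
    return float((dc * dv).sum() / r2)


def spans_axis(state: NetworkState, overlaps: OverlapSet) -> bool:
    """True when a connected chain of overlapping filaments links the
    pinned band to the forced band (percolation along the strain axis)."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    prm = state.params
    xlo = np.minimum(state.p[:, 0], state.b[:, 0])
    xhi = np.maximum(state.p[:, 0], state.b[:, 0])
    src = xlo < WINDOW_FRAC * prm.D_x
    snk = xhi > (1.0 - WINDOW_FRAC) * prm.D_x
    if not src.any() or not snk.any():
        return False
    if overlaps.k == 0:
        return bool((src & snk).any())
    n = state.n
    adj = sp.coo_matrix((np.ones(overlaps.k), (overlaps.i, overlaps.j)),
                        shape=(n, n))
    _, labels = connected_components(adj + adj.T, directed=False)
    return bool(np.intersect1d(labels[src], labels[snk]).size > 0)


def record_frame(state: NetworkState, overlaps: OverlapSet,
                 velocities: np.ndarray, scenario,
                 ref_scale: Optional[dict] = None) -> dict:
    """Per-frame measurement record (one row of a trajectory table)."""
    gamma = state.strain
    total, ext, comp = mean_stresses(state)
    n = max(state.n, 1)
    rec = {
        "time": state.time,
        "n_filaments": state.n,
        "length_density": float(state.lengths.sum()
                                / (state.params.D_x * state.params.D_y)),
        "mean_total_stress": total,
        "mean_ext_stress": ext,
        "mean_comp_stress": comp,
        "mean_filament_strain": float(gamma.sum() / n),
        "mean_ext_strain": float(gamma[gamma > 0].sum() / n),
        "mean_comp_strain": float(gamma[gamma < 0].sum() / n),
    }
    kind = getattr(scenario, "kind", "uniaxial")
    if velocities is None or len(velocities) != 2 * state.n:
        rate, used = 0.0, 0
    elif kind == "uniaxial":
        mask = None
        bf = getattr(scenario, "band_frac", WINDOW_FRAC)
        if overlaps is not None and overlaps.k:
            from .scenarios import _connected_to_left_wall

            mask = _connected_to_left_wall(state, overlaps, bf)
        prm = state.params
        rate, used = strain_rate(state, velocities, mask=mask,
                                 window=((bf + 0.02) * prm.D_x,
                                         (1.0 - bf) * prm.D_x))
    elif kind == "gradient":
        prm = state.params
        rate, used = strain_rate_slope(
            state, velocities,
            window=(0.07 * prm.D_x, 0.43 * prm.D_x))
    elif kind == "free":
        rate, used = _gyration_rate(state, velocities), state.n
    else:  # isometric
        rate, used = strain_rate_slope(state, velocities,
                                       window=(0.0, state.params.D_x))
    rec["strain_rate"] = rate
    rec["n_window"] = used
    if kind == "gradient" and overlaps.k:
        x = np.mod(overlaps.x[:, 0], state.params.D_x)
        left = x < 0.5 * state.params.D_x
        rec["motor_frac_left"] = float(overlaps.q[left].mean()) if left.any() else 0.0
        rec["motor_frac_right"] = float(overlaps.q[~left].mean()) if (~left).any() else 0.0
    return rec


def reference_scale(state: NetworkState, scenario) -> dict:
    c = state.mid
    dc = c - c.mean(axis=0)
    return {"R0": float(np.sqrt((dc * dc).sum() / max(state.n, 1)))}


# ---------------------------------------------------------------------------
# Trajectory-level analyses
# ---------------------------------------------------------------------------

class RheologySummary(dict):
    """Dict-like container for G0, eta, tau_c, sigma_m, tau_m, sigma_ss."""

    def __getattr__(self, name):
        try:
            return self[name]
        except KeyError as exc:  # pragma: no cover
            raise AttributeError(name) from exc


def cumulative_strain(times: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Trapezoidal time integral of the strain rate."""
    from scipy.integrate import cumulative_trapezoid

    return np.concatenate([[0.0], cumulative_trapezoid(rates, times)])


def _frames(traj):
    return traj.frames if hasattr(traj, "frames") else traj


def _smooth(y: np.ndarray, w: int = 5) -> np.ndarray:
    if len(y) < w:
        return y
    kern = np.ones(w) / w
    pad = np.r_[np.full(w // 2, y[0]), y, np.full(w - 1 - w // 2, y[-1])]
    return np.convolve(pad, kern, mode="valid")


def _local_exponent(t: np.ndarray, g: np.ndarray) -> np.ndarray:
    """d ln g / d ln t on the frame grid (NaN where undefined)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lt, lg = np.log(t), np.log(np.maximum(g, 1e-300))
    n = np.full(len(t), np.nan)
    ok = np.isfinite(lt) & np.isfinite(lg) & (g > 0)
    if ok.sum() >= 3:
        n[ok] = np.gradient(lg[ok], lt[ok])
    return n


def _event_cut(traj, fr):
    """Index cutting the frame table at the first recorded event (e.g.
    percolation loss); len(fr) when no event applies."""
    events = getattr(traj, "events", None)
    t = fr["time"].to_numpy()
    if events:
        return max(int(np.searchsorted(t, events[0][0])), 8)
    return len(t)


def viscous_window(traj, n_threshold: float = 0.8, t_cut: bool = True):
    """Constant-rate window: (onset index, onset time) of the last sustained
    crossing of the local log-log slope of cumulative strain above
    ``n_threshold`` (strain grows ~t^n with n > 0.8).  With ``t_cut`` the
    trace is truncated at the first recorded event so that post-failure
    acceleration cannot masquerade as the viscous window."""
    fr = _frames(traj)
    if t_cut:
        fr = fr.iloc[:_event_cut(traj, fr)]
    t = fr["time"].to_numpy()
    g = _smooth(fr["cumulative_strain"].to_numpy())
    n = _local_exponent(t, g)
    above = n > n_threshold
    onset = None
    for k in range(1, len(t)):
        if above[k] and not above[k - 1]:
            onset = k
    if onset is None:
        onset = 1 if above[1:].any() else None
    if onset is None:
        return None, None
    return onset, float(t[onset])


def failure_onset(traj, factor: float = 2.0):
    """Cumulative strain (fraction) and time at which the strain rate first
    exceeds ``factor`` times the viscous-window mean for three consecutive
    frames; None if the run never accelerates."""
    fr = _frames(traj)
    k0, _ = viscous_window(traj)
    if k0 is None:
        return None
    t = fr["time"].to_numpy()
    rate = _smooth(fr["strain_rate"].to_numpy())
    g = fr["cumulative_strain"].to_numpy()
    n_ref = max(5, (len(t) - k0) // 5)
    ref = float(np.median(rate[k0:k0 + n_ref]))
    if ref <= 0:
        return None
    hot = rate[k0:] > factor * ref
    for k in range(len(hot) - 2):
        if hot[k] and hot[k + 1] and hot[k + 2]:
            idx = k0 + k
            return float(g[idx]), float(t[idx])
    return None


def flow_breakdown(traj, hi: float = 2.0, lo: float = 0.3):
    """Cumulative strain (fraction), time and mode at which sustained
    viscous flow is lost.

    After the constant-rate window opens, breakdown is the first sustained
    (3-frame) excursion of the smoothed strain rate above ``hi`` times the
    window reference (tearing and acceleration) or below ``lo`` times it
    (loss of the percolating load path and arrest).  Returns None when the
    flow persists to the end of the run.
    """
    fr = _frames(traj)
    k0, _ = viscous_window(traj, t_cut=False)
    if k0 is None:
        return None
    t = fr["time"].to_numpy()
    rate = _smooth(fr["strain_rate"].to_numpy())
    g = fr["cumulative_strain"].to_numpy()
    n_ref = max(5, (len(t) - k0) // 5)
    ref = float(np.median(rate[k0:k0 + n_ref]))
    if ref <= 0:
        return None
    for k in range(k0 + n_ref, len(t) - 2):
        window = rate[k:k + 3]
        if (window > hi * ref).all():
            return float(g[k]), float(t[k]), "acceleration"
        if (window < lo * ref).all():
            return float(g[k]), float(t[k]), "arrest"
    return None


def effective_viscosity(traj, sigma_applied: float) -> RheologySummary:
    """eta = sigma / (mean strain rate over the constant-rate window) and
    the transition time tau_c (window onset).

    The window runs from the onset of n > 0.8 growth to the failure onset
    (strain-rate acceleration), or to the end of the run.  When the window
    is never reached the run failed first: eta is NaN.
    """
    fr = _frames(traj)
    k0, tau_c = viscous_window(traj)
    out = RheologySummary(eta=math.nan, tau_c=math.nan, window=(None, None))
    if k0 is None:
        return out
    fr = fr.iloc[:_event_cut(traj, fr)]
    t = fr["time"].to_numpy()
    rate = fr["strain_rate"].to_numpy()
    fail = failure_onset(traj)
    k1 = len(t)
    if fail is not None:
        k1 = min(k1, int(np.searchsorted(t, fail[1])))
    k0 = min(k0, max(k1 - 2, 1))
    if k1 - k0 < 2:
        return out
    mean_rate = float(np.mean(rate[k0:k1]))
    if mean_rate > 0:
        out["eta"] = sigma_applied / mean_rate
    out["tau_c"] = tau_c
    out["mean_rate"] = mean_rate
    out["window"] = (float(t[k0]), float(t[k1 - 1]))
    return out


def elastic_modulus(traj, sigma_applied: float) -> RheologySummary:
    """G0 = sigma / (extrapolated elastic plateau strain).

    The cumulative strain is fitted with the viscoelastic form
    a*(1 - exp(-t/tau)) + c*t; the fast-phase plateau a is the elastic
    limit and G0 = sigma/a.
    """
    from scipy.optimize import curve_fit

    fr = _frames(traj)
    fr = fr.iloc[:_event_cut(traj, fr)]
    t = fr["time"].to_numpy()
    g = fr["cumulative_strain"].to_numpy()
    fail = failure_onset(traj)
    if fail is not None:
        k1 = int(np.searchsorted(t, fail[1]))
        if k1 > 8:
            t, g = t[:k1], g[:k1]
    if len(t) < 5 or g.max() <= 0:
        return RheologySummary(G0=math.nan, plateau=math.nan, tau=math.nan)

    def model(tt, a, tau, c):
        return a * (1.0 - np.exp(-tt / tau)) + c * tt

    gmax = g.max()
    tmax = t.max()
    p0 = (0.5 * gmax, 0.1 * tmax, 0.5 * gmax / tmax)
    try:
        popt, _ = curve_fit(model, t, g, p0=p0,
                            bounds=([0.0, 1e-12, 0.0],
                                    [10 * gmax, 10 * tmax, np.inf]),
                            maxfev=20000)
    except RuntimeError:
        return RheologySummary(G0=math.nan, plateau=math.nan, tau=math.nan)
    a, tau, c = popt
    g0 = sigma_applied / a if a > 0 else math.nan
    return RheologySummary(G0=float(g0), plateau=float(a), tau=float(tau),
                           creep_rate=float(c))


def stress_buildup_summary(traj, tail_frac: float = 0.2) -> RheologySummary:
    """Peak stress sigma_m, its buildup time tau_m, and the steady-state
    stress sigma_ss (mean of |total stress| over the final ``tail_frac``
    of the run).

    The stress trace fluctuates strongly about its plateau, so the series
    is smoothed over ~5% of the run and tau_m is taken as the first time
    the smoothed stress reaches 80% of its maximum — a rise-time estimate
    far more stable run-to-run than the argmax of a noisy plateau.
    Magnitudes are used so contractile (negative) total stress summarises
    the same way as extensile stress.
    """
    fr = _frames(traj)
    t = fr["time"].to_numpy()
    s = _smooth(np.abs(fr["mean_total_stress"].to_numpy()),
                w=max(5, len(t) // 20))
    k = int(np.argmax(s))
    rise = np.flatnonzero(s >= 0.8 * s[k])
    k_rise = int(rise[0]) if rise.size else k
    k_tail = max(int(len(t) * (1.0 - tail_frac)), min(k + 1, len(t) - 1))
    return RheologySummary(sigma_m=float(s[k]), tau_m=float(t[k_rise]),
                           sigma_ss=float(np.mean(s[k_tail:])))
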