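"""Experimental setups: uniaxial extension, free contraction, isometric
contraction, and activity-gradient flow.

Each scenario supplies the boundary conditions per step (velocity-pinned
endpoints and external endpoint forces, membership re-evaluated dynamically)
and, for the gradient scenario, the position-dependent active fraction used
when motor flags are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np

from .network import ModelParams, NetworkState

__all__ = [
    "Scenario",
    "uniaxial",
    "free",
    "isometric",
    "gradient",
    "uniaxial_constraints",
    "gradient_phi_field",
]

#: Width of the pinned / forced boundary bands, fraction of D_x.
BOUNDARY_FRAC = 0.05


@dataclass
class Scenario:
    """Boundary protocol and activity pattern for one run.

    kind : one of {"uniaxial", "free", "isometric", "gradient"}.
    applied_stress : boundary force per unit length sigma (pN/um),
        uniaxial only.
    phi_hi : active fraction of the active half (gradient) or of the whole
        network (isometric); ``None`` defers to ``params.phi``.
    ramp_frac : width of the linear ramps of the gradient activity field,
        fraction of D_x.
    """

    kind: str
    applied_stress: float = 0.0
    phi_hi: Optional[float] = None
    ramp_frac: float = 0.05
    periodic_x: bool = False
    periodic_y: bool = True
    #: loading ramp: the applied stress grows linearly from zero over this
    #: many seconds (smoothing mandate — avoids an impulsive start that
    #: tears the sparsely attached forcing band off the network).
    stress_ramp_time: float = 0.0
    #: width of the pinned / forced boundary bands as a fraction of D_x.
    band_frac: float = BOUNDARY_FRAC

    def phi_field(self, params: ModelParams) -> Optional[Callable]:
        if self.kind != "gradient":
            return None
        hi = params.phi if self.phi_hi is None else self.phi_hi
        return lambda x: gradient_phi_field(x, params.D_x, phi_hi=hi,
                                            ramp=self.ramp_frac * params.D_x)

    def boundary(self, state: NetworkState,
                 overlaps=None) -> Tuple[np.ndarray, np.ndarray]:
        """(pinned mask over 2N endpoints, external forces (2N, 2)).

        When the current overlap set is supplied, boundary forces go only
        to endpoints of filaments that still carry at least one crosslink:
        a filament that has detached from the network no longer belongs to
        its loaded edge, and feeding it force would simply carry the load
        away with the debris.
        """
        ne = 2 * state.n
        pinned = np.zeros(ne, dtype=bool)
        fext = np.zeros((ne, 2))
        if self.kind == "uniaxial":
            sigma = self.applied_stress
            if self.stress_ramp_time > 0:
                sigma *= min(1.0, state.time / self.stress_ramp_time)
            attached = None
            if overlaps is not None and overlaps.k:
                attached = _connected_to_left_wall(state, overlaps,
                                                   self.band_frac)
            return uniaxial_constraints(state, sigma, attached=attached,
                                        band_frac=self.band_frac,
                                        require_nonempty=self.applied_stress > 0)
        return pinned, fext


def uniaxial(stress: float, ramp_time: float = 0.0,
             band_frac: float = BOUNDARY_FRAC) -> Scenario:
    """Pinned-left / forced-right extension protocol (periodic in y)."""
    if stress < 0:
        raise ValueError("applied stress must be non-negative")
    return Scenario("uniaxial", applied_stress=stress,
                    periodic_x=False, periodic_y=True,
                    stress_ramp_time=ramp_time, band_frac=band_frac)


def free() -> Scenario:
    """Active network with free boundaries (no constraints, no periodicity)."""
    return Scenario("free", periodic_x=False, periodic_y=False)


def isometric(phi: Optional[float] = None) -> Scenario:
    """Contraction against fixed boundaries, realized with doubly periodic
    boundary conditions; boundary stress is read from the internal stress."""
    return Scenario("isometric", phi_hi=phi, periodic_x=True, periodic_y=True)


def gradient(phi_hi: float = 0.5, ramp_frac: float = 0.05) -> Scenario:
    """Right half active (phi = phi_hi), left half passive (phi = 0),
    doubly periodic."""
    return Scenario("gradient", phi_hi=phi_hi, ramp_frac=ramp_frac,
                    periodic_x=True, periodic_y=True)


def _connected_to_left_wall(state: NetworkState, overlaps,
                            band_frac: float = BOUNDARY_FRAC) -> np.ndarray:
    """Filaments in the same crosslink-graph component as the pinned band.

    Only this load-bearing cluster can transmit boundary stress to the
    wall; debris that has sheared off is excluded from the forcing so the
    applied load is not carried away with it.
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    n = state.n
    adj = sp.coo_matrix((np.ones(overlaps.k), (overlaps.i, overlaps.j)),
                        shape=(n, n))
    _, labels = connected_components(adj + adj.T, directed=False)
    xlo = np.minimum(state.p[:, 0], state.b[:, 0])
    wall = xlo < band_frac * state.params.D_x
    if not wall.any():
        return np.ones(n, dtype=bool)
    wall_labels = np.unique(labels[wall])
    return np.isin(labels, wall_labels)


def uniaxial_constraints(state: NetworkState, sigma: float,
                         attached: Optional[np.ndarray] = None,
                         band_frac: float = BOUNDARY_FRAC,
                         require_nonempty: Optional[bool] = None,
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Pin endpoints with x < 0.05*D_x; share a total rightward force
    sigma*D_y equally among endpoints with x > 0.95*D_x.

    Membership is re-evaluated at every call, so material that flows into
    either band joins it.  When ``attached`` (per-filament boolean, the
    wall-connected load-bearing cluster) is given, the forcing band tracks
    that cluster's material right edge instead of the fixed coordinate
    band: the load always drives the connected network and never leaves
    with sheared-off debris.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    prm = state.params
    x = np.empty(2 * state.n)
    x[0::2] = state.p[:, 0]
    x[1::2] = state.b[:, 0]
    pinned = x < band_frac * prm.D_x
    forced = x > (1.0 - band_frac) * prm.D_x
    fext = np.zeros((2 * state.n, 2))
    if require_nonempty is None:
        require_nonempty = sigma > 0
    if require_nonempty and not forced.any():
        raise ValueError("empty forcing region: no endpoints with "
                         f"x > {(1.0 - band_frac) * prm.D_x:g}")
    if attached is not None and attached.any():
        member = np.repeat(attached, 2)
        x_edge = x[member].max()
        forced = member & (x > x_edge - band_frac * prm.D_x)
    nf = int(forced.sum())
    if sigma > 0 and nf > 0:
        fext[forced, 0] = sigma * prm.D_y / nf
    return pinned, fext


def gradient_phi_field(x, D_x: float, phi_hi: float = 0.5,
                       ramp: Optional[float] = None):
    """Active fraction vs position: 0 on the left half, ``phi_hi`` on the
    right half, with linear ramps of width ``ramp`` centred on the midline
    and on the periodic seam (x = 0 = D_x).

    The exact midline returns ``phi_hi/2``.
    """
    if ramp is None:
        ramp = 0.05 * D_x
    x = np.mod(np.asarray(x, dtype=float), D_x)
    # Unfold the seam: points just past x = 0 belong to the falling edge
    # of the active half, so shift them by one period.
    xe = np.where(x < 0.5 * ramp, x + D_x, x)
    up = np.clip((xe - (0.5 * D_x - 0.5 * ramp)) / ramp, 0.0, 1.0)
    down = np.clip((D_x + 0.5 * ramp - xe) / ramp, 0.0, 1.0)
    val = phi_hi * np.minimum(up, down)
    return val if val.ndim else float(val)
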