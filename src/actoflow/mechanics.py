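"""Force evaluation and the overdamped velocity solve A·ẋ = f(x).

Force balance per endpoint (low Reynolds number, inertia neglected):

    zeta*(L/2)*v_p,i + sum_j (1-lam_ij)*xi_ij*(v_i - v_j) = F_elas + F_motor + F_ext
    zeta*(L/2)*v_b,i + sum_j    lam_ij *xi_ij*(v_i - v_j) = ...

where v_i = (v_p,i + v_b,i)/2 is the filament centroid velocity and
xi_ij = xi*s_ij includes the tip engagement ramp.  The couplings are
identical for the x and y coordinates, so A is assembled once as a
(2N x 2N) endpoint matrix and solved with two right-hand-side columns.

Endpoint indexing convention used across the package: endpoint 2*i is the
pointed end of filament i, endpoint 2*i+1 its barbed end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import ModelParams, NetworkState, OverlapSet

__all__ = [
    "ForceAccumulator",
    "VelocitySystem",
    "mu_of_gamma",
    "elastic_forces",
    "motor_forces",
    "assemble_velocity_system",
    "solve_velocities",
    "constraint_forces",
]

#: Relative residual tolerance for the sparse velocity solve.
SOLVER_RTOL = 1e-10


def mu_of_gamma(gamma: np.ndarray, params: ModelParams) -> np.ndarray:
    """Piecewise spring constant with a linear blend over |gamma| < eps_gamma.

    mu = mu_e for extension, mu_c for compression; the ramp removes the
    force-derivative discontinuity at zero strain.
    """
    eps = params.eps_gamma
    frac = np.clip((np.asarray(gamma, float) + eps) / (2.0 * eps), 0.0, 1.0)
    return params.mu_c + (params.mu_e - params.mu_c) * frac


@dataclass
class ForceAccumulator:
    """Per-endpoint force vectors (pN), shape (2N, 2) each."""

    elastic: np.ndarray
    motor: np.ndarray
    external: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.elastic + self.motor + self.external

    @classmethod
    def zeros(cls, n_filaments: int) -> "ForceAccumulator":
        z = np.zeros((2 * n_filaments, 2))
        return cls(z, z.copy(), z.copy())


def elastic_forces(state: NetworkState,
                   p: Optional[np.ndarray] = None,
                   b: Optional[np.ndarray] = None) -> np.ndarray:
    """Elastic endpoint forces, shape (2N, 2).

    F_p = mu(gamma)*gamma*uhat pulls the pointed end toward the barbed end
    under extension; F_b = -F_p, so each internal pair sums to zero exactly.
    ``p``/``b`` override the state's positions (used at RK4 stages).
    """
    if p is None:
        p, b = state.p, state.b
    d = b - p
    ell = np.linalg.norm(d, axis=1)
    uhat = d / ell[:, None]
    gamma = (ell - state.params.L) / state.params.L
    fmag = mu_of_gamma(gamma, state.params) * gamma
    fp = fmag[:, None] * uhat
    out = np.empty((2 * state.n, 2))
    out[0::2] = fp
    out[1::2] = -fp
    return out


def motor_forces(state: NetworkState, overlaps: OverlapSet,
                 p: Optional[np.ndarray] = None,
                 b: Optional[np.ndarray] = None) -> np.ndarray:
    """Motor endpoint forces, shape (2N, 2).

    At each flagged crossing a force of magnitude ``upsilon`` acts on each
    filament toward its pointed end, with the reaction on its partner; per
    filament the pair force is upsilon*(uhat_j - uhat_i), apportioned to the
    endpoints by (1-lam, lam).  Forces are scaled by the engagement ramp so
    crossings appear and disappear smoothly at tips.  The network total is
    exactly zero.
    """
    out = np.zeros((2 * state.n, 2))
    if overlaps.k == 0 or state.params.upsilon == 0.0:
        return out
    if p is None:
        p, b = state.p, state.b
    d = b - p
    uhat = d / np.linalg.norm(d, axis=1)[:, None]
    w = state.params.upsilon * overlaps.q * overlaps.s
    act = w > 0.0
    if not act.any():
        return out
    i, j = overlaps.i[act], overlaps.j[act]
    li, lj = overlaps.lam_i[act], overlaps.lam_j[act]
    pair = w[act, None] * (uhat[j] - uhat[i])  # force on filament i
    np.add.at(out, 2 * i, (1.0 - li)[:, None] * pair)
    np.add.at(out, 2 * i + 1, li[:, None] * pair)
    np.add.at(out, 2 * j, -(1.0 - lj)[:, None] * pair)
    np.add.at(out, 2 * j + 1, -lj[:, None] * pair)
    return out


@dataclass
class VelocitySystem:
    """Assembled overdamped system for endpoint velocities.

    ``A`` (2N x 2N, sparse) holds the drag couplings with constrained
    endpoint rows replaced by identity; ``A_raw`` keeps the unconstrained
    matrix for reaction-force queries.  ``f`` is the (2N, 2) right-hand
    side of elastic + motor + external forces, zeroed on constrained rows.
    """

    A: sp.csc_matrix
    f: np.ndarray
    constrained: np.ndarray
    raw_coo: tuple
    f_raw: np.ndarray
    _lu: object = None
    _A_raw: object = None

    @property
    def A_raw(self) -> sp.csr_matrix:
        """Unconstrained drag matrix (built on demand)."""
        if self._A_raw is None:
            rows, cols, data, ne = self.raw_coo
            self._A_raw = sp.csr_matrix((data, (rows, cols)), shape=(ne, ne))
        return self._A_raw

    @property
    def lu(self):
        if self._lu is None:
            self._lu = spla.splu(self.A)
        return self._lu

    def with_rhs(self, f: np.ndarray) -> "VelocitySystem":
        """Same matrix (and factorization), new forces."""
        fc = f.copy()
        fc[self.constrained] = 0.0
        sys = VelocitySystem(self.A, fc, self.constrained, self.raw_coo, f)
        sys._lu = self._lu
        sys._A_raw = self._A_raw
        return sys


def assemble_velocity_system(state: NetworkState, overlaps: OverlapSet,
                             forces: np.ndarray,
                             constrained: Optional[np.ndarray] = None,
                             ) -> VelocitySystem:
    """Build the sparse drag matrix and right-hand side.

    ``forces`` is the (2N, 2) total endpoint force; ``constrained`` a
    boolean mask over endpoints with prescribed zero velocity (their rows
    become identity with zero right-hand side).
    """
    n = state.n
    ne = 2 * n
    prm = state.params
    if constrained is None:
        constrained = np.zeros(ne, dtype=bool)

    rows = [np.arange(ne)]
    cols = [np.arange(ne)]
    data = [np.full(ne, prm.zeta * prm.L / 2.0)]

    if overlaps.k:
        xs = prm.xi * overlaps.s
        i, j = overlaps.i, overlaps.j
        epi, ebi = 2 * i, 2 * i + 1
        epj, ebj = 2 * j, 2 * j + 1
        # Row blocks: each endpoint row couples to the four endpoint
        # velocities of the pair through the centroid difference
        # (v_i - v_j)/2 with its apportionment weight.
        for erow, wrow, sign in (
            (epi, 1.0 - overlaps.lam_i, +1.0),
            (ebi, overlaps.lam_i, +1.0),
            (epj, 1.0 - overlaps.lam_j, -1.0),
            (ebj, overlaps.lam_j, -1.0),
        ):
            coef = 0.5 * xs * wrow * sign
            for ecol, csign in ((epi, +1.0), (ebi, +1.0), (epj, -1.0), (ebj, -1.0)):
                rows.append(erow)
                cols.append(ecol)
                data.append(coef * csign)

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)

    if constrained.any():
        keep = ~constrained[rows]
        rows_c = np.concatenate([rows[keep], np.flatnonzero(constrained)])
        cols_c = np.concatenate([cols[keep], np.flatnonzero(constrained)])
        data_c = np.concatenate([data[keep], np.ones(int(constrained.sum()))])
    else:
        rows_c, cols_c, data_c = rows, cols, data
    A = sp.csc_matrix((data_c, (rows_c, cols_c)), shape=(ne, ne))

    f = forces.copy()
    f[constrained] = 0.0
    return VelocitySystem(A, f, constrained, (rows, cols, data, ne), forces)


def solve_velocities(sys: VelocitySystem) -> np.ndarray:
    """Endpoint velocities, shape (2N, 2); constrained endpoints exactly 0.

    Uses a sparse LU factorization (cached on the system so the four RK4
    stages of a step share it) and verifies the relative residual.
    """
    xdot = sys.lu.solve(sys.f)
    fnorm = np.linalg.norm(sys.f)
    if fnorm > 0:
        res = np.linalg.norm(sys.A @ xdot - sys.f) / fnorm
        if not np.isfinite(res) or res > 1e3 * SOLVER_RTOL:
            from scipy.sparse.csgraph import connected_components

            ncomp, _ = connected_components(abs(sys.A) + abs(sys.A.T),
                                            directed=False)
            raise RuntimeError(
                f"velocity solve failed: relative residual {res:.3e} "
                f"(graph components: {ncomp})")
    xdot[sys.constrained] = 0.0
    return xdot


def constraint_forces(sys: VelocitySystem, xdot: np.ndarray) -> np.ndarray:
    """Reaction force on each constrained endpoint, shape (2N, 2).

    From the unconstrained force balance, the constraint supplies
    A_raw·xdot - f on pinned rows (zero elsewhere).
    """
    r = np.asarray(sys.A_raw @ xdot) - sys.f_raw
    r[~sys.constrained] = 0.0
    return r
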