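"""Hand-specified micro-networks and an independent dense solver.

``dense_oracle`` re-derives the overdamped force balance directly from the
model equations — centroid-velocity drag couplings apportioned by the
overlap fractions, endpoint solvent drag, piecewise elastic springs and
pointed-end motor force pairs — as straight loops over filaments and
overlaps, sharing no assembly code with the production sparse path.  It is
deliberately slow and caps at 50 filaments; its job is to catch
transcription errors in the production assembler.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mechanics import mu_of_gamma
from .network import ModelParams, NetworkState, OverlapSet

__all__ = ["MicroCase", "dense_oracle", "make_micro_suite"]

ORACLE_MAX_FILAMENTS = 50


@dataclass
class MicroCase:
    """A tiny network with optional external endpoint forces.

    The reference velocities are always recomputed by the dense oracle at
    test time, never stored.
    """

    name: str
    state: NetworkState
    f_ext: Optional[np.ndarray] = None
    pinned: Optional[np.ndarray] = None
    motor_pairs: dict = field(default_factory=dict)
    notes: str = ""


def dense_oracle(state: NetworkState, overlaps: OverlapSet,
                 f_ext: Optional[np.ndarray] = None,
                 pinned: Optional[np.ndarray] = None) -> np.ndarray:
    """Endpoint velocities from a dense direct transcription of the model.

    Builds the full (4N x 4N) drag matrix over the flattened coordinate
    vector [p0x, p0y, b0x, b0y, ...] one scalar equation at a time, then
    solves it with a dense solver.
    """
    n = state.n
    if n > ORACLE_MAX_FILAMENTS:
        raise ValueError("dense oracle caps at 50 filaments")
    prm = state.params
    dim = 4 * n
    A = np.zeros((dim, dim))
    f = np.zeros(dim)

    def slot(fil: int, endpoint: int, coord: int) -> int:
        # endpoint 0 = pointed, 1 = barbed
        return 4 * fil + 2 * endpoint + coord

    # solvent drag on each half-filament
    for i in range(n):
        for e in range(2):
            for c in range(2):
                A[slot(i, e, c), slot(i, e, c)] += prm.zeta * prm.L / 2.0

    # crosslink drag: -xi*(v_i - v_j) on filament i at each shared overlap,
    # apportioned (1-lam) to the pointed and lam to the barbed end, with
    # centroid velocities v = (v_p + v_b)/2.
    for k in range(overlaps.k):
        i, j = int(overlaps.i[k]), int(overlaps.j[k])
        li, lj = float(overlaps.lam_i[k]), float(overlaps.lam_j[k])
        xs = prm.xi * float(overlaps.s[k])
        for c in range(2):
            cols_i = [slot(i, 0, c), slot(i, 1, c)]
            cols_j = [slot(j, 0, c), slot(j, 1, c)]
            for (fil_rows, lam_row, sign) in ((i, li, 1.0), (j, lj, -1.0)):
                for e, w in ((0, 1.0 - lam_row), (1, lam_row)):
                    r = slot(fil_rows, e, c)
                    for col in cols_i:
                        A[r, col] += sign * xs * w * 0.5
                    for col in cols_j:
                        A[r, col] -= sign * xs * w * 0.5

    # elastic forces
    for i in range(n):
        d = state.b[i] - state.p[i]
        ell = float(np.hypot(d[0], d[1]))
        u = d / ell
        gamma = (ell - prm.L) / prm.L
        fp = float(mu_of_gamma(gamma, prm)) * gamma * u
        for c in range(2):
            f[slot(i, 0, c)] += fp[c]
            f[slot(i, 1, c)] -= fp[c]

    # motor force pairs at flagged overlaps
    for k in range(overlaps.k):
        if overlaps.q[k] == 0:
            continue
        i, j = int(overlaps.i[k]), int(overlaps.j[k])
        li, lj = float(overlaps.lam_i[k]), float(overlaps.lam_j[k])
        w = prm.upsilon * float(overlaps.s[k])
        di = state.b[i] - state.p[i]
        dj = state.b[j] - state.p[j]
        ui = di / np.hypot(di[0], di[1])
        uj = dj / np.hypot(dj[0], dj[1])
        pair_i = w * (uj - ui)
        for c in range(2):
            f[slot(i, 0, c)] += (1.0 - li) * pair_i[c]
            f[slot(i, 1, c)] += li * pair_i[c]
            f[slot(j, 0, c)] -= (1.0 - lj) * pair_i[c]
            f[slot(j, 1, c)] -= lj * pair_i[c]

    if f_ext is not None:
        # f_ext given in (2N, 2) endpoint layout
        for i in range(n):
            for e in range(2):
                for c in range(2):
                    f[slot(i, e, c)] += f_ext[2 * i + e, c]

    if pinned is not None:
        for idx in np.flatnonzero(pinned):
            fil, e = divmod(int(idx), 2)
            for c in range(2):
                r = slot(fil, e, c)
                A[r, :] = 0.0
                A[r, r] = 1.0
                f[r] = 0.0

    v = np.linalg.solve(A, f)
    out = np.empty((2 * n, 2))
    for i in range(n):
        for e in range(2):
            out[2 * i + e] = v[slot(i, e, 0)], v[slot(i, e, 1)]
    return out


def _two_filament_state(prm: ModelParams, offset=(0.0, 0.0), cross=True,
                        antiparallel=False) -> NetworkState:
    L = prm.L
    p1, b1 = np.array([0.0, 0.0]), np.array([L, 0.0])
    if cross:
        p2 = np.array([L / 2 + offset[0], -L / 2 + offset[1]])
        b2 = p2 + np.array([0.0, L])
    else:
        p2, b2 = np.array([0.0, 1.0]), np.array([L, 1.0])
    if antiparallel:
        p2, b2 = np.array([L, 0.5]), np.array([0.0, 0.5])
    return NetworkState(np.vstack([p1, p2]), np.vstack([b1, b2]), prm,
                        periodic_x=False, periodic_y=False)


def make_micro_suite(params: Optional[ModelParams] = None) -> list:
    """Deterministic micro-networks exercising every mechanics contract."""
    prm = params or ModelParams(D_x=20.0, D_y=20.0, L=4.0, l_c=1.0, phi=1.0)
    L = prm.L
    cases = []

    # 1. isolated filament under tension (stretched 10%)
    s1 = NetworkState(np.array([[0.0, 0.0]]), np.array([[1.1 * L, 0.0]]),
                      prm, periodic_x=False, periodic_y=False)
    cases.append(MicroCase("isolated_tension", s1,
                           notes="single stretched filament relaxing"))

    # 2. two crossing passive filaments with a relative pulling force
    s2 = _two_filament_state(prm)
    f2 = np.zeros((4, 2))
    f2[1, 0] = 2.0   # pull barbed end of filament 0
    f2[2, 0] = -2.0  # pull pointed end of filament 1
    cases.append(MicroCase("crossed_relative_force", s2, f_ext=f2,
                           motor_pairs={}, notes="passive drag transmission"))

    # 3. nearly antiparallel pair crossing at midpoints, one motor
    #    (sliding case; a slight tilt makes the crossing transversal)
    s3 = NetworkState(np.array([[0.0, 0.0], [L, 0.2]]),
                      np.array([[L, 0.0], [0.0, -0.2]]), prm,
                      periodic_x=False, periodic_y=False)
    cases.append(MicroCase("antiparallel_motor", s3, motor_pairs={(0, 1): 1},
                           notes="motor-driven sliding"))

    # 4. three-filament chain transmitting a tension
    p = np.array([[0.0, 0.1], [0.8 * L, -0.1], [1.6 * L, 0.1]])
    b = p + np.array([[L, 0.0]] * 3)
    b[0, 1] = -0.1
    b[1, 1] = 0.1
    b[2, 1] = -0.1
    s4 = NetworkState(p, b, prm, periodic_x=False, periodic_y=False)
    f4 = np.zeros((6, 2))
    f4[5, 0] = 1.0
    pin4 = np.zeros(6, dtype=bool)
    pin4[0] = True
    cases.append(MicroCase("chain_tension", s4, f_ext=f4, pinned=pin4,
                           notes="stress transmitted through a chain"))

    # 5. periodic-wrap overlap: crossing only through the y-image
    prm5 = prm
    p5 = np.array([[prm5.D_x / 2 - L / 2, 0.3], [prm5.D_x / 2, prm5.D_y - 0.3]])
    b5 = np.array([[prm5.D_x / 2 + L / 2, 0.3],
                   [prm5.D_x / 2, prm5.D_y - 0.3 + L]])
    s5 = NetworkState(p5, b5, prm5, periodic_x=False, periodic_y=True)
    s5.wrap()
    cases.append(MicroCase("periodic_wrap", s5,
                           notes="crossing through the periodic y seam"))

    return cases
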