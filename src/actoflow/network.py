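"""Domain types, mikado network generation and geometry queries.

The model is a quasi-2D cross-linked filament network: each actin filament
is a single oriented elastic segment with a pointed (-) end ``p`` and a
barbed (+) end ``b``.  Filaments are deposited "mikado" style (uniform
random midpoints and orientations) at the density needed to realise a mean
crosslink spacing ``l_c`` along each filament.  Crosslinking acts at every
filament crossing, so the network topology is the set of segment-segment
intersection points, recomputed as filaments move.

Units throughout the package: lengths in um, forces in pN, times in s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ModelParams",
    "Filament",
    "NetworkState",
    "Overlap",
    "OverlapSet",
    "generate_mikado",
    "length_density",
    "find_overlaps",
    "filament_strain",
]


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Physical and numerical constants of the model.

    Defaults are the biologically plausible reference values used throughout:
    stiff in extension (``mu_e``), soft in compression (``mu_c``, modelling
    buckling), crosslink molecular friction ``xi``, weak solvent drag
    ``zeta``, and motor stall force ``upsilon`` acting at a fraction ``phi``
    of filament crossings.

    Parameters
    ----------
    mu_e, mu_c : float
        Extensional / compressional spring constants (pN).  The restoring
        force on a filament with strain ``gamma`` is ``mu(gamma)*gamma``.
    xi : float
        Crosslink drag coefficient (pN s/um) coupling the centroid
        velocities of every pair of overlapping filaments.
    zeta : float
        Solvent drag coefficient (pN s/um^2); each endpoint carries drag
        ``zeta*L/2`` for its adjoining half-filament.
    L : float
        Filament rest length (um).
    l_c : float
        Mean crosslink spacing along a filament (um); sets network density.
    upsilon : float
        Motor stall force (pN) applied toward each filament's pointed end
        at motor-occupied crossings.
    phi : float
        Fraction of crossings carrying an active motor, in [0, 1].
    k_app : float
        Filament appearance rate (1/(um^2 s)).
    tau_r : float
        Filament turnover (mean lifetime) time in s; ``math.inf`` disables
        turnover.  The dissociation rate is ``1/tau_r``.
    tau_s : float
        Interval between turnover updates (s); must stay below
        ``0.01*tau_r`` so that each update recycles <1% of the network.
    D_x, D_y : float
        Domain size (um).
    seed : int
        Seed for the single per-run RNG stream.
    dt : float or None
        Integrator step (s); ``None`` selects a stability-limited default.
    eps_gamma : float
        Half-width of the linear blend between ``mu_c`` and ``mu_e`` around
        zero strain (smoothing mandate: no sharp discontinuities).
    eps_L_frac : float
        Crosslink capture margin at filament tips, as a fraction of ``L``.
        An established crossing persists as a crosslink until its
        intersection point slides this far past a filament tip, with the
        coupling fading linearly over the margin (a finite-size
        crosslinker keeps a fiber pair engaged slightly beyond the strict
        geometric crossing; numerically this removes binary contact
        flicker at tips).
    """

    mu_e: float = 100.0
    mu_c: float = 1.0
    xi: float = 100.0
    zeta: float = 0.05
    L: float = 5.0
    l_c: float = 0.5
    upsilon: float = 10.0
    phi: float = 0.5
    k_app: float = 0.0
    tau_r: float = math.inf
    tau_s: float = math.inf
    D_x: float = 50.0
    D_y: float = 20.0
    seed: int = 0
    dt: Optional[float] = None
    eps_gamma: float = 0.005
    eps_L_frac: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.mu_e >= self.mu_c > 0):
            raise ValueError("require mu_e >= mu_c > 0")
        for name in ("xi", "zeta", "L", "l_c", "D_x", "D_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")
        if self.k_app < 0:
            raise ValueError("k_app must be non-negative")
        if math.isfinite(self.tau_r):
            if self.tau_r <= 0:
                raise ValueError("tau_r must be positive")
            if not (self.tau_s < 0.01 * self.tau_r):
                raise ValueError("tau_s must be < 0.01*tau_r")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def eps_L(self) -> float:
        return self.eps_L_frac * self.L

    @property
    def n_filaments(self) -> int:
        """Mikado filament count 2*D_x*D_y/(L*l_c), rounded to nearest."""
        return int(round(2.0 * self.D_x * self.D_y / (self.L * self.l_c)))

    @property
    def rho_0(self) -> float:
        """Undeformed length density 2/l_c (um^-1)."""
        return 2.0 / self.l_c

    def with_turnover(self, tau_r: float, tau_s: Optional[float] = None) -> "ModelParams":
        """Copy of the parameters with turnover at lifetime ``tau_r``.

        The appearance rate is chosen so the equilibrium density matches
        the mikado density: k_app*tau_r*D_x*D_y = 2*D_x*D_y/(L*l_c).
        """
        if not math.isfinite(tau_r):
            return replace(self, tau_r=math.inf, tau_s=math.inf, k_app=0.0)
        if tau_s is None:
            tau_s = tau_r / 200.0
        k_app = 2.0 / (self.L * self.l_c * tau_r)
        return replace(self, tau_r=tau_r, tau_s=tau_s, k_app=k_app)


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class Filament:
    """Single oriented filament; convenience view used by micro-fixtures."""

    p: np.ndarray
    b: np.ndarray
    id: int = 0
    birth_time: float = 0.0

    @property
    def uhat(self) -> np.ndarray:
        d = self.b - self.p
        return d / np.linalg.norm(d)


@dataclass
class NetworkState:
    """Array-of-filaments network snapshot.

    ``p`` and ``b`` hold unwrapped endpoint coordinates, shape (N, 2); the
    minimum-image convention is applied in all geometry queries for the
    periodic dimensions, and whole filaments are re-centred into the domain
    by :func:`wrap` (a rigid translation by a lattice vector, so the
    geometry is unchanged).
    """

    p: np.ndarray
    b: np.ndarray
    params: ModelParams
    time: float = 0.0
    periodic_x: bool = False
    periodic_y: bool = True
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    birth: np.ndarray = field(default=None)  # type: ignore[assignment]
    next_id: int = 0

    def __post_init__(self) -> None:
        self.p = np.atleast_2d(np.asarray(self.p, dtype=float))
        self.b = np.atleast_2d(np.asarray(self.b, dtype=float))
        n = len(self.p)
        if self.ids is None:
            self.ids = np.arange(n, dtype=np.int64)
            self.next_id = n
        if self.birth is None:
            self.birth = np.full(n, self.time, dtype=float)

    # -- basic geometry -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.p)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.b - self.p, axis=1)

    @property
    def uhat(self) -> np.ndarray:
        d = self.b - self.p
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    @property
    def strain(self) -> np.ndarray:
        return filament_strain_arrays(self.p, self.b, self.params.L)

    @property
    def mid(self) -> np.ndarray:
        return 0.5 * (self.p + self.b)

    def filament(self, i: int) -> Filament:
        return Filament(self.p[i].copy(), self.b[i].copy(),
                        int(self.ids[i]), float(self.birth[i]))

    def copy(self) -> "NetworkState":
        return NetworkState(self.p.copy(), self.b.copy(), self.params,
                            self.time, self.periodic_x, self.periodic_y,
                            self.ids.copy(), self.birth.copy(), self.next_id)

    def wrap(self) -> None:
        """Translate whole filaments by lattice vectors so midpoints lie in
        the domain (periodic dimensions only)."""
        mid = self.mid
        box = (self.params.D_x, self.params.D_y)
        for axis, per in enumerate((self.periodic_x, self.periodic_y)):
            if per:
                shift = np.floor(mid[:, axis] / box[axis]) * box[axis]
                self.p[:, axis] -= shift
                self.b[:, axis] -= shift

    def to_table(self):
        """One row per filament: id, px, py, bx, by, birth_time."""
        import pandas as pd

        return pd.DataFrame({
            "id": self.ids,
            "px": self.p[:, 0], "py": self.p[:, 1],
            "bx": self.b[:, 0], "by": self.b[:, 1],
            "birth_time": self.birth,
        })


@dataclass
class Overlap:
    """A single filament-filament crossing (one record per unordered pair)."""

    i: int
    j: int
    x_ij: np.ndarray
    lambda_i: float
    lambda_j: float
    q_ij: int = 0


@dataclass
class OverlapSet:
    """Current crossings with apportionment fractions and motor flags.

    Arrays are parallel over the K crossings; ``i``/``j`` index into the
    state arrays.  ``s`` is the crosslink engagement factor in [0, 1]
    (product of the two tip ramps) that smooths overlap appearance and
    disappearance at filament tips.  ``motor_assignments`` maps persistent
    id pairs to their Bernoulli(phi) motor flag so a pair keeps its flag for
    as long as the crossing persists.
    """

    i: np.ndarray
    j: np.ndarray
    x: np.ndarray
    lam_i: np.ndarray
    lam_j: np.ndarray
    q: np.ndarray
    s: np.ndarray
    #: sorted packed id-pair keys and their motor flags (persistence store)
    pair_keys: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    pair_q: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def k(self) -> int:
        return len(self.i)

    @property
    def motor_assignments(self) -> dict:
        """Persistent (id_lo, id_hi) -> q map (built on demand)."""
        return {(int(k >> 32), int(k & 0xFFFFFFFF)): float(q)
                for k, q in zip(self.pair_keys, self.pair_q)}

    def counts(self, n: int) -> np.ndarray:
        """Number of crossings per filament."""
        c = np.bincount(self.i, minlength=n) + np.bincount(self.j, minlength=n)
        return c

    def overlaps(self) -> list:
        return [Overlap(int(self.i[k]), int(self.j[k]), self.x[k].copy(),
                        float(self.lam_i[k]), float(self.lam_j[k]),
                        int(self.q[k])) for k in range(self.k)]


def empty_overlap_set() -> OverlapSet:
    z = np.zeros(0)
    return OverlapSet(z.astype(np.int64), z.astype(np.int64),
                      np.zeros((0, 2)), z, z, z, z)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filament_strain(f, L: float) -> float:
    """Strain gamma = (|b - p| - L)/L of a single filament (negative under
    compression)."""
    if L <= 0:
        raise ValueError("L must be positive")
    ell = float(np.linalg.norm(np.asarray(f.b, float) - np.asarray(f.p, float)))
    if ell <= 0:
        raise ValueError("degenerate filament: |b - p| = 0")
    return (ell - L) / L


def filament_strain_arrays(p: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    return (np.linalg.norm(b - p, axis=1) - L) / L


def generate_mikado(params: ModelParams,
                    region: Optional[tuple] = None,
                    rng: Optional[np.random.Generator] = None,
                    periodic_x: bool = False,
                    periodic_y: bool = True,
                    n_override: Optional[int] = None) -> NetworkState:
    """Deposit N = round(2*D_x*D_y/(L*l_c)) unstrained filaments.

    Midpoints are uniform in ``region`` (default the full domain) and
    orientations uniform in [0, 2pi).  Reproducible from ``rng`` (or
    ``params.seed`` when no generator is supplied).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if region is None:
        region = (0.0, 0.0, params.D_x, params.D_y)
    x0, y0, x1, y1 = region
    if (x1 - x0) < params.L and not periodic_x:
        raise ValueError("region narrower than filament length L in x "
                         "(non-periodic dimension)")
    if (y1 - y0) < params.L and not periodic_y:
        raise ValueError("region narrower than filament length L in y "
                         "(non-periodic dimension)")
    area = (x1 - x0) * (y1 - y0)
    if n_override is not None:
        n = int(n_override)
    else:
        n = int(round(2.0 * area / (params.L * params.l_c)))
    mid = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    half = 0.5 * params.L * np.column_stack([np.cos(theta), np.sin(theta)])
    state = NetworkState(mid - half, mid + half, params,
                         periodic_x=periodic_x, periodic_y=periodic_y)
    state.wrap()
    return state


def length_density(state: NetworkState) -> float:
    """Total filament length per unit domain area (um/um^2); approximately
    2/l_c for a freshly generated network."""
    if state.n == 0:
        return 0.0
    return float(state.lengths.sum() / (state.params.D_x * state.params.D_y))


def _min_image(d: np.ndarray, state: NetworkState) -> np.ndarray:
    """Minimum-image displacement for the active periodic dimensions."""
    d = d.copy()
    box = (state.params.D_x, state.params.D_y)
    for axis, per in enumerate((state.periodic_x, state.periodic_y)):
        if per:
            d[:, axis] -= box[axis] * np.round(d[:, axis] / box[axis])
    return d


def _candidate_pairs(state: NetworkState, radius: float) -> np.ndarray:
    """Midpoint pairs closer than ``radius`` under the minimum image."""
    mid = state.mid.copy()
    box = [state.params.D_x if state.periodic_x else 0.0,
           state.params.D_y if state.periodic_y else 0.0]
    # cKDTree requires a full toroidal box; emulate mixed periodicity by
    # giving non-periodic dimensions a box large enough to never wrap.
    boxsize = np.empty(2)
    for axis in range(2):
        if box[axis] > 0:
            mid[:, axis] = np.mod(mid[:, axis], box[axis])
            boxsize[axis] = box[axis]
        else:
            lo = mid[:, axis].min() - 2.0 * radius
            mid[:, axis] -= lo
            boxsize[axis] = mid[:, axis].max() + 4.0 * radius
    tree = cKDTree(mid, boxsize=boxsize)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    return pairs


def find_overlaps(state: NetworkState,
                  previous: Optional[OverlapSet] = None,
                  rng: Optional[np.random.Generator] = None,
                  phi_field: Optional[Callable[[np.ndarray], np.ndarray]] = None,
                  ) -> OverlapSet:
    """Locate all segment-segment crossings and refresh motor flags.

    Intersections are exact (solved pairwise from the segment parametric
    equations) under the minimum-image convention for periodic dimensions.
    Motor flags of persisting id pairs are preserved; new pairs draw
    ``q ~ Bernoulli(phi)`` with ``phi`` evaluated at the crossing point when
    a ``phi_field`` is given, else the uniform ``params.phi``.
    """
    n = state.n
    if n < 2:
        return empty_overlap_set()
    if rng is None:
        rng = np.random.default_rng(state.params.seed + 1)
    prev_keys = previous.pair_keys if previous is not None else np.zeros(0, np.int64)
    prev_q = previous.pair_q if previous is not None else np.zeros(0)

    h = max(state.params.eps_L_frac, 1e-12)  # capture margin (fraction)
    lengths = state.lengths
    radius = float(lengths.max()) * (1.0 + 2.0 * h) + 1e-12
    pairs = _candidate_pairs(state, radius)
    if len(pairs) == 0:
        return empty_overlap_set()
    ii, jj = pairs[:, 0], pairs[:, 1]

    # Shift filament j so its midpoint is the nearest image of filament i's.
    dmid = state.mid[jj] - state.mid[ii]
    shift = _min_image(dmid, state) - dmid
    pi, bi = state.p[ii], state.b[ii]
    pj, bj = state.p[jj] + shift, state.b[jj] + shift
    di, dj = bi - pi, bj - pj

    denom = di[:, 0] * dj[:, 1] - di[:, 1] * dj[:, 0]
    ok = np.abs(denom) > 1e-12
    rel = pj - pi
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[:, 0] * dj[:, 1] - rel[:, 1] * dj[:, 0]) / denom
        u = (rel[:, 0] * di[:, 1] - rel[:, 1] * di[:, 0]) / denom
    strict = ok & (t >= 0.0) & (t <= 1.0) & (u >= 0.0) & (u <= 1.0)
    gi_all, gj_all = state.ids[ii], state.ids[jj]
    keys_all = (np.minimum(gi_all, gj_all).astype(np.int64) << 32) \
        + np.maximum(gi_all, gj_all).astype(np.int64)
    if len(prev_keys):
        # established pairs stay engaged while the crossing point lies
        # within the capture margin beyond a tip
        pos = np.searchsorted(prev_keys, keys_all)
        pos_c = np.minimum(pos, len(prev_keys) - 1)
        known = prev_keys[pos_c] == keys_all
        within = ok & (t >= -h) & (t <= 1.0 + h) & (u >= -h) & (u <= 1.0 + h)
        ok = strict | (known & within)
    else:
        known = np.zeros(len(ii), dtype=bool)
        ok = strict
    if not ok.any():
        return empty_overlap_set()

    ii, jj, t, u = ii[ok], jj[ok], t[ok], u[ok]
    keys = keys_all[ok]
    known = known[ok]
    # engagement fades linearly over the capture margin beyond each tip;
    # crossings in the filament interior are fully engaged
    margin_i = np.minimum(t, 1.0 - t)
    margin_j = np.minimum(u, 1.0 - u)
    s = np.clip((margin_i + h) / (1.1 * h), 0.0, 1.0) * \
        np.clip((margin_j + h) / (1.1 * h), 0.0, 1.0)
    t = np.clip(t, 0.0, 1.0)
    u = np.clip(u, 0.0, 1.0)
    x = state.p[ii] + t[:, None] * (state.b[ii] - state.p[ii])

    # Motor flags: persist per id pair, redraw on (re)formation.
    if phi_field is not None:
        xw = x.copy()
        if state.periodic_x:
            xw[:, 0] = np.mod(xw[:, 0], state.params.D_x)
        phis = np.asarray(phi_field(xw[:, 0]), dtype=float)
    else:
        phis = np.full(len(ii), state.params.phi)
    fresh = (rng.random(len(ii)) < phis).astype(float)
    q = fresh
    if len(prev_keys) and known.any():
        pos = np.minimum(np.searchsorted(prev_keys, keys[known]),
                         len(prev_keys) - 1)
        q = fresh.copy()
        q[known] = prev_q[pos]

    order = np.argsort(keys, kind="stable")
    return OverlapSet(ii.astype(np.int64), jj.astype(np.int64), x,
                      t, u, q, s, keys[order], q[order])
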