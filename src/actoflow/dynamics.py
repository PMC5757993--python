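"""Time integration and stochastic filament turnover.

The endpoint positions follow the overdamped system A·ẋ = f(x), integrated
with classical RK4.  The overlap topology (sparsity pattern of A, the
apportionment fractions and motor flags) is frozen during the four stages
of a step and refreshed between steps; elastic and motor force directions
are re-evaluated at each stage from the stage positions.

Two numerical safeguards keep the explicit scheme both accurate and
affordable:

* a displacement guard rejects any step whose largest endpoint displacement
  exceeds ``0.1*l_c`` and halves dt (with gentle regrowth after a run of
  accepted steps);
* filaments with no (effective) crosslink engagement are advanced by the
  exact solution of their decoupled linear dynamics instead of RK4.  Their
  spring relaxes against bare solvent drag on the timescale zeta*L^2/(4*mu),
  by far the stiffest mode of the system; integrating it exactly lets the
  coupled network run at the much larger step its own dynamics allows.

Whole-filament turnover removes a fraction tau_s/tau_r of filaments every
tau_s of simulated time and inserts k_app*tau_s*D_x*D_y new unstrained ones
at uniform random positions in the original domain, with stochastic
rounding of both counts so the expected rates are exact for any tau_s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import measure
from .mechanics import (assemble_velocity_system, elastic_forces,
                        motor_forces, mu_of_gamma, solve_velocities)
from .network import (ModelParams, NetworkState, OverlapSet, empty_overlap_set,
                      find_overlaps, generate_mikado)
from .scenarios import Scenario

__all__ = ["TurnoverSchedule", "Trajectory", "StepInfo",
           "rk4_step", "turnover_step", "run_simulation"]

#: Displacement guard: reject a step moving any endpoint further than this
#: fraction of l_c.
GUARD_FRAC = 0.1

#: Overlaps with xi*s below this multiple of the solvent drag zeta*L are
#: dropped for the step (negligible coupling; removes near-isolated stiff
#: modes from the explicit integrator).
WEAK_DRAG_FRAC = 0.1


@dataclass
class TurnoverSchedule:
    """Whole-filament turnover rates: lifetime tau_r, update interval tau_s
    (< 0.01*tau_r) and appearance rate k_app per unit area."""

    tau_r: float = math.inf
    tau_s: float = math.inf
    k_app: float = 0.0

    def __post_init__(self) -> None:
        if math.isfinite(self.tau_r) and not (self.tau_s < 0.01 * self.tau_r):
            raise ValueError("tau_s must be < 0.01*tau_r")

    @classmethod
    def from_params(cls, params: ModelParams) -> "TurnoverSchedule":
        return cls(params.tau_r, params.tau_s, params.k_app)

    @property
    def active(self) -> bool:
        return math.isfinite(self.tau_r)


@dataclass
class StepInfo:
    """Diagnostics from one attempted RK4 step."""

    accepted: bool
    max_disp: float
    v0: Optional[np.ndarray] = None  # stage-1 endpoint velocities (2N, 2)


@dataclass
class Trajectory:
    """Frame-indexed measurement records plus run metadata."""

    frames: "object"  # pandas DataFrame
    params: ModelParams
    scenario: Scenario
    seed: int
    events: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)

    def save(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.frames.to_csv(out / "frames.csv", index=False)
        if self.snapshots:
            import pandas as pd

            rows = []
            for t, p, b in self.snapshots:
                for k in range(len(p)):
                    rows.append((t, k, p[k, 0], p[k, 1], b[k, 0], b[k, 1]))
            pd.DataFrame(rows, columns=["time", "filament", "px", "py",
                                        "bx", "by"]).to_csv(
                out / "snapshots.csv", index=False)
        manifest = {
            "seed": self.seed,
            "scenario": self.scenario.kind,
            "applied_stress": self.scenario.applied_stress,
            "events": [{"time": t, "event": e} for t, e in self.events],
            "params": {k: (v if v is None or isinstance(v, (int, str))
                           else (None if isinstance(v, float) and not math.isfinite(v)
                                 else v))
                       for k, v in vars(self.params).items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# RK4 step
# ---------------------------------------------------------------------------

def _retained(overlaps: OverlapSet, params: ModelParams) -> OverlapSet:
    """Drop overlaps whose engaged drag is negligible next to solvent drag."""
    if overlaps.k == 0:
        return overlaps
    keep = params.xi * overlaps.s >= WEAK_DRAG_FRAC * params.zeta * params.L
    if keep.all():
        return overlaps
    return OverlapSet(overlaps.i[keep], overlaps.j[keep], overlaps.x[keep],
                      overlaps.lam_i[keep], overlaps.lam_j[keep],
                      overlaps.q[keep], overlaps.s[keep],
                      overlaps.pair_keys, overlaps.pair_q)


def _advance_isolated(X: np.ndarray, fil_idx: np.ndarray, fext: np.ndarray,
                      pinned: np.ndarray, params: ModelParams,
                      dt: float) -> None:
    """Exact update of decoupled filaments (in place on the (2N,2) array X).

    Each such filament sees only its own spring, solvent drag and any
    frozen external endpoint forces: a linear ODE whose axial strain
    relaxes exponentially toward the force-balanced value while the
    centroid drifts and the perpendicular force difference rotates it.
    """
    L, zeta = params.L, params.zeta
    for i in fil_idx:
        ep, eb = 2 * i, 2 * i + 1
        pp, pb = bool(pinned[ep]), bool(pinned[eb])
        if pp and pb:
            continue
        p, b = X[ep], X[eb]
        r = b - p
        ell = float(np.hypot(r[0], r[1]))
        u = r / ell
        gamma = (ell - L) / L
        fp, fb = fext[ep], fext[eb]
        if not pp and not pb:
            mu = float(mu_of_gamma(gamma, params))
            dF = fb - fp
            dF_ax = float(dF @ u)
            gstar = dF_ax / (2.0 * mu)
            rate = 4.0 * mu / (zeta * L * L)
            gnew = gstar + (gamma - gstar) * math.exp(-rate * dt)
            v_perp = 2.0 * (dF - dF_ax * u) / (zeta * L)
            vec = (1.0 + gnew) * L * u + dt * v_perp
            vec *= (1.0 + gnew) * L / float(np.hypot(vec[0], vec[1]))
            mid = 0.5 * (p + b) + dt * (fp + fb) / (zeta * L)
            X[ep] = mid - 0.5 * vec
            X[eb] = mid + 0.5 * vec
        else:
            # one end pinned: the free end relaxes toward it
            if pb:
                anchor, free_e, sign = X[eb].copy(), ep, -1.0
                f_free = fp
            else:
                anchor, free_e, sign = X[ep].copy(), eb, +1.0
                f_free = fb
            mu = float(mu_of_gamma(gamma, params))
            f_ax = float(f_free @ (sign * u))
            gstar = f_ax / mu
            rate = 2.0 * mu / (zeta * L * L)
            gnew = gstar + (gamma - gstar) * math.exp(-rate * dt)
            v_perp = (f_free - float(f_free @ u) * u) / (zeta * L / 2.0)
            vec = sign * u * (1.0 + gnew) * L + dt * v_perp
            vec *= (1.0 + gnew) * L / float(np.hypot(vec[0], vec[1]))
            X[free_e] = anchor + vec


def _stage_forces(state: NetworkState, overlaps: OverlapSet, X: np.ndarray,
                  fext: np.ndarray) -> np.ndarray:
    p, b = X[0::2], X[1::2]
    f = elastic_forces(state, p, b)
    f += motor_forces(state, overlaps, p, b)
    f += fext
    return f


def rk4_step(state: NetworkState, dt: float, scenario: Scenario,
             overlaps: Optional[OverlapSet] = None,
             rng: Optional[np.random.Generator] = None,
             ) -> tuple[NetworkState, StepInfo]:
    """One classical RK4 step of length dt with frozen topology.

    Returns the advanced state and step diagnostics; if the displacement
    guard trips, ``info.accepted`` is False and the input state is returned
    unchanged (the caller halves dt and retries).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    prm = state.params
    if overlaps is None:
        overlaps = find_overlaps(state, None, rng, scenario.phi_field(prm))
    ov = _retained(overlaps, prm)

    pinned, fext = scenario.boundary(state, ov)
    counts = ov.counts(state.n)
    isolated = counts == 0
    iso_ep = np.repeat(isolated, 2)

    X0 = np.empty((2 * state.n, 2))
    X0[0::2], X0[1::2] = state.p, state.b

    frozen = pinned | iso_ep
    sys0 = assemble_velocity_system(state, ov, _stage_forces(state, ov, X0, fext),
                                    constrained=frozen)
    k1 = solve_velocities(sys0)
    k2 = solve_velocities(sys0.with_rhs(
        _stage_forces(state, ov, X0 + 0.5 * dt * k1, fext)))
    k3 = solve_velocities(sys0.with_rhs(
        _stage_forces(state, ov, X0 + 0.5 * dt * k2, fext)))
    k4 = solve_velocities(sys0.with_rhs(
        _stage_forces(state, ov, X0 + dt * k3, fext)))

    X1 = X0 + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    disp = np.linalg.norm(X1 - X0, axis=1)
    max_disp = float(disp.max()) if len(disp) else 0.0
    if not np.isfinite(max_disp) or max_disp > GUARD_FRAC * prm.l_c:
        return state, StepInfo(False, max_disp)

    if isolated.any():
        _advance_isolated(X1, np.flatnonzero(isolated), fext, pinned, prm, dt)

    new = state.copy()
    new.p, new.b = X1[0::2].copy(), X1[1::2].copy()
    new.time = state.time + dt
    new.wrap()
    return new, StepInfo(True, max_disp, v0=k1)


# ---------------------------------------------------------------------------
# Turnover
# ---------------------------------------------------------------------------

def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    base = int(math.floor(x))
    return base + (1 if rng.random() < (x - base) else 0)


def turnover_step(state: NetworkState, sched: Optional[TurnoverSchedule] = None,
                  rng: Optional[np.random.Generator] = None,
                  elapsed: Optional[float] = None) -> NetworkState:
    """Remove a random fraction elapsed/tau_r of filaments and insert
    k_app*elapsed*D_x*D_y fresh unstrained ones (``elapsed`` defaults to
    tau_s).  Counts use stochastic rounding so expectations are exact."""
    if sched is None:
        sched = TurnoverSchedule.from_params(state.params)
    if not sched.active:
        return state
    if rng is None:
        rng = np.random.default_rng(state.params.seed + 2)
    if elapsed is None:
        elapsed = sched.tau_s
    prm = state.params

    n_rem = min(_stochastic_round(state.n * elapsed / sched.tau_r, rng), state.n)
    keep = np.ones(state.n, dtype=bool)
    if n_rem > 0:
        keep[rng.choice(state.n, size=n_rem, replace=False)] = False

    n_app = _stochastic_round(sched.k_app * elapsed * prm.D_x * prm.D_y, rng)
    mid = np.column_stack([rng.uniform(0.0, prm.D_x, n_app),
                           rng.uniform(0.0, prm.D_y, n_app)])
    theta = rng.uniform(0.0, 2.0 * np.pi, n_app)
    half = 0.5 * prm.L * np.column_stack([np.cos(theta), np.sin(theta)])

    new = state.copy()
    new.p = np.vstack([state.p[keep], mid - half])
    new.b = np.vstack([state.b[keep], mid + half])
    new.ids = np.concatenate([state.ids[keep],
                              np.arange(state.next_id, state.next_id + n_app)])
    new.birth = np.concatenate([state.birth[keep],
                                np.full(n_app, state.time)])
    new.next_id = state.next_id + n_app
    return new


# ---------------------------------------------------------------------------
# Run loop
# ---------------------------------------------------------------------------

def default_dt_max(params: ModelParams) -> float:
    """Largest step the stiffest mode tolerates under RK4.

    Crosslink drag couples filament *centroid* velocities, so the internal
    stretch mode of every filament is damped by solvent drag alone: its
    relaxation rate is 4*mu_e/(zeta*L^2) regardless of connectivity.
    0.6*zeta*L^2/mu_e puts lambda*dt at 2.4, inside the RK4 real-axis
    stability boundary (2.79) with margin.
    """
    return 0.6 * params.zeta * params.L ** 2 / params.mu_e


def run_simulation(params: ModelParams, scenario: Scenario, t_end: float,
                   frame_dt: Optional[float] = None,
                   record_snapshots: bool = False,
                   overlap_refresh_disp: Optional[float] = None,
                   state: Optional[NetworkState] = None,
                   ) -> Trajectory:
    """Integrate a network under the given scenario up to ``t_end``.

    One RNG stream (seeded from ``params.seed``) drives all stochastic
    draws, so identical configurations give bit-identical trajectories.
    Frames (measurement records) are appended every ``frame_dt`` of
    simulated time (default t_end/200).  ``overlap_refresh_disp`` sets the
    accumulated-displacement threshold for recomputing the crossing
    topology; the default refreshes every step.
    """
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    sched = TurnoverSchedule.from_params(params)
    phi_field = scenario.phi_field(params)

    if state is None:
        state = generate_mikado(params, rng=rng,
                                periodic_x=scenario.periodic_x,
                                periodic_y=scenario.periodic_y)
    if scenario.kind == "uniaxial" and scenario.applied_stress > 0:
        scenario.boundary(state)  # validates non-empty forcing region

    dt_max = params.dt if params.dt is not None else default_dt_max(params)
    if frame_dt is None:
        frame_dt = t_end / 200.0 if t_end > 0 else 1.0
    if sched.active:
        dt_max = min(dt_max, sched.tau_s)
    dt = dt_max / 8.0

    overlaps = find_overlaps(state, None, rng, phi_field)
    records = []
    events = []
    snapshots = []
    ref_scale = measure.reference_scale(state, scenario)
    cum_strain = 0.0
    prev_rate = None
    prev_t = state.time
    percolated = True
    spans_fail_streak = 0
    spans_fail_t = None
    next_frame = state.time
    since_turnover = 0.0
    since_refresh = 0.0
    streak = 0
    rejects = 0

    def record(v0):
        nonlocal cum_strain, prev_rate, prev_t, percolated
        nonlocal spans_fail_streak, spans_fail_t
        rec = measure.record_frame(state, overlaps, v0, scenario,
                                   ref_scale=ref_scale)
        rate = rec["strain_rate"]
        if prev_rate is not None:
            cum_strain += 0.5 * (rate + prev_rate) * (state.time - prev_t)
        prev_rate, prev_t = rate, state.time
        rec["cumulative_strain"] = cum_strain
        records.append(rec)
        if record_snapshots:
            snapshots.append((state.time, state.p.copy(), state.b.copy()))
        if scenario.kind == "uniaxial" and percolated:
            # spanning through marginal contacts flickers; only a
            # persistent loss (3 consecutive frames) counts as an event
            if not measure.spans_axis(state, overlaps):
                if spans_fail_streak == 0:
                    spans_fail_t = state.time
                spans_fail_streak += 1
                if spans_fail_streak >= 3:
                    events.append((spans_fail_t, "percolation_lost"))
                    percolated = False
            else:
                spans_fail_streak = 0

    # initial frame (stage-1 velocities of the current state)
    ov0 = _retained(overlaps, params)
    pinned0, fext0 = scenario.boundary(state, ov0)
    X0 = np.empty((2 * state.n, 2))
    X0[0::2], X0[1::2] = state.p, state.b
    iso0 = np.repeat(ov0.counts(state.n) == 0, 2)
    sys0 = assemble_velocity_system(state, ov0,
                                    _stage_forces(state, ov0, X0, fext0),
                                    constrained=pinned0 | iso0)
    last_v0 = solve_velocities(sys0)
    record(last_v0)
    next_frame += frame_dt

    while state.time < t_end - 1e-12:
        dt = min(dt, t_end - state.time)
        new, info = rk4_step(state, dt, scenario, overlaps, rng)
        if not info.accepted:
            dt *= 0.5
            streak = 0
            rejects += 1
            if dt < dt_max * 2.0 ** -30:
                raise RuntimeError(
                    f"step size collapsed at t={state.time:.4g} "
                    f"(max_disp={info.max_disp:.3g})")
            continue
        state = new
        last_v0 = info.v0
        streak += 1
        since_turnover += dt
        since_refresh += info.max_disp
        if streak >= 8 and dt < dt_max:
            dt = min(1.3 * dt, dt_max)
            streak = 0

        if sched.active and since_turnover >= sched.tau_s:
            state = turnover_step(state, sched, rng, elapsed=since_turnover)
            since_turnover = 0.0
            overlaps = find_overlaps(state, overlaps, rng, phi_field)
            since_refresh = 0.0
        elif overlap_refresh_disp is None or since_refresh >= overlap_refresh_disp:
            overlaps = find_overlaps(state, overlaps, rng, phi_field)
            since_refresh = 0.0

        if state.time >= next_frame - 1e-12:
            record(info.v0)
            while next_frame <= state.time + 1e-12:
                next_frame += frame_dt

    if records and records[-1]["time"] < state.time - 1e-9:
        record(last_v0 if last_v0 is not None and len(last_v0) == 2 * state.n
               else np.zeros((2 * state.n, 2)))

    frames = pd.DataFrame(records)
    return Trajectory(frames, params, scenario, params.seed,
                      events=events, snapshots=snapshots)
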