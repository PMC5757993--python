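# Methods

## Model

`actoflow` simulates a quasi-2D cross-linked actomyosin network as a
collection of N single-segment filaments in a rectangular domain
D_x × D_y. Filament i is an oriented linear spring with rest length L,
pointed-end position **p**_i and barbed-end position **b**_i; its strain is
γ_i = (|**b**_i − **p**_i| − L)/L and û_i points from the pointed toward
the barbed end.

Four ingredients make up the mechanics:

1. **Asymmetric compliance.** The elastic force on the pointed end is
   μ(γ)·γ·û with the reaction on the barbed end. μ = μ_e under extension
   and μ = μ_c ≪ μ_e under compression (a piecewise-linear stand-in for
   buckling), blended linearly over |γ| < ε_γ (default 0.005) so the
   force law has no kink at zero strain.

2. **Crosslink molecular friction.** Every filament crossing acts as an
   effective crosslink that resists relative motion of the pair with a
   drag force −ξ(v̄_i − v̄_j) built from the filament centroid velocities,
   apportioned to the endpoints of each filament by the fractional
   position λ of the crossing (1−λ to the pointed end, λ to the barbed
   end). This coarse-grains many transiently binding crosslinkers into a
   single friction coefficient ξ.

3. **Dispersed motor activity.** A fraction φ of crossings carries a
   motor. A motor-occupied crossing applies a force of magnitude υ on
   each filament of the pair toward that filament's own pointed end
   (υ(û_j − û_i) on filament i), apportioned to endpoints by the same
   (1−λ, λ) rule. Motor flags are drawn once per filament pair
   (Bernoulli with the local φ) and persist while the crossing persists;
   a pair that separates and re-forms redraws its flag.

4. **Whole-filament turnover.** Every τ_s of simulated time a random
   fraction τ_s/τ_r of filaments is removed and k_app·τ_s·D_x·D_y fresh
   unstrained filaments appear uniformly in the original domain
   (stochastic rounding keeps both expectations exact for any τ_s). With
   no deformation the filament count equilibrates to k_app·τ_r·D_x·D_y
   with time constant τ_r.

Inertia is neglected: endpoint velocities solve the force balance
A·ẋ = f(x), where A contains the solvent drag ζL/2 on every endpoint plus
the crosslink couplings, and f the elastic, motor and boundary forces.
A is assembled sparsely once per time step (one 2N×2N scalar matrix shared
by the x and y components), LU-factorized, and reused across the four
stages of a classical RK4 step; elastic and motor force directions are
re-evaluated at each stage from the stage positions while the crossing
topology, apportionment fractions and motor flags stay frozen within the
step.

### Reference parameters

Defaults (the "reference" cell-like scale, units pN, µm, s): μ_e = 100,
μ_c = 1, ξ = 100, ζ = 0.05, L = 5, l_c = 0.5, υ = 10, φ = 0.5 (the
plausible range is 0.1–0.9), D_x × D_y = 50 × 20. Networks are seeded
mikado-style: N = round(2·D_x·D_y/(L·l_c)) filaments with uniform random
midpoints and orientations, giving length density 2/l_c.

### Crosslink capture margin

A binary in/out test for crossings makes contacts near filament tips
flicker: a near-tangent pair can gain and lose its crossing with
nanometre-scale motion, which both injects force noise and — in sparse
networks near the connectivity threshold — dissolves the load-bearing
cluster unphysically. We therefore give crosslinks a small capture
margin h (default 0.05·L, the scale of a real crosslinker such as
α-actinin relative to the filament): an *established* crossing persists
until its intersection point slides a fraction h past a filament tip,
with the coupling fading linearly over the margin; *new* crossings still
require a strict geometric intersection. Interior crossings are fully
engaged.

### Time stepping

Crosslink friction couples centroid velocities only, so each filament's
internal stretch mode is damped by solvent drag alone, with relaxation
rate 4μ_e/(ζL²) regardless of connectivity — this is the stiffest mode of
the system. The default step is dt = 0.6·ζL²/μ_e (λ·dt ≈ 2.4, inside the
RK4 real-axis stability boundary of 2.79). Accuracy is enforced by a
displacement guard: a step that moves any endpoint further than 0.1·l_c
is rejected and dt is halved, with gentle regrowth (×1.3 after eight
accepted steps) back toward the cap. Filaments with no retained
crossings are advanced by the exact solution of their decoupled linear
dynamics instead of RK4, which removes the very stiffest configurations
from the explicit scheme without approximation. Overlaps whose engaged
drag is below 10% of the solvent drag are dropped for the step. The
sparse velocity solve is verified to a relative residual of 1e-10; an
independent dense transcription of the force balance (`oracles.py`)
cross-checks the production assembler in the test suite.

Runs with turnover additionally cap dt at 0.02·τ_r so a single turnover
update never recycles more than ~2% of the network.

## Scenarios

* **Uniaxial extension** — endpoints within 0.05·D_x of the left domain
  edge are velocity-pinned; a total rightward force σ·D_y is shared
  equally by endpoints in the forcing band at the right, with membership
  re-evaluated every step; periodic in y. Two protocol details matter at
  desk scale: the applied stress ramps up linearly over a configurable
  loading time (an impulsive start tears the sparsely connected forcing
  band off the network before any bulk flow develops), and the forcing
  band tracks the material right edge of the wall-connected cluster — the
  set of filaments in the same crossing-graph component as the pinned
  band — so that load is never fed to debris that has sheared off. For
  the sparse failure configuration (L = 1, l_c = 0.3) the bands are
  widened to 0.15·D_x; at that density a 0.33 µm band contains of order
  one wall-connected filament and cannot define a meaningful boundary.
* **Free contraction** — no constraints, no periodicity; the network
  strain rate is measured as (1/R)dR/dt of the filament centroid cloud.
* **Isometric contraction** — doubly periodic boundaries; the boundary
  stress is read from the internal stress profile.
* **Activity gradient** — doubly periodic; φ(x) is 0 in the left half and
  0.5 in the right half with linear ramps (width 0.05·D_x) at the midline
  and the periodic seam. Motor eligibility is evaluated at the crossing's
  position when its flag is drawn and is not re-evaluated as the crossing
  advects.

## Measurements

Stress is a force per unit length: σ(x) sums the axial component
μ(γ)γ|û·x̂| of filament tensions crossing the vertical line at x, divided
by D_y; extension counts positive, and the sign convention uses |û·x̂| so
σ is independent of filament orientation. The domain mean weights each
filament by its axial extent. Strain rate is the mean of per-filament
estimates (1/X)dX/dt relative to the reference boundary (uniaxial), or
the least-squares slope of centroid velocity against position (gradient
and isometric), measured in windows that exclude the constrained bands
and, for uniaxial runs, restricted to the load-bearing cluster.
Cumulative network strain is the trapezoidal time integral of the strain
rate; it deliberately differs from the mean filament strain whenever
filaments slide or turn over.

Derived rheology: the constant-rate (effectively viscous) window opens at
the last sustained crossing of the local log-log slope of cumulative
strain above n = 0.8; η = σ/(mean rate in the window) and τ_c is the
window onset. The elastic limit is the amplitude of the fast exponential
phase of a fit a(1−e^{−t/τ}) + ct, and G0 = σ/a. Scan protocols use the
noise-robust variants: the flow rate is the cumulative-strain increment
over a fixed late window (1.2–2.4 predicted transition times), the
elastic limit is the creep-corrected strain at mid-run, and the measured
transition time is their ratio η·γ_el/σ = η/G0. Trajectories are
truncated at a recorded persistent percolation-loss event before
rheology extraction, and spanning is only declared lost after three
consecutive failed frames (spanning through marginal contacts
flickers). For isometric runs the
stress trace is smoothed over ~5% of the run; σ_m is its maximum, τ_m the
first crossing of 80% of σ_m (a rise time, much more stable than the
argmax of a fluctuating plateau), and σ_ss the mean over the final
20–40%. Flow breakdown in extension runs is the first sustained
excursion of the smoothed rate beyond 2× (tearing/acceleration) or below
0.3× (arrest after loss of the percolating load path) of the window
reference; both signatures mark the dilution-driven loss of connectivity
and the cumulative strain at that event is the failure strain.

## Theory layer

Closed forms: η_c = C·ξ(L/l_c − 1)² with the geometry prefactor C held as
a module constant (default 4/π; all scaling tests probe the functional
form, not C), G0 = 2μ_e/l_c, τ_c = L²ξ/(l_c μ_e), and the empirical
active-stress scales σ_m ∼ μ_e υ/l_c, τ_m ∼ Lξ/(μ_e υ). Phenomenological
collapses: η = η_c/(1 + (τ_c/τ_r)^m) with m = 3/4 and
σ_ss = σ_m/((τ_r/τ_m)^n + τ_m/τ_r) with n = 1 (bracket in the
denominator — the only reading consistent with the linear rise below
τ_m, the peak at τ_r ≈ τ_m and the decay beyond). Steady gradient flow
composes the two: γ̇ = σ_ss/η, which in the fast-turnover regime
(τ_r < min(τ_m, τ_c)) reduces to γ̇ = (υ/ξL)·τ_r^{1/4}.

The coarse-grained density balance for uniaxial extension with turnover
is dρ/dt = (ρ_0 − ρ)/τ_r − ρ·σ/η(ρ) with η(ρ) from the viscosity formula
via l_c = 2/ρ. Its stable fixed point disappears at
τ_crit = max_ρ (ρ_0 − ρ)η(ρ)/(ρσ); below τ_crit density (and flow)
reaches a steady state, above it density runs away to the connectivity
floor ρ = 2/L. This closure is a reconstruction from the model's own
scaling relations and is tested qualitatively (existence of the
stability boundary, plateau-vs-collapse agreement with agent-based
runs), not quantitatively.

## Desk-scale study conditions

The reduced-scale protocols in `repro.py` (used by the test suite and
`scripts/acceptance.py`) choose domains of 10–16 µm and minutes-scale
wall time. Two systematic choices:

* **Raised solvent drag.** dt scales with ζ, and ζ only competes with
  the crosslink couplings through the body-drag fraction of the boundary
  load, which is kept below ~10% in every protocol. Runs therefore use
  ζ = 0.2–1 instead of 0.05.
* **Measured-timescale normalization.** Collapse scans normalize the
  turnover time by the system's own measured transition time η/G₀ and
  peak-stress rise time, not by the mean-field formulas: the measured
  transition time is an order of magnitude below the prediction (see
  Known limitations), and normalizing by the prediction would place the
  whole scan in the saturated branch.
* **Joint load/drag scaling for the failure protocol.** The model is
  invariant under joint scaling of (σ, ξ, time), so reducing ξ alone
  strengthens the boundary load relative to crosslink cohesion and
  shreds the sparse failure configuration. The failure protocol uses
  ξ = 300, σ = 0.5 and μ_e = 10 (μ_c kept at 1): load-to-drag ratios
  within ~30× of the reference, filament stretch on the serial load path
  kept small, and the measured observable — the strain at which
  sustained flow is lost — is a timescale-free, dilution-controlled
  quantity.

## What the generator does and does not emulate

Synthetic networks are ideal mikado systems: straight single-segment
filaments, no bending modes, no excluded volume, no thermal noise, exact
binary crosslinks at crossings with a single friction coefficient, and
spatially uniform turnover. Passing tests therefore demonstrate the
internal consistency of this model class at reduced scale — not, for
example, the behavior of semiflexible filaments with discrete crosslinker
kinetics.

## Known limitations

* Centroid-coupled friction (the literal reading of the drag law) leaves
  single-crossing filaments free to pivot and internal stretch modes
  undamped by crosslinks. Measured effective viscosities sit roughly an
  order of magnitude below the mean-field prediction, the measured
  transition times are correspondingly compressed (τ_c,eff = η/G0 of a
  few seconds at the reduced scale), and the dependence of the measured
  viscosity on the crosslink drag coefficient is markedly sublinear at
  desk scale — pivot- and churn-mediated creep short-circuits part of
  the crosslink dissipation. The active-stress scales σ_m and τ_m track
  their predicted parameter combinations well; the passive scaling
  exponents do not reach the mean-field values.
* Without turnover, isometric networks in this model retain a large
  residual stress (balanced extension/compression) instead of decaying
  toward zero; the slow-turnover branch of the steady-stress collapse is
  correspondingly much shallower than the idealized n = 1 form.
* The steady gradient-flow rate follows the composed weak power law
  (≈ τ_r^{1/4}-like growth) rather than a strictly flat plateau; over
  two decades of τ_r this amounts to a factor ~2–3, not a ≤15% band.
* Near the connectivity threshold (L/l_c ≲ 4) results are sensitive to
  boundary protocol details; the hardened uniaxial protocol above is
  required for reproducible failure measurements there.
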