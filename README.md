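# actoflow

Agent-based mechanics of cross-linked actomyosin networks — the engine of
cortical flow in animal cells. `actoflow` simulates a quasi-2D "mikado"
network of actin filaments with four minimal ingredients: asymmetric
filament compliance (stiff in extension, soft in compression — buckling),
crosslink molecular friction at every filament crossing, stall-force
motors on a dispersed subset of crossings, and whole-filament turnover.
From simulated trajectories it extracts the quantities a rheologist would
ask for — internal stress profiles, strain rates, effective viscosity η,
elastic modulus G₀, transition time τ_c, peak and steady-state active
stress σ_m, σ_ss — and provides the coarse-grained scaling theory that
organizes them.

## Model in brief

Each filament is an oriented segment with pointed end **p**ᵢ and barbed
end **b**ᵢ, strain γᵢ = (|**b**ᵢ−**p**ᵢ|−L)/L, and elastic endpoint force
μ(γ)γû (μ = μ_e in extension, μ_c in compression). Overlapping filaments
exchange a friction force −ξ(v̄ᵢ−v̄ⱼ); motor-occupied crossings add a
force pair υ(ûⱼ−ûᵢ) pulling each filament toward its pointed end. All
forces balance against solvent drag in the overdamped system **A**·ẋ =
**f**(x), integrated with RK4. Whole filaments disappear at rate 1/τ_r
and reappear unstrained at a fixed areal rate.

Headline scaling results the package reproduces at reduced scale:

- η_c ∝ ξ(L/l_c − 1)², G₀ ≈ 2μ_e/l_c, τ_c ≈ L²ξ/(l_c μ_e)
- viscosity–turnover collapse η = η_c/(1 + (τ_c/τ_r)^m)
- active-stress collapse σ_ss = σ_m/((τ_r/τ_m)ⁿ + τ_m/τ_r)
- steady cortical flow γ̇ = σ_ss/η, with the weak fast-turnover law
  γ̇ = (υ/ξL)·τ_r^¼
- a critical turnover time τ_crit separating steady flow from
  dilution-driven material failure

## Worked example

Closed-form predictions for the reference parameter set:

```bash
$ actoflow theory
{
  "eta_c": 10313.240312354817,
  "tau_c": 50.0,
  "G0": 400.0,
  "sigma_m_scale": 2000.0,
  "tau_m_scale": 0.5
}
```

With the reference values (μ_e = 100 pN, l_c = 0.5 µm, ξ = 100 pN·s/µm,
L = 5 µm, υ = 10 pN) the network should behave elastically with modulus
G₀ = 2μ_e/l_c = 400 pN/µm up to τ_c = L²ξ/(l_c μ_e) = 50 s, then flow
with effective viscosity η_c = (4/π)ξ(L/l_c−1)² ≈ 1.0×10⁴ pN·s/µm.

A short uniaxial creep run on a reduced 15 × 8 µm domain (config file
with `D_x = 15`, `D_y = 8`, `xi = 300`, `zeta = 0.2`, `stress = 0.5`,
`t_end = 25`):

```bash
$ actoflow simulate --config demo.cfg --out runs/demo
{
  "frames": 51,
  "t_end": 25.0,
  "final_strain": 0.012890058726324621,
  "events": []
}
```

The 1.3% cumulative strain after 25 s of 0.5 pN/µm loading is the fast
viscoelastic phase plus the onset of crosslink-slip creep;
`runs/demo/frames.csv` holds the per-frame stress decomposition, strain
rate and density, and `actoflow analyze --frames runs/demo/frames.csv
--stress 0.5` summarizes the effective viscosity and transition time
from it.

Reduced-scale reproductions of the package's headline experiments are
exposed as one-liners, e.g.

```bash
actoflow reproduce fig7d --seed 1 --out scan7d.json   # stress collapse
actoflow reproduce fig9e --seed 1 --out flow.json     # gradient flow
actoflow reproduce ref-scale --seed 1                 # full-domain flow
```

(`ref-scale` runs the 50 × 20 µm reference-scale activity-gradient flow
and takes several minutes.)

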