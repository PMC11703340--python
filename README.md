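# foammech

Analysis toolkit for the mechanics and microstructure of cell-laden
conductive foam scaffolds under electrical stimulation: viscoelastic DMA
endpoint extraction, hysteresis energy-dissipation shakedown modelling,
microCT-style 3D morphometry, diffusive tortuosity, and effective
electric-field estimation — with a seeded synthetic-data layer that
carries closed-form ground truth for every analysis.

## Who it is for

Tissue-engineering and biomaterials groups running unconfined-compression
bioreactor tests and microCT volumetric analysis on porous scaffold–cell
constructs (e.g. graphene-foam chondrogenic cultures), who need the
downstream numbers — moduli, relaxation, per-cycle dissipated energy,
Obj.V/TV-style tables, tortuosity, effective fields, cohort statistics —
computed reproducibly from raw traces and voxel volumes.

## The models at the core

**Viscoelasticity.** Constructs are modelled as a Prony series
(generalized Maxwell): `E(t) = E∞ + Σ Eᵢ e^(−t/τᵢ)`, with storage/loss
components `E′(ω) = E∞ + Σ Eᵢω²τᵢ²/(1+ω²τᵢ²)`,
`E″(ω) = Σ Eᵢωτᵢ/(1+ω²τᵢ²)`; `|E*| = √(E′²+E″²)`, `tan δ = E″/E′`.  Five
endpoints are extracted from the standard protocol (preconditioning to
14 % at 0.5 Hz, ramp to 12 %, 120 s relaxation, 1 % dynamic amplitude at
10 %/s): compressive linear modulus (peak dS/dE, 12-point fit),
equilibrium modulus, stress relaxation %, dynamic modulus and phase shift.

**Energy dissipation.** Each preconditioning cycle's hysteresis loop area
`∮σ dε` (trapezoid rule, kJ/m³) decays toward steady state and is fit by

    y_fit = A e^(−t/τ) + y0,   y_norm = y_fit/A,   y_adj = (y_fit − y0)/A

with RMSE, R², and regression-F diagnostics.

**Morphometry & transport.** Binary volumes yield porosity, Obj.V/TV,
Obj.S/Obj.V, Obj.S/TV (marching-cubes surface), Euler-based connectivity
density Conn.Dn = (1 − χ)/TV, 26-connected object counts, and
inscribed-sphere structure thickness.  The tortuosity factor τ follows
`D_eff = D·ε/τ` from a finite-volume Laplace solve
(Dirichlet:Dirichlet, periodic lateral boundaries); the effective field is
`E = V_RMS / (d_cm · τ)`.

## Worked example

Simulate one specimen with a known material and recover its endpoints:

```python
from foammech import (PronyMaterial, ProtocolSpec, simulate_dma_protocol,
                      extract_endpoints, extract_hysteresis_loops,
                      energy_decay_series, fit_energy_decay)

material = PronyMaterial(equilibrium_modulus=26e3, arms=((52e3, 10.0),))
protocol = ProtocolSpec()
sim = simulate_dma_protocol(material, protocol, seed=42)

ep = extract_endpoints(sim.trace, protocol)
loops = extract_hysteresis_loops(sim.trace)
fit = fit_energy_decay(*energy_decay_series(loops))
```

Output (printed by the snippet in `docs/` form):

```
equilibrium modulus :   26.00 kPa (truth 26.00)
dynamic modulus     :   78.15 kPa (truth 78.00)
phase shift         :   3.525 mrad (truth 6.666)
stress relaxation   :   58.70 %
cycle-1 dissipation :  0.0719 kJ/m^3
cycle-8 dissipation :  0.0375 kJ/m^3
shakedown fit       : tau = 9.36 s, y0 = 0.0274 kJ/m^3, RMSE = 3.89e-04
```

The equilibrium and dynamic moduli land on the material's closed forms
(the dynamic modulus within 0.2 % despite 0.5 % stress noise).  The phase
shift of this nearly elastic material is a few milliradians, at the
resolution limit set by the noise.  Cycle-1 dissipation is roughly double
cycle-8 — the start-up transient that the shakedown fit summarizes with a
time constant close to the material's 10 s relaxation time and a
steady-state level y0.  Stress relaxation on the full protocol (58.7 %)
sits below the step-response value (66.7 %) because the 5 s rest does not
erase preconditioning stress history — see `docs/methods.md`.

A full cohort run (simulate → analyze → report) from a YAML config:

```bash
foammech run --config cfg.yaml --seed 1
```

writes `endpoints.csv`, `energy_cycle_pairs.csv`, `decay_fits.csv`,
`morphometry.csv`, `summary.json` and a hash manifest.  Other subcommands:
`simulate`, `analyze-dma`, `analyze-energy`, `morphometry`, `tortuosity`,
`field`.

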