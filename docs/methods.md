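# Methods

`foammech` implements the quantitative analysis chain used to characterize
electrically stimulated cell–scaffold composites on conductive open-cell
foam: unconfined-compression dynamic mechanical analysis (DMA), hysteresis
energy dissipation with exponential shakedown modelling, microCT-style
binary-volume morphometry, image-based diffusive tortuosity, and
effective-field estimation for scaffold-coupled electrical stimulation.
Because no raw bioreactor traces or reconstructed scans are distributed
with the study this package emulates, every analysis is validated against
a first-class synthetic-data layer that attaches closed-form ground truth
to its outputs.

## Viscoelastic simulator

The constitutive ground truth is a linear-viscoelastic Prony series
(generalized Maxwell model): an equilibrium spring `E_inf` in parallel
with arms `(E_i, tau_i)`, with relaxation modulus

    E(t) = E_inf + sum_i E_i exp(-t / tau_i)

and the standard storage/loss components

    E'(w)  = E_inf + sum_i E_i w^2 tau_i^2 / (1 + w^2 tau_i^2)
    E''(w) =         sum_i E_i w   tau_i   / (1 + w^2 tau_i^2).

Stress under an arbitrary strain history is the Boltzmann hereditary
integral, discretized per arm with the exact-exponential recursive update
(`h[n] = e^(-dt/tau) h[n-1] + E (tau/dt)(1 - e^(-dt/tau)) deps`), which is
exact for piecewise-linear strain and unconditionally stable — a naive
convolution would be both slower and less accurate at this protocol's
74k-sample traces.

The strain schedule follows the standard construct-testing protocol:
offset-sinusoid preconditioning to 14 % peak strain at 0.5 Hz (8 cycles),
5 s rest, a linear ramp to 12 % strain, a 120 s relaxation hold, and a
dynamic segment of 1 % amplitude at a 10 %/s peak strain velocity.  The
dynamic angular frequency follows from the velocity: for
`eps = eps0 sin(w t)` the peak rate is `w eps0`, so `w = 0.10/0.01 =
10 rad/s` (≈1.59 Hz).  Choices the protocol leaves open, fixed here once:

- preconditioning waveform: offset sinusoid from zero strain,
  `eps = 0.07 (1 - cos(2 pi f t))`, so each cycle starts and ends at zero;
- ramp duration 1.2 s (a 10 %/s ramp, consistent with the dynamic rate);
- 10 dynamic cycles; endpoint fits use the last three;
- sampling 500 Hz (1000 samples per preconditioning cycle);
- measurement noise: additive Gaussian stress noise, default 0.5 % of the
  noise-free peak preconditioning stress.

Default material parameters for the synthetic cohort sit at the
cartilage-construct scale reported for this system: equilibrium moduli
15–30 kPa, arm moduli up to twice the equilibrium arm, relaxation times
10–20 s.

## DMA endpoints

- **Compressive linear modulus** — max of the central-difference dS/dE on
  the loading arc of the final preconditioning cycle, then an OLS line
  through the 12 samples centred on the peak (6 each side, shifted inward
  at arc boundaries, first index on ties).  The peak search excludes
  samples where the strain rate is below 10 % of the arc maximum: at the
  loop tips the strain rate vanishes and dS/dE of any viscoelastic loop
  diverges (vertical tangent), which is a parametrization artifact, not
  stiffness.
- **Equilibrium modulus** — mean stress over the final 10 s of the hold
  divided by the held strain (read from the trace, not hard-coded).
- **Stress relaxation %** — `100 (sigma_peak - sigma_eq)/sigma_peak`, with
  the peak searched over the ramp plus the first second of the hold.
  Note that on the full protocol the 5 s rest does not fully erase arm
  stress left by preconditioning when `tau ~ 10 s`, which genuinely lowers
  the post-ramp peak; the step-response closed form
  `100 sum(E_i)/(E_inf + sum E_i)` is reproduced on ramp+hold inputs
  without that history.
- **Dynamic modulus and phase shift** — stress and strain over the last
  three dynamic cycles are each fit by `y = c + a sin(wt) + b cos(wt)` at
  the known protocol frequency (linear least squares: deterministic, no
  starting values).  `|E*| = sigma0/eps0`; `delta = phi_sigma - phi_eps`
  wrapped to the centred interval (-pi/2, pi/2].  The centred wrap keeps a
  noise-level negative estimate near zero instead of folding it to ~pi;
  passive materials report `delta` in [0, pi/2).

## Hysteresis energetics

Each preconditioning cycle is split at its strain maximum into loading and
unloading arcs.  Dissipated energy density is the closed-cycle integral
`∮ sigma deps` by the trapezoid rule (loading minus unloading integral),
in J/m^3 = Pa·strain, reported in kJ/m^3; a signed result below
-1e-9 kJ/m^3 raises instead of being silently flipped, so orientation bugs
surface.  Strain energy is the trapezoid area under the loading arc.  On
the constructed steady-state sinusoid pair the trapezoid area converges
quadratically to the analytic ellipse area `pi sigma0 eps0 sin(delta)`.

Dissipation per cycle versus cycle-end time is fit by

    y_fit      = A exp(-t/tau) + y0          (shakedown model)
    y_norm     = y_fit / A
    y_adjusted = (y_fit - y0)/A = exp(-t/tau)

using bounded trust-region least squares (`A >= 0`, `tau > 0`), with the
deterministic initializer `y0 = min y`, `A = y(t1) - y0`, `tau = span/3`
and restarts at `tau x {0.3, 1, 3}` — no randomness.  Diagnostics: RMSE
`sqrt(SSE/n)`, R², and the regression F of the 3-parameter model against
the intercept-only model with df (2, n-3) and its p-value.  A flat series
returns `A = 0` with `tau` flagged unidentifiable rather than an arbitrary
number.  Both the raw (kJ/m^3) and the cycle-1-peak-stress-normalized
series can be fit; the normalized series carries kJ/m^3 per kPa.  With
only 8 preconditioning cycles, `tau` is the weakly identified parameter:
at 2 % noise its sampling error is ~10 %, consistent with the large spread
such experiments report for the time constant, while `y0` and `A` are
recovered to ~2 %.

## Morphometry

Metrics follow CT bone-morphometry conventions on binary or labelled
(0 void / 1 scaffold / 2 cell) volumes with cubic voxels:

- thresholding is inclusive on both ends of an 8-bit window (the scaffold
  window 25–115 and dense-label window 115–255 overlap at 115; the
  labelled-volume convention here assigns 115 to the dense phase when both
  windows are applied in that order);
- Obj.V from voxel counting; Obj.S from a marching-cubes isosurface at
  level 0.5 after Gaussian pre-smoothing (sigma = 0.8 voxels) of the
  binary mask — raw binary marching cubes overestimates a sphere's area
  by ~8.5 %, the smoothed surface is accurate to ~0.5 % (sphere) and
  ~3 % (cube); voxel-face counting (biased ~1.5x high) is available for
  cross-checks;
- foreground connectivity 26, background 6, for components and for the
  exact voxel Euler characteristic chi; Conn.Dn = (1 - chi)/TV, the
  Euler-based density of redundant connections (ball: 0; torus: 1/TV).
  TV is always the full grid volume;
- structure thickness by the largest-inscribed-sphere convention: from
  the Euclidean distance transform, maximal spheres are painted in
  descending radius order (half-voxel bins) with diameter `2 edt - 1`
  voxels, so a slab of 15 voxels reads exactly 15 and a single voxel reads
  1; the coverage test is inclusive of the sphere's boundary shell so the
  bumpy rim of digitized round structures is not spuriously thin
  (a 24-voxel cylinder reads 23).

`slice_stack` exports planes at a fixed physical spacing as single-page
8-bit TIFFs with the structure in black (0) and voids in white (255) plus
a JSON manifest, the input convention of image-based transport tools;
restacking reproduces the sampled planes bit-exactly.

## Transport

The tortuosity factor is defined through `D_eff = D eps / tau` (a
transport ratio, not a geometric path length; a serpentine channel of
centreline `L_e` over gap `L` gives `tau ≈ (L_e/L)^2`).  The steady-state
Laplace problem is discretized by voxel-centred finite volumes on the
conducting phase: unit conductance across faces between phase voxels,
conductance 2 on the half-cells linking the inlet/outlet planes
(Dirichlet:Dirichlet, concentrations 1 and 0), lateral boundaries periodic
by default (insulating available).  Only the face-connected (6-connected)
components spanning both planes enter the linear system; the volume
fraction in `tau = eps/(D_eff/D)` counts the whole phase, and directional
percolation is reported with the 26-connected convention.  The symmetric
positive-definite system is solved by diagonally preconditioned conjugate
gradients with a deterministic ordering; convergence is certified by the
relative inlet/outlet flux mismatch (default tolerance 1e-6).  Exactness
checks: a dense block gives `tau = 1` and straight channels give
`D_eff/D = eps` to 1e-6 by the parallel-resistor argument; a direct sparse
solve reproduces the iterative flux to 1e-8 on small grids.

## Stimulus and effective field

The stimulus is a zero-mean biphasic square wave (50/50 duty cycle, no
interphase gap), vpp in mV; its RMS is exactly vpp/2.  The effective field
policy is

    E_eff [mV/cm] = V_RMS [mV] / (d [cm] * tau),

the nominal field across the electrode gap (default 3.17 mm) attenuated by
the transport tortuosity factor.  This is the only single-formula reading
consistent in magnitude with fields reported for this kind of system, but
published per-condition values typically mix per-replicate averaging that
a single (V, d, tau) formula cannot reproduce exactly; the formula is
therefore exposed as an explicit, swappable policy rather than buried.

## Statistics

One-way ANOVA by direct between/within sums of squares, Tukey HSD
post-hoc comparisons (studentized range), and post-hoc achieved power from
the observed Cohen's f at alpha = 0.05; paired two-sided t-tests compare
cycle-1 with cycle-8 dissipated energy per specimen.  Calibration is
tested, not assumed: on 1000 seeded null replicates (3 groups of 5) the
ANOVA type-I error must fall in [0.03, 0.07], and paired-t null p-values
must be uniform to Kolmogorov distance < 0.05.

## Synthetic data: what it does and does not emulate

The foam generator's default is a Voronoi-edge strut network: solid
voxels are those whose third-nearest tessellation seed is nearly as close
as their first (i.e. voxels near cell edges), thresholded at the quantile
that realizes the requested porosity exactly.  This reproduces the defining
transport property of an open-cell conductive foam — a connected strut
skeleton that still percolates at 97 % porosity — which a thresholded
Gaussian random field (also available, `model="gaussian"`) cannot: level
sets of a smooth random field disconnect below ~16 % volume fraction.
Neither model is a physical growth simulation; strut hollowness, node
shapes, wrinkled surfaces and scan artifacts (noise, beam hardening, ring
artifacts) are not modelled.  Cell blobs are non-overlapping spheres
placed in void space, optionally required to touch the scaffold phase.

Consequently, passing morphometry/transport tests demonstrate correctness
of the *measurements* on geometry with known truth, not fidelity of the
generator to any particular specimen; printed per-study values such as a
specific tortuosity factor or connectivity density depend on the raw scans
and are not reproduction targets.

## Problem sizes and numerical defaults

Simulated traces: full protocol (~148 s) at 500 Hz, ~74k samples,
milliseconds per specimen.  Volumes: phantoms up to ~130 voxels per edge;
foam demonstrations at 48–128 per edge.  Transport solves use CG with
rtol 1e-8 and flux-mismatch certification at 1e-6.  Decay fits use xtol =
ftol = gtol = 1e-14.  All randomness flows through explicit integer seeds
(numpy `default_rng`); the pipeline derives per-specimen sub-seeds by a
fixed counter scheme so extending a cohort never changes existing
specimens.

## Known limitations

- Linear viscoelasticity only: no poroelastic/biphasic fitting, no
  Mullins-type damage, no finite-strain corrections (engineering strain on
  the preload-contact thickness).
- The stress-relaxation endpoint on the full protocol retains real
  preconditioning history; it matches the step-response closed form only
  for step-like inputs.
- Isotropic cubic voxels only; TV is the full grid (no irregular ROI).
- The Euler-based Conn.Dn convention is an informed default; commercial
  CT tools do not document theirs, so absolute agreement with such outputs
  is not claimed.
- No electrode/electrolyte circuit model: the field estimate is a bulk
  attenuation policy, not an electrochemical simulation.
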