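# Methods

## Model structure

The lobule is a lattice of identical unit cells: a tissue cube of edge
24 µm (one hepatocyte plus its ECM shell) surrounded by sinusoid channels of
square cross-section 6 × 6 µm running along the 12 cell edges, lattice pitch
30 µm. Sinusoid junctions sit on the `(n+1)³` grid points; segments are the
grid bonds; one tissue node per cell forms the second continuum. Each
interior segment is shared by four cells. Sinusoid volume is attributed 3
segments/cell (12 edges ÷ 4), so the accounted cell volume splits into a
sinusoid fraction `3·pitch·A_ch` and a tissue fraction `24³`, summing to one
by construction.

Ports follow the idealized lobule: four portal inlets at the vertical corner
columns of boundary junctions and one central vertical column as the
pericentral outlet. The exact port extent of the conceptual figures is not
constrained by data; full-height columns are this package's convention. All
non-port boundaries are closed to flow.

## Property estimation

All base-case parameters derive from physical laws (see README for the
formulas): Poiseuille tube porosity/permeability, Carman–Kozeny tissue
permeability (classic packed-bed constant 180; the 50 nm collagen fiber
diameter as grain scale), Stokes–Einstein free diffusion, and a fixed 10×
hindrance for tissue diffusion. Two conventions deserve note:

- **K_sin = R²/8 with R = 3 µm.** The open-tube Poiseuille equivalent; the
  alternative φ·R²/8 does not reproduce the canonical 1.125 µm² value, so
  the porosity-free form is used and the porosity enters separately through
  fluid volumes and diffusive cross-sections.
- **Mole-fraction conversions** use the pure-water molar density
  55.56 mol/L (1 µM = 1.8 × 10⁻⁸ mole fraction), the unique factor
  consistent with the dual-unit kinetic parameters.

Tissue porosity (0.2) and hence tissue permeability (1.736 × 10⁻⁷ µm²) are
not fixed by any printed measurement; both are configuration values with
these defaults.

## Flow solver

Steady incompressible Darcy flow with pressure unknowns on junctions and
tissue nodes. Conductances (µm³/(Pa·min)):

- sinusoid segment: `K_sin·A_ch/(µ·L)`, per-segment heterogeneity factors
  multiply K_sin;
- tissue–tissue face: `K_tis·a²/(µ·L)` (a = tissue edge);
- tissue↔segment exchange: Warren–Root-style shape factor
  `K_tis·(a·w)/(µ·L/2)` per cell–segment link (w = channel width), split as
  two half-conductances to the segment's endpoint junctions. This keeps the
  system a symmetric M-matrix; coupling to the segment mean pressure would
  differ only by a rank-one term per link.

Inlet junctions are held at Δp (default 100 Pa — the portal–central drop is
not a measured value; it is configurable and logged), outlet at 0. The
sparse SPD system is solved by LU factorization (deterministic ordering),
residual checked against 1e-10. Sinusoid components not connected to any
port are excluded and carry exactly zero flux; if no inlet–outlet spanning
sinusoid cluster exists the solver returns the flagged zero-flow solution
rather than routing flow through the ~10⁷× less conductive tissue continuum.
Bond percolation uses a single seeded permutation, so retained segment sets
are nested across fractions at a fixed seed, and the retained count is
round-half-away-from-zero of `p·E`.

## Transport and reaction

Mole-fraction concentrations live on junctions and tissue nodes with fluid
volumes `φ_sin·A_ch·L/2` per incident segment end and `φ_tis·a³` per tissue
node. Advection uses first-order upwinding on every conducting link with
link fluxes recomputed from the flow solution's pressures — the advective
divergence therefore matches the flow solve exactly and the cumulative
ledgers (injected, outlet-produced, reacted) close the mole balance to
machine precision; the audit helper exposes the residual. Diffusion uses
`D·A_fluid/L` per link, free D in the sinusoid, hindered D for tissue and
exchange links.

Transient stepping is operator-split: backward-Euler advection–diffusion
(LU factorization reused across equal steps), then a pointwise implicit
Michaelis–Menten update solved in closed form as the positive root of the
scalar quadratic — exact, unconditionally non-negative, and cheaper than the
Newton iteration it replaces. Default dt = 10⁻³ min; halving dt changes the
1-minute metabolite output by <1% on the test lobule. Because first-order
splitting biases the *steady* balance at large steps, steady states are not
time-marched: they are solved directly by damped Newton iteration on
`A c + R(c) = b` (transport operator, MM sink, advective inlet source),
starting from the reaction-free linear solution. The Jacobian is an
M-matrix, so the iteration is robust; junctions isolated by percolation are
pinned at zero.

**Oxygen.** Inlet O₂ (60 µM dissolved, mixed portal blood) and the O₂
kinetics are modeling choices, not measured lobule values: v_max = 1000
µM/min and K_m = 6 µM were calibrated once so that the intact 8³ lobule at
the default pressure drop shows a steady pericentral/periportal tissue O₂
ratio ≈ 0.33, inside the physiological zonation band (0.3–0.5). The
apparent v_max exceeds bulk-liver O₂ consumption because the lattice
exchange geometry (diffusion across a half-pitch of hindered ECM) under-
states the real sinusoid–hepatocyte transfer surface; the product of demand
and exchange, which is what the O₂ field feels, is what the calibration
fixes. Fractional utilization is consumed/injected per unit time at steady
state (NaN when the lattice carries no flow).

**Zonation.** The enzyme field maps steady tissue O₂ through a monotone
rule; the default linear rule `(O₂max − O₂)/(O₂max − O₂min)` clipped to
[0, 1] encodes pericentral CYP enrichment. Threshold and Hill alternatives
are pluggable; the exact experimental protocol behind zonal CYP estimation
is not reproduced here, and the rule family is a documented stand-in.

**First-pass paclitaxel.** A 1 µM inlet bolus sustained for 1 min (both
configuration values), eliminated in tissue with the dual-unit kinetics
above scaled by local enzyme abundance; every eliminated mole appears as
PAC-OH, transported with PAC's diffusivities (no metabolite-specific data).
At these kinetics the lobule-scale extraction fraction is small, so the
fibrosis comparison below uses the *outlet-produced* PAC-OH at 1 min — the
washout-limited quantity — which falls monotonically with the percolation
fraction in the median over seeded replicates.

## Poroelasticity

Small-strain Biot theory: trilinear hexahedral elements for the skeleton
(E = 5 kPa, ν = 0.35 defaults; G = E/(2(1+ν))), cell-centered finite-volume
pressure with two overlapping compartments (sinusoid, tissue) carrying
upscaled permeabilities `K_sin·A_ch/pitch²` and `K_tis·(a/pitch)²`, coupled
by the per-cell exchange conductance (12 links). The skeleton sees the
volume-fraction-weighted pressure through α; storage follows from α and
Skempton's Sk as `1/M = α(1−αSk)/(Sk·K_dr)`, zero in the default
incompressible-constituent limit α = Sk = 1.

Each step runs the fixed-stress sequential split: flow with the mean total
stress frozen at the previous iterate (stabilization
`β_cd = α²w_c w_d/K_dr`), then mechanics with the updated pressure, iterated
until relative pressure and displacement increments fall below 1e-8. The
split remains contractive in the incompressible limit; α = 0 decouples the
physics and returns after a single pass. A dense monolithic solve of the
identical discrete system verifies the converged iteration to ~1e-12 on a
2×2×2 block.

Boundary conditions are not dictated by any printed protocol and are the
package's documented choices: relaxation runs fix the base, prescribe the
top vertical displacement (sealed), and leave lateral faces traction-free
and drained to zero pressure, so relaxation proceeds by lateral fluid
expulsion. The column (consolidation) mode confines lateral displacement,
seals all faces but the drained top, and supports traction control; the
classic uniaxial consolidation series (drained top, sealed base, constant
load, ramp folded in by Duhamel superposition) then serves as the analytic
benchmark, matched to 0.8% space-time L2 at the test resolution. A sealed
variant verifies the undrained Skempton limit p = −σ_mean to better than 1%.

The ramp-hold protocol applies 5% compression in 0.1 s (20 uniform steps;
strain rate 0.5 s⁻¹) and holds 60 s with geometrically growing steps
(factor 1.3). Fibrosis scenarios compare (i) normal, (ii) stiffness ×5 with
permeability ×0.2, and (iii) stiffness ×5 alone; the ×5 stiffening reflects
the severalfold stiffness increase of advanced fibrosis, while the
permeability reduction factor is a free scenario parameter.

## Synthetic data and problem sizes

All inputs are generated by code; there are no external data. The fixture
generator provides a `chain` (1×1×n duct whose four symmetric corner chains
obey the series-path closed form), a `tiny_lobule` (6³, full port layout)
and a `column` (1×1×n consolidation stack). Tests run on 2³–6³ lattices and
16-cell columns; the acceptance script uses the 8³ lobule with five seeded
percolation replicates and a 4³ mechanics block — sizes at which every
qualitative ordering of the full 50³ configuration is already expressed,
while each full run stays in seconds. What the reduced lattice does *not*
emulate: the long pericentral diffusion distances and steep O₂ crash of the
full-size lobule, absolute flow magnitudes (no measured pressure drop), and
sub-threshold seepage. At percolation fraction 0.2 — below the cubic
bond-percolation threshold ≈ 0.249 — most realizations have no spanning
sinusoid cluster and carry exactly zero flow; orderings that require a
perfused fibrotic lobule (O₂ utilization) therefore condition on a
spanning realization, matching the perfused fibrotic case they describe.

## Known limitations

- Newtonian blood; no Fahraeus–Lindqvist radius dependence of viscosity.
- Single effective metabolite and no protein binding or transporter
  kinetics for paclitaxel; no hemoglobin O₂ carriage (dissolved O₂ only).
- Small-strain linear poroelasticity; no hyperelastic or viscoelastic
  skeleton, no indentor geometry (uniform top-face displacement).
- The zonation rule is phenomenological; abundance rescales v_max only.
- Image-derived (anisotropic) sinusoid networks and lobule-array tiling are
  out of scope; the lattice is the idealized cubic topology.
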