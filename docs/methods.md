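# Methods

## Scope and assumptions

`vasoperf` models steady-state blood circulation in a single organ as
three coupled sub-systems: an arterial vessel graph, a venous vessel
graph, and a two-compartment porous continuum standing in for every
vessel too small to segment.  The main simplifications are inherited
from the quasi-1D/porous-media framework itself:

- laminar, Newtonian, incompressible flow; no pulsatility, no
  Fahraeus–Lindqvist effect, no plasma skimming;
- each segment is a straight cylinder with a single radius; no
  tapering or curvature within a segment;
- the capillary bed is homogeneous and isotropic (scalar
  permeabilities), with impermeable organ boundary (no-flow Neumann,
  imposed by face omission in the finite-volume stencil);
- the vasculature is passive: no autoregulation, growth or remodelling
  — an occlusion changes radii, never topology;
- wall mechanics enter only through the static thin-wall radius law;
  the wall has no dynamics of its own.

## Governing equations

**Segments.**  Pressure drop `ΔP = ΔP^h + ΔP^b` with the Poiseuille
term `ΔP^h = 8μLq/(πr⁴)` and, when junction losses are enabled, a
Bernoulli-type loss at each degree-≥3 endpoint where the segment is not
the datum vessel:

    ΔP^b = ρ q_dat² / (2π² r_dat⁴) · (1 + x² − 2x cos(¾θ)),
    x = (q_n / r_n²) / (q_dat / r_dat²).

The datum at a junction is the inflowing segment with the largest |q|
(ties broken to the lowest segment id; if no segment flows in at the
current iterate the junction term is skipped there).  θ is measured
between the datum's flow direction entering the node and segment *n*'s
flow direction at the node, in [0, π]; a straight pass-through has
θ = 0 and pays nothing.  The loss applies to *every* non-datum segment
at the junction, including a non-datum inflow at a converging node,
and is subtracted in the direction of that segment's flow.

**Elasticity.**  `r = r_init + (1−λ²) r_init²/(hE) (P_in − P_ext)`
with `h = h_ratio·r_init` (the wall-thickness ratio is held at the
rest radius so the law stays explicit).  P_in is the mean of the
segment's endpoint pressures; P_ext is the same-compartment capillary
pressure at the in-mask cell nearest the segment midpoint.  The result
is clamped to [0.5, 2]·r_init purely for solver robustness — converged
dilations are a few percent, so the clamp is inactive in normal
regimes (clamping events are logged at debug level).

**Capillary bed.**  Two Darcy compartments on the same mask exchange
volume at `α(P_a − P_v)` per unit volume.  The two-point flux
approximation uses the homogeneous transmissibility `τ = S K/(μ Δx)`
per face (`S = Δx · thickness`); on these uniform grids TPFA is
consistent and second-order in practice (checked by a manufactured
solution in the tests).  All discrete sources and exchanges are stored
as volumetric flows per cell (densities × cell volume = Δx²·thickness)
so that global balances are plain sums.

**Coupling.**  A terminal's flow is distributed with the bump
`w_i ∝ exp(−1/(1 − d_i²/ε²))` over in-mask cells with centre distance
d_i < ε, renormalized to sum to one — renormalization (rather than a
continuum normalization constant) keeps the discrete mass transfer
exact when the support is clipped by the organ boundary.  If ε is so
small that no cell centre qualifies but the terminal sits inside an
in-mask cell, that cell receives weight 1.  Pressure continuity is
`P_t − Σ w_i P_β,i = κ Q_t` with
`κ = 8με m^{4/3}/(π r_t⁴)` (a surrogate tube of length ε, radius
m^{−1/3} r_t, m = cells strictly within the ε-disc).  κ is evaluated
at the rest radius and held constant.

**Sign convention** (used everywhere): `Q_t` is the flow arriving at
the terminal node through its segment, which equals the signed source
strength delivered into the compartment — positive at arterial
terminals, negative at venous ones in normal operation.  One
continuity equation then serves both trees.

## Discrete system and solver

Unknowns: x_N (non-terminal nodal pressures + segment flows, both
trees), x_T (terminal pressures), x_D (cell pressures, both
compartments).  Rows: one per segment, one per internal node (mass),
one per root (Dirichlet pressure), one per terminal (continuity
through κ), one per cell (TPFA + exchange + mollified sources).  The
global root-flow balance is implied by the interior equations and is
checked after every solve rather than imposed as a redundant row.

In the cell rows the terminal flow is eliminated through the
continuity equation, which adds `(1/κ) w wᵀ` to the Darcy operator and
`−w/κ` couplings to x_T.  This removes the constant-pressure nullspace
of the pure-Neumann operator, so the Darcy block A_DD is symmetric
positive definite and state-independent.  It is factorized once
(sparse LU); `C = A_DD⁻¹ A_DT` has only as many columns as terminals,
so `x_D = −C x_T` is exact and cheap, and the Schur complement
`A_TT − A_TD C` closes a reduced system over (x_N, x_T) only.

The linear variant is a single direct sparse solve (available both
reduced and unreduced; the two agree to machine precision and are
cross-checked in the tests).  Nonlinear variants solve the reduced
residual with MINPACK's Powell hybrid method (a dogleg trust-region
iteration with finite-difference Jacobians), initialized from the
linear solution; datum vessels and effective radii are re-evaluated
from the current iterate at every residual evaluation.  Convergence:
‖F‖ ≤ tol·(1 + ‖b‖) with tol = 1e-9 by default; in practice the
direct and dogleg solves land near machine precision, which matters
because junction losses perturb the solution only at the 1e-6 relative
level.  If the trust-region iteration stalls, a damped Picard
iteration on the frozen-coefficient linear system (damping 0.7) takes
over and the fallback is logged.  The solver is fully deterministic;
seeds only influence synthetic geometry.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| μ | 3e-6 | kPa·s | blood viscosity |
| ρ | 1.05e-6 | kg·mm⁻³ | blood density (junction losses only; 1050 kg/m³) |
| E_a, E_v | 1000, 500 | kPa | Young's moduli (arteries twice as stiff) |
| λ | 0.5 | — | Poisson ratio |
| h/r | 0.22 / 0.1 | — | wall-thickness ratio, arteries / veins |
| K_a, K_v | 3e-6, 6e-6 | mm² | compartment permeabilities (venous twice as permeable) |
| α | 5e-4 | kPa⁻¹·s⁻¹ | perfusion coefficient (≡ kg⁻¹·mm·s in these units) |
| ϕ | 0.1 | — | porosity (velocity reporting only) |
| P_in, P_out | 30, 7.5 | mmHg | root Dirichlet pressures |
| ε | 3·Δx | mm | mollifier radius (per-terminal override allowed) |
| tol | 1e-9 | — | relative residual target |

All are amphibian-scale values typical of small-organ microvascular
studies.  The unit system (mm, s, kPa) makes 1 kPa = 1 kg·mm⁻¹·s⁻²,
so resistances are natively kg·mm⁻⁴·s⁻¹ and α's two customary unit
spellings coincide numerically; mmHg is converted at the I/O boundary
(1 mmHg = 0.1333224 kPa).

A note on the scalar permeability estimate `K = v μ ΔL / ΔP`
(`estimate_permeability`): with the commonly quoted calibration inputs
v = 0.5 mm/s, ΔL = 2 mm, ΔP = 7.5 mmHg it yields 3.0e-6 mm², which is
the arterial default here.

## Synthetic vasculature

The generator emulates the geometry class of a flat organ with two
arterial and two venous root vessels entering the lower boundary:
dyadic branching over `depth` generations, branch lengths decaying by
0.72 per generation, child radii from the Murray-type rule
`r_child = 2^{−1/γ} r_parent` (γ = 3), angles jittered from the seed.
The two arterial sub-trees can be joined near the top by a small
connecting vessel and the venous ones near mid-height by a large one —
the anastomoses that provide collateral circulation; connected leaves
become internal degree-2 nodes.  The left venous root's radius is
scaled by 0.75, making it the *minor* drain (real venous drainage is
strongly asymmetric).  Terminals keep ≥ ε clearance from the mask
boundary so every mollifier is feasible.  The default mask is the full
rectangle.

The packaged mini organ (8×8 mm, 16×16 cells, depth 3, root radius
0.25 mm) keeps every solve in the sub-second range.  Two honest
consequences of this scale: terminal radii (0.125 mm) are a quarter of
a cell, and with only 28 terminals the lumped κ and perfusion exchange
dominate the total resistance (~99.9%), whereas a fully resolved organ
with hundreds of terminals puts most of the drop in the arterial
network.  Passing tests therefore demonstrate the *mechanisms*
(variant ordering, mass balances, occlusion monotonicity/plateau,
collateral protection), not organ-scale resistance budgets.  What the
generator does not emulate: real segmentation noise, vessel tortuosity
and crossings, non-rectangular masks, or physiologically optimized
(CCO-style) branching.

Occlusion scales the target segment's rest radius by (1 − rate); a
100% occlusion floors the radius at 1e-3 of the original instead of
deleting the segment, so system dimensions are identical across a
sweep and the resistance stays finite (×10¹² on the segment —
hydraulically sealed).

## Numerical and design choices

- Four root Dirichlet pressures are imposed; the "sum of root flows is
  zero" identity is then implied by interior conservation and is
  verified post-solve (≤ 1e-10 relative on every variant in the tests)
  rather than assembled as a (redundant) fifth control equation.
- Component resistance decomposition: R_total = (P_in − P_out)/Q is
  split at flow-weighted interfaces — the flow-weighted mean arterial
  and venous terminal pressures, and the exchange-flow-weighted mean
  of (P_a+P_v)/2 as the capillary midpoint (the perfusion drop is
  shared evenly between the two compartment resistances).  Because
  adjacent components share their interface value, the four drops
  telescope to P_in − P_out exactly; the split itself is a convention,
  chosen so the decomposition closes identically.
- The viscosity dependence of R_total is *not* a pure scaling: tube,
  κ and TPFA resistances are ∝ μ but the exchange resistance 1/(αV)
  is not; the test suite asserts the exact mixed prediction on the
  series loop.
- Degenerate inputs: zero flow at a junction skips the loss term (no
  datum); a terminal whose mollifier reaches no cell raises a coupling
  error naming the terminal; an empty mask, a component without a root
  or terminal, or mismatched tree labels are rejected at assembly.
- Networks may consist of several connected components as long as each
  has at least one root and one terminal (e.g. anastomosis-free paired
  trees); the capillary bed couples the pieces.

## Limitations

- 2D masks with unit out-of-plane thickness; the grid structure would
  extend to 3D but is untested there.
- Scalar, homogeneous permeabilities; no anisotropy or heterogeneity.
- Junction-loss and elasticity corrections are evaluated with
  finite-difference Jacobians; very large networks would want an
  analytic sparse Jacobian.
- κ is frozen at the rest radius even in the elastic variants.
- The trust-region solve re-selects datum vessels inside the residual,
  which makes the residual only piecewise smooth; on the tested
  geometries the flow directions are settled well before convergence,
  but pathological near-zero junction flows could slow the iteration
  (the Picard fallback then engages).
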