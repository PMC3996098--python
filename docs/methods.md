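# Methods

## Governing model

Each tissue region obeys the Pennes bioheat equation
`rho c dT/dt = div(k grad T) + omega_b rho_b c_b (T_b − T) + q_met` with
piecewise-constant coefficients. The perfusion term treats capillary blood
as a distributed heat exchanger equilibrating toward the arterial
temperature `T_b`; it is both the dominant heat source of deep tissue and
the physical carrier of the ischemia/inflammation contrast. Metabolic
heating `q_met` is a constant volumetric source. Temperature and normal
heat flux are continuous across layer and lesion interfaces, which the
conforming single-field finite-element discretization enforces implicitly.

The heel cross-section is the band of soft tissue between the skin — the
lower arc of an ellipse with semi-axes `a_out` × `b_out`, cut by a flat top
edge — and the muscle–bone interface, an inward normal offset of the skin
at the cumulative layer depth. Bone is not simulated: observed bone
temperatures vary little over the protocol, so the muscle–bone interface
carries a 37 °C Dirichlet condition, which also anchors the steady problem.
The flat top edge is adiabatic (the lesion sits 22 mm away from it, too far
to be felt there); the skin is convective, `q" = h_inf (T − T_inf)`, except
during cooling, when a 15 °C Dirichlet value models gel-pack contact.

## Parameters

Layer stack (thickness mm; k W/mK; omega_b 1/s; q_met W/m³; T_b °C; rho
kg/m³; c J/kgK), totalling 11.3 mm of soft tissue:

| layer | t | rho | c | k | omega_b | q_met | T_b |
|---|---|---|---|---|---|---|---|
| epidermis | 0.46 | 1200 | 3589 | 0.235 | 0 | 0 | — |
| papillary dermis | 1.67 | 1200 | 3300 | 0.445 | 0.18e-3 | 368.1 | 37 |
| reticular dermis | 1.67 | 1200 | 3300 | 0.445 | 1.26e-3 | 368.1 | 37 |
| fat | 5.0 | 1000 | 2674 | 0.185 | 0.08e-3 | 368.3 | 37 |
| muscle | 2.5 | 1085 | 3600 | 0.51 | 2.7e-3 | 684.2 | 37 |

Lesion rows: ischemia (rho 1037, c 2450, k 0.1, omega_b 0.405e-3,
q_met 342.1, T_b 35) and inflammation (rho 1037, c 2450, k 0.558,
omega_b 6.95e-3, q_met 5262.5, T_b 37). Default lesion geometry: full axes
d1 = 15 mm (tangential) × d2 = 2.5 mm (through-thickness); study depths
3.8, 6 and 8 mm (depth of the lesion *center* below the skin along the
symmetry axis — the only reading under which the stated layer memberships
of the three study depths hold); multilayer shell thickness 1.25 mm.

Blood properties in the perfusion product are `rho_b = 1060 kg/m³` and
`c_b = 3770 J/(kg K)`, standard whole-blood values used throughout
dynamic-thermography modelling; both are config-exposed. Protocol defaults:
`h_inf = 12 W/m²K`, `T_inf = 22 °C`, `T_cool = 15 °C`, `t_cool = 60 s`,
`T_core = 37 °C`, recovery simulated to 30 min (`t_end = 1800 s`), though
all diagnostic observables live in the first 5 min.

The outer heel dimensions are not anatomical constants; the defaults
`a_out = 27 mm`, `b_out = 30 mm` are chosen so that (i) an 8 mm deep lesion
center sits 22 mm below the flat top and (ii) the apex arc coordinate is
≈ 45 mm, centering the 35–55 mm sub-lesion observation window on the
periphery. A sensitivity sweep (a_out 22–35 mm, b_out 30–40 mm) moves the
headline ΔT values by under 0.1 °C, so conclusions do not hinge on this
choice.

## Geometry and meshing

The natural frame is surface-fitted: `u` = arc length along the skin,
`v` = normal depth. Layer interfaces are exact `v = const` curves (uniform
thickness by construction), and the map to physical space,
`F(u, v) = skin(u) + v·n_in(u)`, is injective because the 11.3 mm band
stays below the ellipse's minimum radius of curvature (≈ 24 mm at the
defaults; violating this raises a geometry error).

The lesion is specified as an ellipse *in the (u, v) frame*, i.e. it bends
gently with the layers. This keeps "depth below the skin" exact everywhere
along the lesion; at the default curvature the outline deviates from a
Cartesian ellipse by well under 0.5 mm. The multilayer shell outer boundary
is the ellipse with both semi-axes inflated by the shell thickness (the
exact offset curve of an ellipse is not an ellipse; the difference is
confined to the tips). The severe stage adds the normal-projection band
from the core outline to the skin surface.

Meshing is a deterministic column construction: vertical columns in `u`
(quasi-uniform spacing, with columns pinned at the lesion center and tips)
each carry mandatory nodes at the skin, every layer interface, the bone
interface, and the column's crossings with the lesion/shell outlines;
gaps are filled to 0.65× the requested element size and adjacent node
ladders are zipper-triangulated in depth order. Maximum element sizes are
1.3 mm in the epidermis, fat, muscle and lesion regions and 2.4 mm in the
dermis layers, giving ≈ 3100 triangles on the default model. For laterally
centred lesions the left half is built and mirrored exactly, so the
triangulation — and hence the discrete solution — is symmetric to round-off
(an asymmetric zipper tie-break otherwise biases the early-recovery
profiles by ≈ 0.1 °C). There is no randomness anywhere in the mesher:
identical inputs give bit-identical meshes.

Element regions are tagged by centroid; each element also records its
*background layer*, which is what a `healthy`-stage lesion falls back to,
making the null lesion thermally invisible on an unchanged mesh. All ΔT
observables are differences between two property assignments on one mesh,
so discretization error cancels to first order.

## Discretization and solvers

Linear (P1) triangles with a consistent mass matrix; the perfusion reaction
adds a mass-pattern term `omega_b rho_b c_b`, keeping the steady operator
symmetric positive definite whenever a Dirichlet or Robin boundary is
present (an all-adiabatic, perfusion-free configuration is rejected as
singular). Steady and transient linear systems are solved by sparse LU;
the steady residual is verified below 1e-10 relative.

Time stepping is backward Euler: unconditionally stable, and with constant
coefficients each protocol phase needs one factorization plus a triangular
solve per step. Δt = 0.1 s during cooling and the first 300 s of recovery,
1 s afterwards; halving Δt changes the 5-min field by < 0.001 °C, and
halving the fine element size changes steady skin temperatures by < 0.01 %,
both comfortably inside the 1 % convergence criterion the model targets.
Snapshots are retained every 0.5 s in the fine window and every 10 s after
(full per-step storage adds nothing the observables need). Boundary-
condition switches (cooling on/off) occur exactly at phase boundaries, with
the end state of each phase as the next phase's initial condition; the
recovery clock puts t = 0 at cooling removal and stores the cooling phase
on the negative axis.

Verification rests on two independent oracles: the closed-form steady
multilayer perfusion slab (cosh/sinh layer solutions matched at interfaces;
the pseudo-1D strip FEM agrees to < 0.01 °C) and the erf similarity
solution for step surface cooling of a conduction half-space (< 2 % of the
applied step at early times). A discrete energy budget (metabolism + net
perfusion + net convection = Dirichlet boundary extraction) closes to 1e-8
relative, and all fields respect the physical bounds set by the boundary
data.

## Numerical and design choices

* Lesion-boundary nodes within 0.02 mm of a layer interface are snapped
  onto it; ties in the ladder merge advance the left column first. Both
  choices only matter at the lesion tips, where element areas are small.
* Point P is the skin point on the symmetry axis (directly beneath the
  lesion center); profiles use the arc coordinate l from the arc end with
  the lower x-coordinate, and extrema break ties toward smaller l.
* The ΔT extremum is the signed value of the largest magnitude, so cold
  and warm signatures are directly comparable.
* Config lengths are millimetres (converted to SI internally); plausibility
  checks reject metre-valued lengths slipping into mm fields. Unknown keys
  are rejected outright.
* "Complete" thermal recovery is asymptotic: the stack's slowest mode
  (Robin surface, Biot ≈ 0.5, fat-dominated diffusivity) has a time
  constant of roughly ten minutes, leaving a ≈ 0.14 °C residual 30 min
  after cooling. The recovery test therefore requires the residual to fall
  below 1 % of the ≈ 22 °C core-to-coolant span — the usual IR-resolution
  notion of "recovered" — together with monotone decay, rather than an
  arbitrary absolute cutoff.

## What the model does and does not capture

The simulated scenarios are idealizations: homogeneous layers of uniform
thickness, a single elliptical lesion on the symmetry axis,
temperature-independent properties, and a perfectly applied 15 °C cooling
load. Real heels have patient-specific geometry, heterogeneous perfusion,
thermoregulatory response, and imperfect coolant contact; passing tests
therefore demonstrate correctness of the stated model, not clinical
accuracy. In particular the absolute skin temperature (≈ 32 °C steady at
the apex) and the ΔT magnitudes depend on the assumed boundary parameters,
while the *structure* of the predictions — sign of the anomaly by stage,
growth of the signal toward shallower lesions, transient enhancement over
steady imaging for multilayer lesions — is robust across the explored
parameter ranges.

Known limitations: no inverse estimation of lesion parameters from surface
data; no vascular (discrete-vessel) or temperature-dependent Pennes
variants; 2D cross-section only; curved boundaries are piecewise-linear at
the element scale.
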