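# Methods

This note documents the models, numerical methods and design choices in
`cartimech`, in the order the pipeline uses them: synthetic study
fixtures, constitutive laws, the poroelastic finite-element solver,
defect tools, CT calibration, and the failure analysis.

## What the package models

A focal, partial-thickness defect in the cartilage of a loaded tibial
compartment concentrates strain in the tissue around its rim. The
pipeline quantifies that concentration: it builds an idealized
compartment, loads it through a two-peak stance-phase force with a rigid
spherical femoral-condyle surrogate, solves the fibril-reinforced
poroelastic tissue response with and without the defect, and classifies
the ROI around the defect rim against five literature failure limits
(maximum principal stress 7 MPa, fibril strain 8 %, maximum principal
logarithmic strain 30 %, minimum principal logarithmic strain −30 %,
maximum engineering shear strain 32 %).

Everything runs at desk scale: meshes of order 10³–10⁴ hexahedra, one
CPU, minutes per scenario. Absolute stress/strain magnitudes from a
patient-specific knee cannot be reproduced at this scale (and the
original subject geometry and material constants are not public); the
package instead reproduces the *procedures* — defect relocation at
constant normalized depth, the <2 % mesh-convergence rule, the
five-criterion classification — and the *qualitative mechanics* (strain
concentration at the rim, compressive/shear criteria governing).

## Synthetic study fixtures (`cartimech.synthetic`)

**Compartment.** The articular surface is a shallow concave dish
`z = (x² + y²) / 2R` with `R = 100 mm` over a 16 × 16 mm plateau; the
cartilage thickness field is analytic (base 2.2 mm, optional linear
gradient and Gaussian bump, validated to stay within 0.5–6 mm). The
layered structured hexahedral mesh (≥4 element layers, vertically graded
so the superficial arcade zone is meshed at one third of the nominal
element size; default in-plane element size 1.0 mm) is generated
directly from these analytic fields,
so carving, relocation and submodeling can evaluate exact surface
heights and thicknesses rather than interpolating a mesh. The femoral
side is a rigid analytic sphere (R = 35 mm); a sphere is symmetric about
any axis through its center, so the varus–valgus tilt freedom of a
condyle reduces to a geometric no-op and is omitted. Split lines default
to the anterior–posterior direction projected onto the surface, with a
configurable swirl; an optional meniscus is a partial-annulus wedge
whose only coupling to the tibia is the 350 N/mm horn spring groups.

**Stance load.** The axial force is a sum of two Gaussian bumps in
percent stance (width 5.5 %), with amplitudes solved exactly so the
force at the configured peak times (15 % and 85 %) equals the configured
multiples of body weight (defaults 2.2 and 2.6 × 71 kg × 9.81 m/s²,
the instrumented-knee range); the waveform decays below 5 % of the first
peak at the stance endpoints. Time is parameterized over a 0.6 s stance.

**Desk-scale force.** A single 16 × 16 mm compartment cannot carry a
full tibiofemoral load. Scenario configurations therefore scale the
stance force by `force_scale` (default 0.008, peak ≈ 15 N), chosen so
the *intact* peak compressive strain falls in the 10–18 % range reported
for healthy cartilage during stance. This is the one deliberate
calibration in the synthetic study; everything downstream (fold changes,
criterion ordering) is computed, not tuned.

**CT phantom volume.** A scalar volume (0.2 mm isotropic voxels) with
five cylindrical hydroxyapatite-density phantoms (defaults 0, 100, 200,
400, 800 mg/cm³) whose intensity is affine in density plus Gaussian
voxel noise; label masks and true densities travel with the volume.

All generators are pure functions of (spec, seed).

## Constitutive laws (`cartimech.constitutive`)

**Cartilage** is fibril-reinforced poroelastic: a compressible
Neo-Hookean ground matrix, σ = G/J (b − J^{2/3} I) + K ln J / J I,
carrying Darcy fluid flow (constant permeability k = 2·10⁻³ mm⁴/(N·s)),
reinforced by tension-only fibrils with the strain-stiffening law
σ_f = (E₀ + E_ε ε) ε. One primary family follows the Benninghoff arcade
— split-line direction in the superficial zone (normalized depth
≤ 0.15), bone-normal in the deep zone (≥ 0.70), spherical-linear
interpolation between — plus 13 fixed secondary families on a Fibonacci
sphere sharing 20 % of the fibril density. Defaults (E_nf = 0.31 MPa,
ν = 0.42, E₀ = 0.47 MPa, E_ε = 150 MPa) are the standard
fibril-reinforced cartilage card from the literature; they are
configurable and no acceptance quantity depends on their specific
values.

Two deliberate simplifications: fibril *visco*elasticity is dropped
(the analysis outputs are strain snapshots over one stance cycle, for
which the elastic fibril backbone governs; a rate-dependent law can be
slotted behind `fibril_stress_1d` without touching the solver), and
permeability is strain-independent (single-cycle loading, not long-term
consolidation). The fibril strain measure is engineering stretch minus
one along the deformed primary direction, matching the 8 % damage
threshold's convention; the 1-D fibril law is taken as the Cauchy
stress carried along the deformed fibril direction.

**Meniscus**: transversely isotropic linear elasticity (stiff
circumferential axis, E_c = 120 MPa, E_t = 20 MPa), positive
definiteness checked at construction. **Bone**: isotropic elasticity
with per-element CT-calibrated modulus.

## Poroelastic solver (`cartimech.fe`)

Equal-order trilinear u–p hexahedra with 2×2×2 Gauss quadrature;
backward-Euler time integration of the mass balance
`M (v − v_prev) + Δt H p + S p = 0` with v = det F (div u in
small-strain mode); Bochev–Dohrmann polynomial pressure-projection
stabilization S = (α / 2G) (M_e − v v^T / V_e) with α = 0.05, which
suppresses the spurious pressure modes of the equal-order pair at small
Δt·k without measurably degrading the consolidation benchmark (the
1-D oracle passes at ≤2 % with or without it). Kinematics are
total-Lagrangian with logarithmic strain output; a small-strain mode
exists for closed-form benchmarks (the consolidation oracle is a linear
theory).

The Newton matrix combines a finite-difference consistent tangent for
the displacement block (nine perturbations of the pointwise stress
function, A = ∂P/∂F, then K = Bᵀ A B) with analytic pressure-coupling
and flow blocks; Dirichlet rows are replaced by identity rows. A
backtracking line search guards steps that would invert elements.
Linear systems go through SuperLU (COLAMD ordering).

**Contact** is penalty-regularized, node-to-analytic-sphere and
frictionless: nodal force k_c A_node g n along the sphere normal for
penetration g > 0 (k_c = 30 MPa/mm — a regularization of the hard
pressure–overclosure law). Under force control the sphere's axial
position is one extra unknown whose residual enforces that the total
axial contact force equals the applied stance force (satisfied to
Newton tolerance, audited at 0.5 %); when no contact is active the
sphere advances by the minimum clearance per iteration (capped at
0.25 mm). Under displacement control (submodels) the position history
is prescribed.

**Springs** are linear node-to-ground groups; a horn attachment divides
its 350 N/mm total uniformly over its node set.

**Submodeling**: the refined region is re-generated from the analytic
compartment fields at ~0.3 mm elements; its cut-boundary displacement
and pressure histories are interpolated from the global solution with
the global trilinear shape functions (exact for linear fields), the
interior is unconstrained, the indenter follows the globally solved
position, and inner defect walls keep their free-draining condition.

**Convergence bookkeeping**: `convergence_study` tabulates, per
analyzed parameter (peak minimum principal strain, shear strain,
maximum principal stress, fibril strain), the relative change between
successive refinement levels, and flags PASS below 2 %. Comparing peaks
between meshes needs care: raw Gauss-point extrema sample different
physical locations per mesh, and element-averaging scalars that involve
the rapidly rotating arcade direction (fibril strain, fibril stress)
biases them by the per-element direction spread. The study therefore
recovers the *deformation-gradient field* to nodes (volume-weighted
element averages — F converges like the primitive solution), samples it
on a fixed probe lattice shared by every refinement level (0.25 mm
in-plane spacing, nine normalized-depth stations from 0.1 to 0.9, a
0.5 mm margin off the cut boundary), and evaluates the analyzed scalars
pointwise at the probes — principal log strains from the interpolated
F, fibril strain and effective stress from the constitutive law along
each probe's own analytic arcade direction. Raw Gauss extrema remain
available through ``peak_parameters(per_element=False)``.

## Defect tools (`cartimech.defects`)

A defect is a closed footprint polygon in a 2-D tangent-plane chart at
its center (the plan coordinates of the shallow plateau) plus a
normalized penetration profile: `depth_fraction` over the interior,
smoothstep-blending to zero across a wall-ramp band inside the rim. The
ramp width is resolved at carve time as `depth_fraction · t_center / 3`
(a wall-slope cap near 3) so the recessed rim hexahedra keep scaled
Jacobians above 0.1, and is then frozen into the spec. Carving recesses
the articular surface and re-grades each node column's layers; the
connectivity is untouched, so the mesh is conformal at the rim and
intact/damaged solutions share an evaluation grid. Column penetrations
are antialiased (3×3 subsamples per tributary cell) so the removed mesh
volume tracks the continuum integral; the prism estimate
`area × depth × thickness` holds within 5 % when the footprint is wide
relative to the wall band.

*Relocation* transports the footprint polygon and penetration profile
unchanged in the chart and rebuilds node coordinates from the local
surface height and thickness at the target — each node keeps its
penetration fraction exactly while its absolute depth follows the local
thickness. Projected footprint area (the chart polygon area) is
conserved exactly, and A→B→A round trips are exact up to floating
point. *Surface reconstruction* over a defect solves the discrete
biharmonic equation on the structured heightfield clamped to two rings
of intact vertices (interpolating rim positions and slopes; a
paraboloid — the local model of a curved plateau — is biharmonic, so
spherical caps are filled to within a few percent of the sagitta).
*Drainage*: pore pressure is fixed to zero exactly on the inner-wall
face set; every other exterior face is a sealed (no-flux) natural
boundary; a fully sealed variant is a configuration switch that changes
nothing else in the scenario.

## CT calibration (`cartimech.calibration`)

Otsu's threshold is computed by exhaustive maximization of the
between-class variance over the histogram's candidate splits (ties →
the lowest split; the reported threshold is the midpoint of the optimal
split, i.e. strictly between the classes). HU→vBMD calibration is
ordinary least squares of true phantom density on ROI mean intensity
(voxel-count weighting optional), with residuals and R²;
density→modulus is a configurable power law E = a ρ^b (ρ in g/cm³;
presets a = 6850 MPa, b = 1.49 for trabecular and a = 10200 MPa,
b = 2.01 for cortical bone — literature defaults, not fitted here).
Element moduli are Gauss-quadrature volume averages of the continuum
field; total ∫E dV is conserved to quadrature accuracy (≪0.5 % at the
default order).

## Failure analysis (`cartimech.failure`)

Criteria use strict inequalities (a measure-zero boundary, which makes
the load-bisection recovery of each threshold well-defined). The ROI is
all integration points within 1 mm of the nearest rim node, measured in
the reference configuration and computed once. Exceedance intervals are
maximal contiguous stance spans where the ROI extremum series violates
its limit, with crossing times linearly interpolated between samples
(the compressive criterion exceeds *below* its negative limit).
Intact-vs-damaged fold change uses co-located intact values on the
shared grid, with intact magnitudes below 10⁻⁴ masked out.

## Problem sizes and tolerances

Default scenario runs use a 16 × 16 mm compartment at 1 mm elements
(~1000 hexahedra) and 21 protocol points; the test suite uses a
12 × 12 mm compartment, 6-step ramps to peak load and a 20-element
consolidation column; the convergence study re-solves a 4 × 4 mm
central submodel at 0.3 mm and 0.2 mm elements under a 3-step ramp to
the first stance peak. Newton tolerances: relative residual 10⁻⁷,
absolute floor 10⁻⁸ × load scale. The consolidation benchmark is held
to ≤2 % relative L2 against the closed-form series (in small-strain
mode, since the series is a linear theory; the finite-strain mode
deviates by the expected geometric-nonlinearity margin at the benchmark
load).

## What passing tests do and do not show

The synthetic compartment has analytic geometry, a single tissue layer
tied to rigid bone, a rigid spherical femur, no menisci in the load
path, and a stand-in flexion waveform; real knees have deformable
bicondylar contact, menisci carrying a large load share, and
patient-specific geometry and composition. Passing tests therefore
demonstrate the correctness of the *methods* (solver vs closed form,
conservation under relocation, classifier exactness, convergence
procedure) and the *qualitative* rim mechanics — not patient-specific
stress magnitudes. Known limitations: penalty contact admits ~0.01 mm
overclosure at the default stiffness; the carved wall is a smoothed
ramp rather than a vertical face; equal-order u–p with projection
stabilization trades a small pressure-accuracy loss for mesh
simplicity; hexahedral column re-grading cannot represent undercut or
overhanging defect walls.
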