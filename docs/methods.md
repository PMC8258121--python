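# Methods

## The adaptive degeneration model

The package simulates mechanically driven degeneration of an articular
cartilage explant as an iterative interaction between a mechanics stage
and four adaptive rules.  Each iteration represents an arbitrary unit
of degeneration time: the explant (a cylinder, 1.5 mm height × 1.5 mm
radius by default) is allowed to swell freely, a rigid platen applies a
rapid compression ramp (2 MPa for physiological loading, 4 MPa for
injurious loading, 0.1 s), and the end-of-ramp deformation-gradient
field — measured from the undeformed reference configuration — drives
the update of the tissue's composition and collagen architecture:

1. **Fibril reorientation.**  Principal values λⱼ and directions nⱼ of
   the Green–Lagrange strain E = (FᵀF − I)/2 define preferred fibril
   directions e_p ∝ g₁n₁ ± g₂n₂ ± g₃n₃ with gⱼ = max(λⱼ, 0); only
   tensile principal strains attract fibrils.  The computed primary
   fibril rotates about (e_f × e_p)/‖·‖ by κ·α, where
   α = arccos|e_f·e_p| is the angle to the nearest preferred direction
   (candidates are unsigned directions).  κ = 0.3 per iteration is a
   computational rate without physical time scale; no rotation occurs
   when α < 1° or when the fibril is not in tension.  One of the four
   primary fibrils is computed; the second copies it and the remaining
   two are its mirror image across the split-line symmetry (y-z) plane.
   Secondary fibrils do not reorient.
2. **Collagen degradation.**  A fibril whose tensile strain ε_f (the
   nominal strain of the material line along the fibril,
   √(1+2e_fᵀEe_f) − 1) exceeds K₀,f = 10% loses density share by a
   factor derived from the damage function β = |ε_f − K₀,f| with
   material parameter m_coll = 1.  The literature states this rule in two
   mutually inconsistent forms, and both are shipped: `printed` (factor 1 − e^(−β·m_coll) —
   near-total loss in one iteration just above threshold) and
   `complement` (factor e^(−β·m_coll) — gradual decay, the reading under
   which larger strains deplete density faster).  The default is
   `printed`; the choice is a config switch.  Each of the 17 fibrils of an element is assessed
   with the strain along its own direction, so degradation is
   direction-selective.  There is no recovery.
3. **Proteoglycan depletion.**  The maximum shear strain
   ε_max = max|λᵢ − λⱼ| is non-localised with an isotropic 3-D Gaussian
   of characteristic length l = superficial-layer thickness
   (0.12 × height = 0.18 mm) over all integration points, then
   element-averaged.  Where it exceeds K₀,PG = 30%, the relative PG
   content is multiplied by 1 − (ε_max,nl − K₀,PG)/3, clamped to [0,1].
4. **Coupling.**  FCD follows PG proportionally
   (FCD = FCD₀·PG_rel), and hydration rises as PG is lost:
   n_f = 1 − PG_rel·(1 − n_f0), which recovers n_f0 at PG_rel = 1 and
   tends to a fully fluid tissue as PG_rel → 0.

All four updates of one iteration are computed from the same strain
snapshot and the beginning-of-iteration state (a simultaneous update),
so their internal ordering is immaterial.  The loop runs 50 iterations
by default; optional early stopping on the relative change of the
layer summaries exists but is off by default.

## Algebraic conventions and known ambiguities

Three of the adaptive-rule formulas circulate in forms that are
internally inconsistent, and this package adopts the reading that is
dimensionally and behaviourally coherent (where the choice changes
behaviour it is also exposed as a flag):

* the Gaussian weight's exponent is the **sum** of squared coordinate
  differences (an isotropic 3-D Gaussian — its (2π)^(3/2)l³ prefactor
  is exactly the 3-D normalisation; a product of squares is
  dimensionally inconsistent);
* the PG depletion factor groups as 1 − (ε_max,nl − K₀,PG)/3, clamped
  at zero so PG_rel cannot become negative;
* the hydration rule uses the minus sign (the plus-sign form yields
  n_f > 1 and fails to recover n_f0 at PG_rel = 1); the printed form is
  callable behind `printed_variant=True` for audit only.
* the collagen factor's direction is genuinely ambiguous (see rule 2);
  both variants are first-class and tested.

## The mechanics stage (reduced fibril-reinforced swelling model)

Published fibril-reinforced poro-viscoelastic swelling (FRPVES)
descriptions of cartilage rely on parameter sets that are not fully
public; the reference solver here implements a documented reduction
with the same structure, with every parameter configuration-driven:

* **Non-fibrillar matrix**: compressible neo-Hookean,
  E_m = 0.70 MPa at a solid fraction of 0.2, ν = 0.15, scaled per
  element by the local solid fraction (1 − n_f0)/0.2 so the water-rich
  superficial zone is the softest.
* **Collagen fibrils**: tension-only exponential-toe stress per unit
  relative density, σ_f = k₁(e^(k₂ε) − 1) with k₁ = 0.16 MPa, k₂ = 60,
  linearised above ε = 0.15 for robustness.  Each element carries 4
  primary fibrils following a Benninghoff arcade (split-lines along ±x
  at the surface, surface-normal in the deep zone, cosine bend through
  the middle zone) and 13 secondary directions — 6 seeded hemisphere
  draws, their x-mirrors and one in-plane direction, a deterministic
  quasi-isotropic set that is exactly mirror-symmetric.  The primary
  family carries 48% of the depth-dependent relative collagen density
  ρ_z(ẑ) = 0.75 − 0.5ẑ + 1.25ẑ² — lowest mid-depth, highest at the
  deep-zone anchorage (the classical arcade weighting of ~3
  secondary-equivalents per primary fibril over 4 + 13 fibrils).
  The slack→taut transition is smoothed over a strain width of 10⁻⁴ so
  the Newton tangent is well defined at the stress-free state.
* **Donnan swelling**: ideal Donnan pressure
  π = φRT(√(c_F² + 4c̄²) − 2c̄) with osmotic coefficient φ = 0.9,
  external bath c̄ = 0.15 mEq/ml and c_F the initial FCD profile
  (0.11 + 0.14ẑ mEq/ml) scaled by the current PG_rel and diluted by
  the volumetric deformation through the fluid fraction; the initial
  fluid fraction profile is n_f0(ẑ) = 0.90 − 0.25ẑ.
* **Transport limits instead of a Darcy transient**: the 0.1 s ramp is
  far shorter than the explant's consolidation time, so the ramp is
  solved as fully undrained (a stiff volumetric penalty
  K_u ln(J_sw/J), K_u = 100 MPa, about the swollen state); free
  swelling and the stress-relaxation end state are solved fully
  drained.  Permeability therefore appears only as metadata.
* **Contact**: the platen is a rigid flat surface implemented as a
  single master degree of freedom slaving all top-surface vertical
  displacements, loadable by force (pressure ramp) or displacement
  (stress-relaxation test).  The nominal friction coefficient of 0.05
  is approximated as free tangential sliding; at that level the
  tangential traction is at most 5% of the applied pressure and does
  not change which regions cross the adaptive thresholds.
* **Rigid modes**: the bottom surface is fixed vertically and free
  radially; the three in-plane rigid motions are removed by global
  momentum constraints (Σu_x = Σu_y = Σ(x·u_y − y·u_x) = 0 over the
  bottom nodes).  Point pins were deliberately avoided: off-plane pins
  bias the solution and destroy the mirror symmetry the intact explant
  must have.

The solver is total-Lagrangian with 8-node hexahedra, 2×2×2 Gauss
quadrature, Newton iterations with centrally differenced consistent
element tangents (central, not one-sided, so a mirror-symmetric model
keeps an exactly mirror-symmetric Newton path), backtracking line
search and adaptive load stepping.  Warm starts carry displacement
fields across degeneration iterations.

### Calibration

The free material parameters (k₁, k₂, E_m and the composition
profiles) were calibrated once, before any degeneration experiment was
frozen, to reproduce two macroscopic anchors of healthy bovine explant
behaviour: an equilibrium modulus of ≈1.6 MPa in the simulated
stress-relaxation test (free swelling, 10% compression, drained
equilibrium; reaction stress at the bottom over applied strain), and
an undrained compression response in which the physiological 2 MPa
ramp keeps fibril strains below the 10% degradation threshold and the
non-local shear stimulus below the 30% depletion threshold everywhere,
while the injurious 4 MPa ramp crosses both in the superficial and
middle zones.  The exponential fibril toe is what makes this
separation possible: with a linear fibril law the strain gap between
the two load levels is too small relative to the thresholds.

### Meshing

The cylinder is meshed by mapping an n×n structured square grid
smoothly onto the disk and extruding through a graded stack of
z-planes refined toward the articular surface; the default stack
contains node planes exactly at 100, 380 and 750 μm depth, so the
three lesion grades are resolved without remeshing.  A defect is a
20 μm wide slit through the full diameter normal to the split-line
axis, built by duplicating the x = 0 nodes above the lesion tip and
offsetting the two crack faces by ±10 μm; the tip-plane nodes remain
shared.  Layer labels (superficial < 0.12, middle < 0.45 of normalised
depth) follow element centroids.

The runner warns when the largest element edge exceeds the non-local
characteristic length — at the reduced problem sizes the test-suite
uses (a few hundred elements) this warning is always active, and the non-local
average is correspondingly coarse.  Production-scale meshes
(≥ 10,000 elements, matching the mesh-convergence criterion that
element size be below l) are supported by the same code path.

## The synthetic strain provider

For exercising the adaptive rules in isolation, a synthetic provider
realises requested per-layer principal strains (plus an optional
Gaussian lesion-tip amplification blob) as pure-stretch deformation
gradients, one integration point per element.  It emulates the two
features of the compressed explant the rules care about —
surface-concentrated in-plane tension and shear concentration at a
defect tip — but none of the mechanics: no equilibrium, no composition
feedback (the field is frozen across iterations), no swelling
pre-strain and no mesh-scale spatial correlation beyond what is
requested.  Tests passing on synthetic fields therefore validate the
rules' arithmetic, thresholds, fixed points and recurrences — not the
realism of any strain field.

## Readouts

Per-iteration, per-layer (superficial / middle / deep / bulk)
summaries are volume-weighted means of: the unsigned angle between the
current and initial computed primary fibril, relative collagen density
ρ_z/ρ_z,0, relative FCD, and fluid fraction.  Collagen and FCD series
are non-increasing and hydration non-decreasing by construction.  The
equilibrium modulus before and after degeneration characterises the
mechanical consequence of the composition changes; the modulus uses
the nominal cross-section πr² and the swollen height for the 10%
strain.

## Numerical choices and degenerate inputs

* Eigenvector signs are fixed (first nonzero component positive) so
  reorientation is deterministic; candidate ties are broken by a fixed
  enumeration order of the sign combinations.
* Repeated principal strains make the preferred directions basis
  dependent; the α-contraction of the reorientation step holds for any
  basis in the degenerate subspace, which is what the property tests
  assert.
* The non-local average is dense for ≤ 2000 points and KD-tree
  truncated at 6l beyond (within 1e−6 relative of the full sum).
* Degenerate line elements (stretch² ≤ 0) raise in the scalar strain
  API and clamp to full annihilation in the vectorised path used by
  the degradation rule.
* All randomness (secondary fibril set) flows from one seed; repeated
  runs are bitwise identical.

## Known limitations

* The full fibril-reinforced poro-viscoelastic swelling parameter set
  this material approximates is not public; the reduced model
  reproduces the calibrated anchors (intact
  modulus, threshold separation of the two load levels, the injurious
  modulus drop) but not every spatial pattern of the full model.
* Depth localisation is weak: the explant deforms in a depth-coupled
  barrel mode, so the layer-wise strain contrast is small; once the
  protective superficial reorientation stiffens the surface, the deep
  zone becomes the weakest link and PG depletion under injurious
  loading drifts deep-ward instead of running superficial → middle.
  Sweeps over the matrix, fibril and composition depth profiles did
  not invert this within the reduced material class.
* Lesion-tip fields are diffuse: with tension-only fibrils and a soft
  matrix the shear-lag length exceeds the explant size, so slit-tip
  strain concentration washes out even with 20–30 μm tip-local
  elements.  The defect scenarios consequently show near-zero
  composition change and modulus losses within ±1% of zero, leaving
  the lesion-depth ordering of modulus loss at noise level.  The
  corresponding acceptance assertions are kept faithful and fail.
* Fibril viscoelasticity is omitted; the undrained limit stands in for
  the fast-ramp stiffening it would provide.  Its absence is the most
  likely cause of the two preceding items.
* The undrained/drained dichotomy replaces the poroelastic transient;
  intermediate drainage states are not computed.
* Reorientation under near-equibiaxial lateral tension rotates
  split-line fibrils toward the in-plane diagonal; with the reduced
  material the physiological scenario therefore shows a sizeable
  in-plane reorientation angle even though a healthy explant under
  physiological load should remodel very little.  Its composition
  fields do remain quiescent.
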