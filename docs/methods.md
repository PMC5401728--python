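# Methods

## Model

The package solves steady-state current conduction, ∇·(σ∇V) = 0, in a
four-layer skin cylinder with a conical wound, capped by a bath of ambient
medium.  Tissues and media are homogeneous isotropic conductors; under
steady DC the problem is purely resistive, so the relative permittivities
in the material table are stored but never used (they would matter only for
transients, which are out of scope).  Cellular-scale physics — polarized
epithelia, ion pumps — is not modelled; the endogenous case is represented
phenomenologically as a fixed transepithelial potential (TEP) boundary
condition.

Geometry and conventions:

* Cylindrical coordinates (r, θ, z), origin at the centre of the wound
  mouth, z increasing downward.  External interfaces use mm and mV;
  meshes and solvers work in SI.
* Layers from the surface down: stratum corneum 0.014 mm (σ = 2×10⁻⁶ S/m),
  epidermis 0.3 mm (0.026), dermis 2.2 mm (0.222), subcutis 3.0 mm (0.08);
  skin cylinder radius 10 mm.  Ambient PBS: 1.4 S/m.  Air is nominally
  insulating (σ = 10⁻¹² S/m placeholder).
* Wound: a cone of mouth radius 2 mm and depth 5.514 mm (full thickness),
  filled with the ambient medium.
* Bath: 2 mm slab of ambient medium above the surface, no lateral sleeve by
  default (both configurable).  The reported quantities are driven by the
  near-wound region; the bath's role is to close the return path above the
  skin.

## Electrode coupling

Electrodes are ideal equipotential Dirichlet patches with no contact
impedance.  Their *coupling surface* is the one modelling decision that
dominates every result, because the stratum corneum is a 14 µm sheet with
an areal resistance of t/σ = 7 Ω·m² — six hundred times the series
resistance of everything beneath it.  An electrode modelled as a potential
on top of an intact corneum is screened almost completely: the tissue
beneath stays within microvolts of the return potential and no appreciable
field reaches the wound edge.  Physically, stimulation electrodes couple
through a hydrated, compromised peri-wound corneum, and wound dressings
contact the wound bed directly.  The package therefore uses:

* cathodes described as covering the whole wound (geo1, geo3): conforming
  patches on the conical wound-bed surface;
* smaller cathodes placed on/over the wound (geo2, geo4): discs on the
  wound-mouth plane (their top view);
* anodes and side pads on "intact skin" (geo1–geo5): patches clamped at
  the corneum–epidermis plane beneath their footprint;
* the endogenous case: ground on the top surface of the intact skin and
  +30 mV on the epidermis–dermis interface where the wound does not
  interrupt it (the TEP battery).

All placements are explicit `ElectrodePatch` values and can be overridden
per scenario (`placement="top"` restores literal on-corneum contact).

## Discretization

**Axisymmetric scenarios** use linear (P1) triangles on a mapped structured
grid of the (r, z) half-plane.  Vertical grid lines are mapped so that one
column of nodes follows the slanted cone; horizontal lines sit exactly on
every layer interface, and electrode patch edges are inserted as grid
lines.  No element therefore straddles a material interface.  Cells inside
the cone collapse to zero width at the apex; duplicate nodes are merged and
sliver triangles dropped.  Quads split along their shorter diagonal (less
obtuse triangles, better discrete maximum-principle behaviour).  The
stiffness uses the 2πr measure with the centroid radius, which integrates
r over a triangle exactly, so the P1 stiffness is exact and piecewise-linear
solutions (layered 1-D conduction) are reproduced to machine precision.
Element size defaults to 0.1 mm with geometric grading (factor 2) toward
the wound edge; the epidermis always receives ≥ 4 element rows and the
corneum ≥ 2.

**Sector-electrode scenarios** (geo5) use a cell-centred Cartesian grid:
0.35 mm laterally, per-layer vertical spacing (corneum 0.007 mm × 2,
epidermis 0.05, dermis 0.2, subcutis 0.3, bath 0.25) so layer interfaces
are exact grid planes; the cone is staircase-approximated at cell centres.
Fluxes use harmonic averaging of σ across faces (exact for series
conduction); electrode planes clamp the adjacent half-cell conductances
and sever the across-plane link.  Insulating media (air ambient) are
excised from the solve — the exposed surface then carries the natural
zero-flux condition — rather than kept with the σ = 10⁻¹² placeholder,
which would poison the conditioning; the placeholder path remains available
via `include_nonconductive=True`.

Linear systems are solved by sparse LU below 1.5×10⁵ unknowns and by
ILU-preconditioned conjugate gradients above (relative residual 10⁻¹⁰ /
10⁻⁸).  Both paths are deterministic for a fixed mesh.

## Post-processing definitions

* **Field profiles** sample |E| along the 0–20 mm diameter at the middle of
  the epidermis (z = 0.164 mm).  Samples inside the wound cavity or bath
  are flagged and excluded from tissue maxima.
* **Wound-edge maximum**: the largest tissue-side |E| within 1 mm of
  x = 8 or x = 12 mm (the wound rim).
* **Layer dissipation** is the volume average ∫σ|E|²dV / V over each skin
  layer, the wound cavity excluded from both integral and volume (it is
  buffer, not skin).  On triangle meshes the element-constant field makes
  ∑σ|E|²·2πr̄A identically equal to the electrode power ∑IₚVₚ.
* **Surface power**: q·t converted to mW/cm² (q[W/m³] × t[m] × 0.1).
* **Current-loop orientation** is classified operationally: the net
  vertical current through the wound mouth and the net radial current in
  the epidermis+dermis band 1 mm outside the wound rim, on two opposite
  sides.  Symmetric side signs matching a (cached, coarse) endogenous
  reference solve ⇒ `two_loop_endogenous_like`; antisymmetric side signs
  (current traversing the wound laterally) ⇒ `single_loop`.  Fluxes below
  10⁻³ of the largest electrode current count as zero so numerical noise
  cannot flip the classification.

## Reproduction conditions and resolution-limited maxima

In layouts whose electrodes meet at the wound rim with (near-)zero gap
(geo1; geo2's anode terminating at the mouth edge), the continuum field is
singular at the junction: between two fixed potentials ΔV apart meeting at
an edge, |E| ≈ ΔV/(θρ) at distance ρ.  The mid-epidermis sampling line
passes ≈ 0.15 mm below that junction, so its "maximum" grows without bound
under mesh refinement and is meaningful only at a stated smoothing scale.
The package therefore distinguishes:

* **converged defaults** (0.1 mm graded mesh, raw element fields) for
  physical studies — bulk quantities (layer dissipation, currents, loop
  topology) are mesh-converged there;
* **reproduction conditions** (`run_scenario(..., reproduction=True)`;
  used by `scripts/acceptance.py`): a quasi-uniform 0.35 mm mesh — the
  discretization scale of the reference finite-element study this model
  re-implements, estimated from its element count over the model volume —
  with standard region-restricted nodal recovery of the sampled field.
  Nodal recovery never averages across material interfaces, where the true
  field is discontinuous.

Known residual deviations under reproduction conditions, documented rather
than tuned away: the geo1 edge maximum remains ≈ +50 % above the reference
value (the zero-gap singularity), geo3 and geo5 ≈ +30 %, and the
deep-layer (epidermis/dermis/subcutis) dissipation averages differ by
factors of 2–10 in several configurations.  The latter are sensitive to the
unpublished details of the reference model — bath extent, exact electrode
dimensions for geo4/geo5, and its treatment of the thin corneum — and sit
between this package's no-lateral-bath and lateral-sleeve variants.

## Scenario generator

`woundfield.scenarios` is the study's input stage: it emits fully
parameterized, validated scenario descriptions with no external data.  The
defaults encode the study conditions above; where the source material gives
only a drawing (geo4 radii, geo5 pad shape) the defaults are explicit,
overridable choices: geo4 uses a 3 mm disc with the stated 2.5 mm gap
(anode from r = 4 mm); geo5 uses pads covering each side of the intact skin
(r ∈ [2.5, 10] mm, half-angle 80°, i.e. a 0.5 mm standoff from the rim and
20° separations).  What passing tests show is therefore fidelity to this
parameterization, not to living skin: real wounds are irregular, layered
conductivities vary by site and hydration, and electrode–skin contact has
finite impedance.

## Numerical choices and degenerate inputs

* Nodes shared by two touching electrodes of different potentials go to the
  electrode listed first (the ground, by construction); patches overlapping
  with positive measure at distinct potentials are rejected at validation.
* A wound of zero extent is expressed as `wound=None` (degenerate slab
  geometry used by the validation oracles).
* Meshing refuses resolutions that cannot resolve the corneum, and the
  axisymmetric path refuses sector electrodes (directing to the voxel
  path).
* Monte-Carlo geometry checks and all solves are seeded/deterministic;
  repeated runs are bit-identical.

## Problem sizes

The test suite solves coarse meshes (0.3–0.5 mm axisymmetric, 0.5–0.8 mm
voxel) so the full suite runs in a few minutes on one CPU; the acceptance
script uses the reproduction conditions (≈ 1.7×10³ triangles per
axisymmetric scenario, ≈ 7.5×10⁴ voxel unknowns for geo5 in air).
Convergence of the bulk metrics under refinement is exercised by
`woundfield.validation.convergence_study`.
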