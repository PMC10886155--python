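# Methods

`orthok` models overnight orthokeratology (Ortho-K): a rigid
reverse-geometry contact lens is worn on the closed eye, the eyelid
presses it onto the cornea, and the induced reshaping shows up clinically
as a refractive power change (RPC) map. The package implements the whole
chain — topography handling, power-map analysis, patient-specific
finite-element simulation of the lens–eye–eyelid assembly, and map
comparison — so that finite-element stress/strain "barometers" can be
compared quantitatively against the clinically derived RPC.

## Coordinates, units, containers

Right-handed frame with the origin on the topographer axis at the
anterior corneal apex, +Z toward the instrument (anterior); lengths in mm,
forces in N, stresses in MPa (fields are reported in kPa), pressures
entered in mmHg (1 mmHg = 133.32 Pa). Left-eye records are mirrored into
the right-eye frame at ingest (x → −x), so all downstream analysis is
laterality-agnostic; laterality is kept in metadata and ground-truth
decentrations are reported in the mirrored frame.

Topographies are polar elevation grids (default 300 azimuths × 333 radial
stations out to 4.98 mm) with a boolean coverage mask, stored in a small
documented text container (header, radii, azimuths, elevation block,
coverage block). The radial stations are stored explicitly, so the
container is agnostic to the instrument's sampling rule.

## Clinical map analysis

**Tangential power.** Per semi-meridian, the tangential (instantaneous)
radius of curvature is `Rt = (1 + z'^2)^(3/2) / |z''|`, with derivatives
from sliding 5-point Fornberg stencils (4th-order interior, high-order
lopsided at profile ends; the naive one-sided second difference leaves an
edge error two orders above the 1e-4 mm verification target). Power
follows the reduced Gaussian optics formula `Pt = (nh − nair)/Rt` with the
hypothetical index nh = 1.3375 standing in for the unmeasured posterior
surface. RPC = post − pre on the shared valid region.

**Smoothing.** Penalized least squares in a discrete-cosine basis
(`z = argmin ‖√W (z − y)‖² + s ‖D z‖²`, `D` the discrete Laplacian),
smoothing factor s = 4.5 by default, solved exactly by DCT for uniform
weights and by fixed-point iteration for weighted/gappy maps; invalid
cells get zero weight and the outermost valid ring is down-weighted
(default 0.5) to suppress the edge effect; a robust mode applies biweight
reweighting.

**Treatment-zone detection.** Per semi-meridian the radial zero crossings
of the RPC are located by linear interpolation; crossings within an
edge-exclusion margin (default 0.5 mm, configurable) of the local valid
rim are discarded. The central flattened zone (CFZ) is the connected
negative region (connectivity evaluated on a doubled array so it crosses
the azimuthal wrap) inside the innermost crossings. The CFZ centre —
hence the lens decentration, resolved into X/Y via cosine and sine of the
meridian angle — is by default the area centroid of the near-peak plateau
(cells within 1% of the deepest power change). The alternative
|RPC|-weighted centroid of the whole CFZ is available but is pulled
apex-ward by the measurement geometry (meridians pass through the apex,
not the zone centre): at 0.9 mm decentration the centroid is biased by
about 0.15 mm while the plateau peak stays within 0.08 mm.

## Surface extension and meshing

A Zernike fit of order ≤ 3 (Noll-indexed, orthonormal over the 5.5 mm
disc) fills coverage gaps and extends the surface to the 5.5 mm limbal
radius; measured samples are kept verbatim. Because a low-order fit
leaves a residual at the measured rim, a C¹ Hermite ramp absorbs the
offset and slope mismatch across the extrapolated annulus, so the
composite surface is continuous. Beyond 5.5 mm each meridian continues
along a circular arc (default radius 12 mm) tangent-matched at the rim,
out to the 8.2 mm model rim — an exactly tangent-continuous parametric
stand-in for an averaged peripheral eye shape.

Meshing is nonparametric: surface points are converted to spherical
coordinates about a centre on the axis (at the mean scleral-arc centre
depth, keeping every polar angle single-valued) and the radius field is
cubically interpolated onto the directions of a pre-meshed template. The
radius grid is gently Gaussian-smoothed (σ = 2 samples; sub-micrometre on
smooth corneas) because the low-order fill of lid-truncated sectors
otherwise leaves a faint seam crease that imprints bending wiggles on the
finite-element wall.

The disk template is a butterfly/O-grid: a central b × b structured patch
(elliptical square-to-disc map) surrounded by rings of 4·b quads, so a
disk layer holds `b² + 4·b·rings` elements. Cornea presets: `desk`
(b = 4, 30 → 12 rings, 5 layers, 1040 elements) and `paper` (b = 4,
28 rings, 5 layers), both with 5 through-thickness layers; wall thickness
runs linearly from the patient's CCT at the apex to CCT + 0.18 mm at the
5.5 mm limbal radius (constant beyond), offset along the local surface
normal. The denser preset targets the element count used at full clinical
scale; exact totals are implementation-documented, not a contract.

The lens cross-section is built from its zone arcs: five back zones
(base/reverse/two alignment/peripheral), axis-centred and sag-matched
(C⁰) at junctions; three front arcs with the outer two tangent-matched
(the printed 4.00 mm edge radius cannot be axis-centred at a 5.3 mm zone
radius). A minimum edge thickness (default 0.08 mm) keeps the revolved
solid valid where front and back profiles close. The lens mesh uses the
same disk topology (base 4, 30 rings, 2 layers).

The eyelid models the closed upper and lower lids as one continuous
surface: a uniform nx × ny mid-surface grid (reference grid 51 × 41, desk
preset 31 × 25) draped over the upper envelope of the anterior eye and the
seated lens front plus a clearance gap (default 0.05 mm), smoothed over
the lens edge, and extruded 0.5 mm outward in two hexahedral layers.
Material: E = 1.73 MPa, ν = 0.49, density of water. The straightforward
node/element count of this construction (6273/4000) is kept.

## Lens seating (constrained ICP)

The lens is placed at the clinically detected decentration, settled along
the axis to a standoff clearance, and fine-tuned by iterations that pair
every back-surface node with its true closest point on the smooth surface
interpolant (Gauss–Newton in azimuth/elevation). Each iteration offers a
point-to-point Kabsch fit and a damped point-to-plane Gauss–Newton pose
step (point-to-point alone cannot slide a smooth cap tangentially);
steps are clamped (≤ 0.05 mm / 0.25° per iteration; totals ≤ 1 mm / 5°,
with a separate 0.1 mm lateral budget so the clinical decentration
survives), spin about the lens axis is suppressed, the axial settle is
re-imposed exactly every iteration, and a step is accepted only if the
objective (RMS closest-point distance) decreases — the reported objective
sequence is non-increasing by construction. Iterations are capped at 50.

## Finite-element engine

8-node hexahedra with 2×2×2 quadrature and mean-dilatation B-bar
volumetric treatment (the near-incompressible ν = 0.49 materials would
otherwise lock). Kinematics:

* small-strain (default for the contact assembly; displacements are
  sub-millimetre on centimetre geometry, and contact — evaluated on
  deformed coordinates — is the dominant nonlinearity);
* finite-displacement total-Lagrangian St. Venant–Kirchhoff
  (`nlgeom=True`), with B-bar applied to the Green strain and to the
  deformed strain-displacement operator so the internal force is the
  consistent gradient of the modified strain energy; the tangent
  (material + exact geometric stiffness) matches finite differences to
  1e-7.

Pressure loads are integrated consistently (2×2 Gauss) on the reference
surface. Newton iterations use a residual line search (one to three
non-improving steps are tolerated — contact active-set flips sometimes
need them — and four in a row abort the increment); failed increments
are bisected. Contact is node-to-master-facet penalty with: penalty
k = factor · E_cornea · facet area / wall thickness (factor 5); a
quadratic force regularisation over the first 10 µm of penetration
(killing active-set chatter — the regularisation depth must exceed the
typical per-iteration geometry change); lateral build-time filtering of
slave sets so nodes past a master rim never pair; and regularised Coulomb
friction μ = 0.01 as a tangential spring with smooth tanh saturation at
μ·f_n, anchors convected by the slip at each accepted increment. Contact
increments that stall with an out-of-balance force below 1% of the
external load norm are accepted and flagged in the convergence log, the
counterpart of commercial contact stabilisation. The free-floating lens
is grounded by weak springs (1e-5 N/mm per node, orders below the contact
forces).

**Stress-free geometry.** Topography measures the IOP-loaded eye, so the
reference configuration is found by the fixed point
`X0 ← X0 − (x(X0) − X_target)` until the re-inflated surface matches the
measurement (tolerance 1e-4 mm, cap 30 iterations). The inner inflation
solves use the finite-displacement path: without stress stiffening the
fixed point diverges on soft/high-IOP eyes whose Zernike-extrapolated
peripheral patches are locally flat (bulging modes amplify). Inner solves
are warm-started; a secant acceleration of the dominant contraction mode
(ω = 1/(1−ρ), capped at 3, reverted whenever the residual grows) cuts the
outer count to 6–8. In plain (unaccelerated) mode the residual sequence
is monotone, which the property test checks.

**Load program.** (1) stress-free iterations; (2) IOP inflation of the
eye in 10 equal static increments (patient IOP, mean 15 mmHg);
(3) blink settle: 8.0 mmHg lid pressure ramped quasi-statically onto the
eyelid outer surface — a quasi-static replacement for the dynamic blink,
whose lens-repositioning role is carried by the ICP seating; (4) tear-film
surface tension, 43.6 mPa, applied verbatim as a uniform attractive
normal traction on the lens back (dimensionally this is a pressure, not a
surface tension; at 0.04 Pa it is four orders below the other loads and
is retained for fidelity, magnitude configurable); (5) eyelid closure at
the same 8.0 mmHg — the recorded steady closed-eye state. Contact pairs:
cornea anterior (master) ↔ lens back, lens front (master) ↔ eyelid back,
cornea anterior (master) ↔ eyelid back.

**Fields.** Quadrature stresses are volume-averaged per element and
averaged onto the anterior surface nodes. Barometers: contact pressure
(penalty normal traction per master facet area, zero outside contact),
Mises stress √(3/2 s:s), pressure −tr(σ)/3 (positive in compression),
maximum principal stress (largest eigenvalue), maximum principal
logarithmic strain (largest eigenvalue of ln V from the deformation
gradient), and displacement magnitude. The FEA RPC rebuilds anterior
height maps from the inflated and final states (best-fit rigid motion
removed — curvature is a rigid invariant) and runs them through the same
clinical power pipeline.

## Comparison

All maps are resampled by triangulation-based (Clough–Tocher) cubic
interpolation onto the common −8..8 mm, 0.1 mm grid (161 × 161; no
extrapolation outside the convex hull) and normalised to [−1, 1] by their
peak magnitude over the analysis mask (valid region ∩ 5.5 mm disc).

**NCC.** The masked normalized cross-correlation surface over every
displacement (u, v), with all local sums precomputed by running-sum/FFT
correlations of the zero-filled maps and their masks, so invalid cells
drop out of every term; positions with under 16 valid pairs are invalid.
The central template-sized window (zero displacement at the map centre)
is reported as the spatial coefficient map; the full surface is retained.

**SSIM.** Local luminance l, contrast c and structure s terms over an
11×11 Gaussian window (σ = 1.5) on maps affinely rescaled to [0, 1]
(L = 1), with C1 = (0.01 L)², C2 = (0.03 L)², C3 = C2/2, exponents 1 —
the standard formulation, matched to an independent reference
implementation to 1e-10 in tests.

**Bands.** Weak |γ| < 0.4, moderate 0.4 ≤ |γ| < 0.6, strong |γ| ≥ 0.6
(half-open edges; the interval notation in the clinical convention
overlaps at endpoints). Areas are exact rational cell-count fractions of
the analysis mask, so the three bands sum to 100 exactly; cells without a
valid coefficient count as weak. Cohort statistics: mean ± SD per
barometer and band, Lilliefors-corrected KS normality check (population
parameters are estimated from the sample, so the plain KS test would be
anti-conservative), and pairwise two-sample t-tests at 95% confidence.

## Synthetic study conditions

The generator emulates the clinical cohort the method was designed for;
its defaults are the study conditions. Per patient (one global seed,
per-patient streams hashed from (seed, index), bit-reproducible):

* metadata: age 14.1 ± 4 y, IOP 15 ± 3 mmHg, CCT 0.554 ± 0.033 mm
  (clipped to physiologic ranges), 132:117 right:left;
* pre-wear surface: toric conicoid
  `z = −r²/(R(θ)(1+√(1−(1+Q(θ)) r²/R(θ)²)))` with meridian-dependent
  apical radius from Sim-K flat 42.6 ± 1.3 D / steep 44 ± 1.3 D and
  asphericity flat 0.66 ± 0.1 / steep 0.4 ± 0.18. The tabulated
  asphericity's sign convention is not fixed by the source; the generator
  exposes it (`e2`, `q`, `neg_q`, `p`) and defaults to e² (Q = −e²,
  prolate), the convention under which the values are physiologic;
* coverage: palpebral aperture between lid parabolas drawn from the
  cohort lid-fit statistics, intersected with the device disc, with
  seeded lash-slit dropouts near the lid edges (6 sectors, ~2° wide,
  0.8 mm deep by default);
* Ortho-K effect: specified in power space (central flattening
  −2.5 ± 0.75 D, annulus steepening 1.5 ± 0.5 D at 2.8 ± 0.3 mm,
  decentration N(0, 0.3 mm) per axis) and realised in elevation space by
  double-integrating a target curvature-change profile built from
  C¹ compact bumps; a wide closure shell (the broad annular steepened
  zone real maps show) zeroes the slope at the outer support and a piston
  shift zeroes the value, so the surface is conserved exactly beyond
  annulus radius + 2 transition widths;
* lens: base curve chosen from flat-K plus the target flattening,
  alignment curves at the flat-K radius, standard thickness/diameter;
* correlated validation fields: `ρ·standardized(RPC) + √(1−ρ²)·noise`
  with smooth noise projected exactly orthogonal to the map, so the
  zero-lag NCC equals ρ up to rounding.

What the generator does **not** emulate: measurement noise and tear-film
artefacts, epithelial redistribution biology, diurnal regression, maps
whose treatment zone is not a single connected region, and real-eye
higher-order irregularity beyond the toric conicoid. Passing tests
therefore demonstrate the correctness and self-consistency of the
pipeline under clean study-shaped inputs, not clinical accuracy on
measured eyes.

## Verification problem sizes

The Lamé thick-walled sphere benchmark (a = 11.5 mm, b = 12.05 mm,
E = 0.25 MPa, ν = 0.49, 2 kPa internal pressure) runs on two glued
hemisphere caps (base 6, 12 rings, 3 layers; ~5000 dof); rigid modes of
the self-equilibrated problem are regularised with negligible symmetric
grounding springs rather than point constraints, which would imprint a
rigid offset on the symmetric solution. Reported quantities are the
surface-averaged inner radial displacement and volume-averaged hoop
stress (both within ~1% of closed form; errors fall monotonically under
refinement). The end-to-end cohort runs n = 10 synthetic eyes at the desk
preset (a scaled-down stand-in for a full clinical cohort); the acceptance
script uses n = 3 by default. Band-area statistics at these sizes carry
large SDs and are read as qualitative mirrors of the clinical pattern
(no strong NCC areas anywhere; contact pressure the weakest performer),
not as reproductions of the cohort percentages.

## Known limitations

* Linear elastic, homogeneous cornea (no fibre reinforcement or
  viscoelasticity); the age–modulus law E = 0.0032·age + 0.2 MPa is the
  only patient-specific material input.
* The contact assembly runs small-strain; the finite-displacement path is
  used where it is structurally necessary (stress-free search). The
  small anterior-surface mismatch this introduces cancels in the FEA RPC
  difference.
* Node-to-facet penalty contact with uniform facet weighting conserves
  force but only approximately conserves moment per facet.
* The eyelid is a uniform-thickness elastic shell; no tarsal plate,
  no blink kinematics, no lid tension beyond the applied pressure.
* Desk-scale meshes make contact pressure (a per-facet quantity) the
  noisiest barometer — consistent with its clinical role as the worst
  performer, but quantitative band areas at this resolution are
  indicative only.
* At desk scale the simulated FEA RPC is roughly an order of magnitude
  smaller than the imposed clinical RPC: the elastic model has no
  epithelial redistribution (the dominant clinical mechanism), and the
  coarse lid shell bridges part of its pressure straight onto the
  peripheral cornea. The comparison metrics normalise every map to
  [−1, 1], so the spatial-correlation question the pipeline answers is
  unaffected by this magnitude gap.
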