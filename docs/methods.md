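# Methods

## Physical model and assumptions

Airflow is steady, incompressible and laminar. Inspiration is modelled as a
constant volumetric flow rate Q imposed as a uniform velocity at the naris
(inlet); the nasopharynx (outlet) is an outflow boundary (zero normal
gradient of all transported variables, with the pressure level anchored
there); walls are rigid with no slip. Steadiness rests on the smallness of
the breathing-cycle Strouhal number, and the laminar assumption on the inlet
Reynolds number staying below 600 at 128–512 mL/min — both verified for the
shipped phantom (Re ≈ 41–163).

Odorant transport is one-way coupled to the flow: the nondimensional
concentration c (inlet value 1) obeys steady convection–diffusion with the
odorant's air-phase diffusivity D_a. Uptake at mucus-coated walls uses the
quasi-steady film model: the odorant partitions into the mucus with
equilibrium coefficient β (air/mucus), diffuses across a uniform film of
thickness H_m with c = 0 at the mucus/tissue base (perfect clearance by the
submucosal circulation), giving the Robin condition

    −D_a ∂c/∂n |_wall = k_m c_w,      k_m = D_m / (β H_m).

Low β means a mucus-avid odorant and a large k_m. With H_m = 30 µm the three
registry odorants span k_m ≈ 0.177 m/s (carvone), 1.04e-2 (amyl acetate),
5.14e-5 (octane): carvone's uptake is air-side (supply) limited, octane's is
mucus-side limited, amyl acetate sits in between. The nondimensional
parameter K = k_m d_in / D_a (d_in = inlet hydraulic diameter) is exposed
for reporting; the solver itself works dimensionally, which is equivalent
for every reported quantity. Squamous epithelium takes zero flux. The
dimensional wall flux is j = k_m c_w C_in with C_in the (unknown in
general) inlet mass concentration; the default C_in = 1 kg/m³ is recorded in
every report header, and the preferred deposition measure is the
C_in-independent uptake fraction J/(C_in Q).

## Geometry: the two-channel phantom

The synthetic airway is a mid-sagittally extruded two-channel phantom: an
anterior single lumen (squamous-lined), a septum fin splitting it into a
narrow dorsal (olfactory) channel and a wider ventral (respiratory) channel,
and a merged posterior outlet tube (nasopharynx, counted as respiratory
epithelium). Default dimensions, chosen once at a realistic rat scale:

| parameter | default | note |
|---|---|---|
| total length | 20 mm | naris → nasopharynx |
| lumen height | 1.7 mm | |
| dorsal channel width | 400 µm | the narrow olfactory meatus |
| septum fin thickness | 300 µm | axial extent 2.5–19 mm |
| ventral channel width | 1000 µm | |
| extruded depth | 5 mm | enters all areas/volumes |
| squamous zone | 0–2.5 mm | zero-flux walls |
| respiratory zone | 2.5–5 mm | |
| olfactory zone | 5–18.5 mm | dorsal walls only |
| slice thickness / pixel | 200 µm / 50 µm | 100 coronal slices |
| widening δ | 34 µm | total-width mode |
| mucus thickness H_m | 30 µm | |

The widths give a dorsal/ventral conductance ratio (lubrication limit,
∝ w³) of ≈ 6%, so most flow takes the ventral path, and the
respiratory-zone length makes carvone strongly depleted before the olfactory
zone (olfactory uptake ~1e-4 of the inhaled flux at 128 mL/min) — the regime
in which airway-dimension changes act most strongly on soluble-odorant
deposition. The olfactory epithelium ends at 18.5 mm, strictly inside the
fin extent, because it is a fixed tissue zone: it must not move when the
airway wall recedes, and keeping it inside the two-channel region makes the
olfactory wall set identical between the paired models.

Widening semantics: "uniform widening by δ" is ambiguous between per-wall
recession (each wall moves δ) and total-width growth (each wall moves δ/2,
the local channel width grows by δ). Both modes are implemented; the default
is total-width, consistent with a 5–30 µm per-wall mucus film plus
shrinkage. Analytically, widening adds 2r to each channel, removes 2r from
the fin (r = recession per wall), grows the lumen outer height by 2r and
erodes the fin tips axially by r. On image stacks, each slice is upsampled
(nearest neighbour — masks are labels, no grey interpolation) and the airway
is dilated by thresholding the in-plane Euclidean distance transform of the
tissue side at r; the default 50 µm pixels with upsample factor 25 give the
2 µm operating precision at which a 34 µm widening of a 500 µm lumen is
exact to one pixel. Dilation is 2D in-plane per slice (slice-wise editing
semantics); a dilation that merges previously distinct airway components is
reported as a topology warning in the stack metadata, never silently.

## Discretization and solvers

The mesh is a masked tensor-product Cartesian grid of the mid-sagittal plane
(x anterior→posterior, y ventral→dorsal, SI meters) with a constant extruded
depth. For analytic specs the grid lines conform exactly to every wall,
region boundary and fin face; cell counts per channel can optionally be
pinned (`y_counts`) and near-wall rows geometrically graded (first off-wall
heights h₁·g^k, the stand-in for prism layers). For image stacks the mask is
sampled at cell centers (stair-step walls); cells not 4-connected to the
inlet are dropped with a warning. Every channel must be resolved by ≥ 8
cells across its width.

Flow: SIMPLE on a collocated grid. Convection is deferred-correction
second-order upwind (first-order matrix, explicit linear reconstruction from
the two upwind cells, face values limited to the local neighbour range);
diffusion is central; Rhie–Chow interpolation builds face fluxes; the
pressure-correction system takes a zero-correction Dirichlet anchor on the
outlet faces, and the same (periodically refrozen) face coefficients are
used in the matrix and the flux correction, so cell continuity is satisfied
to machine precision after every iteration — global inlet/outlet mass
balance is exact by construction. Momentum u and v share one matrix; it is
solved by defect correction against an LU factorization refrozen every 10
iterations, with an automatic immediate refactorization whenever the stale
factor stops contracting the linear residual (this is what keeps the scheme
stable at the upper end of the laminar range). Under-relaxation 0.7
(velocity) / 0.3 (pressure); residuals (u, v, continuity imbalance) are RMS
norms over cells, each normalized by its own early-iteration value — with a
fallback normalization by per-cell shares of the inlet momentum/mass flux so
warm-started runs (grid-refinement sweeps prolong the coarser solution) can
converge; tolerance 1e-4. Q = 0 short-circuits to the exact null solution.

Transport: same convection/diffusion stencils on the frozen face fluxes. The
Robin wall enters the wall-adjacent cell as the series conductance
A / (1/k_m + δn/D_a) (δn = wall-normal distance of the adjacent cell
center), equivalent to c_w = c_P / (1 + k_m δn / D_a); k_m = 0 and k_m = ∞
reduce to zero-flux and Dirichlet walls. The first-order system is
factorized once; outer iterations update only the limited second-order
correction and stop when the RMS concentration change per iteration falls
below 1e-6. The face limiter keeps 0 ≤ c ≤ 1 to ≈1e-7 slack in all shipped
cases. Odorant mass balance (inlet advective + diffusive inflow − outlet
advective outflow − total wall deposition, relative to inflow) closes to
≤ 1.5e-4 on every study case.

## The paired study

`run_paired_study` meshes the narrow and the analytically widened spec at
matched resolution — same target cell size *and* the narrow model's
per-interval y cell counts — so the paired discretization errors largely
cancel in the percentage differences; this matters because the weakest
signal (octane olfactory deposition, ~+0.1–0.4%) is smaller than the
cell-count quantization noise of independently meshed models. The widened
*image stack* (the geometry module's product) is still generated and
measured in the bundle's geometry table, cross-checking the analytic
widening: stack volume 1.451e-7 m³ → 1.504e-7 m³ (image pipeline) vs
1.545e-7 m³ (widened spec rasterized); the image value is lower because the
34 µm dilation at upsample 8 quantizes to 6.25 µm pixels. Mesh-based
geometries are meshed from the spec, not the 2 µm mask, because a 34 µm
boundary shift is sub-cell at any affordable Cartesian resolution and would
be quantized away by mask sampling.

Default problem sizes, chosen as the package's study conditions: 50 µm
cells (≈11.6k active cells per model), flow tolerance 1e-4, transport
tolerance 1e-6, grid-independence levels 1/2/3 (up to ≈105k cells,
warm-started). The default 18-case study plus the refinement sweep completes
in a few minutes on one CPU.

"Average velocity" is the volume-weighted mean speed (a throughput-weighted
variant is exposed behind a flag); the olfactory "region" for velocity is
the dorsal-of-fin-midline cells within the olfactory axial extent, while
olfactory deposition uses the olfactory wall faces — both are reported since
the two readings of "OE region" differ. Percentage differences use the
narrow model as baseline, signs retained internally. Volumetric flow
fractions come from integrating face fluxes over a coronal section split at
the fin midline (the operational dorsal/ventral boundary, overridable).

## What the phantom does and does not emulate

It reproduces the features the paired comparison depends on: a narrow
dorsal channel in parallel with a wider ventral path (the w³ conductance
competition), a non-absorbing vestibule, mucus-lined posterior walls, the
solubility spectrum of the odorant set, and a uniform micrometer-scale
widening. It does not emulate turbinate scrolls or lateral geometry
variation (the phantom is laterally extruded), 3D secondary flows, unsteady
breathing, expiration, or the absolute surface/volume of a real rat nose —
so absolute deposition rates, flow splits and velocities are not comparable
with in-vivo-derived models, and passing tests demonstrate correct
transport physics and correct *directional* sensitivity to widening, not
anatomical accuracy.

## Numerical choices and degenerate inputs

Air properties default to ρ = 1.184 kg/m³, μ = 1.849e-5 Pa·s (25 °C,
1 atm), overridable. Faces are owned by the lower-index cell; boundary
faces by their single interior cell. A cross-section snaps to the nearest
interior grid line; sections in solid tissue raise. Empty dosimetry regions
return zero with a warning; a zero narrow-model baseline makes a percentage
difference undefined (error) while the absolute difference is always
reported. Refinement refuses > 5e6 cells. The grid-refinement verdict
ignores direction reversals smaller than the tolerance (plateau wiggles at
convergence are not "non-monotone").

## Known limitations

- The plug inlet meets no-slip walls at a corner whose singular pressure
  contribution converges slowly under refinement; pressure-drop validation
  against the Poiseuille closed form therefore uses long channels (L/h = 30)
  in the Stokes regime, where the entrance contribution is < 1%.
- The 2D planar geometry exaggerates nothing but also averages nothing:
  channel conductances scale as w³/12 per unit depth rather than with a 3D
  duct shape factor, so the ~4%/+5% velocity shifts and ~1-point flow-split
  gain are phantom-specific magnitudes; only their directions and ordering
  are study conclusions.
- Octane's olfactory deposition difference is a ~0.1–0.4% signal riding on
  matched-mesh cancellation; it is deterministic and positive at all three
  flow rates, but its magnitude should not be over-interpreted.
- The transport solve is linear in c; odorant–receptor kinetics, mucus-phase
  PDE transport and multicomponent mixtures are out of scope.
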