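# Methods

`redwall` simulates blood as a suspension of explicitly resolved, deformable
red blood cells (RBCs) in plasma flowing through rigid-walled microvessel
geometries, and quantifies the wall shear stress (WSS) and its surface
gradient (WSSG) that the flowing suspension exerts on the endothelium.
This note records the model, its discretizations, the defaults and why, the
synthetic-geometry conditions, and the known limitations.

## Governing model

At microvascular scales (diameters 6–24 µm, velocities < 10 mm/s) the
Reynolds number is far below one, so the plasma and hemoglobin phases obey
the unsteady Stokes equations with the continuity constraint:

    rho du/dt = -grad p + div(mu grad u) + f,      div u = 0,

where `f` is the body-force density exerted by the immersed cell membranes
and `mu(x)` takes the plasma value 0.001 Pa·s outside the cells and the
hemoglobin value 0.005 Pa·s inside.  The convective term is omitted.  The
transpose part of the variable-viscosity stress, `div(mu (grad u)^T)`, is
also omitted: it vanishes for uniform viscosity, its explicit treatment
destroys the semi-implicit stability budget, and the wall-stress pipeline is
unaffected because the near-wall stencil lies in the cell-free layer where
the viscosity is uniformly the plasma value.

Each RBC is a closed hyperelastic membrane enclosing hemoglobin solution.
The resting shape is the classical biconcave discocyte with end-to-end
distance 7.8 µm, surface area 134.1 µm² and volume 94.1 µm³; the thickness
profile `T(ρ) = D sqrt(1-ξ²)(a0 + a1 ξ² + a2 ξ⁴)/2`, ξ = 2ρ/D, uses
a0 = 0.207, a1 = 2.003, a2 = -1.123 with a one-time +0.8% amplitude
rescaling because the published coefficients attain the printed area/volume
at D = 7.82 µm rather than 7.8 µm.  In-plane elasticity follows the Skalak
strain-energy law

    W = (G_s/4)(I1² + 2 I1 - 2 I2) + (G_s C_dil/4) I2²,

bending follows the Helfrich energy `(k_b/2)∮(2H - c0)² dA`.  The moduli
are not geometry-derived and default to standard human-RBC literature
values: G_s = 2.5e-6 N/m, C_dil = 100 (near-inextensible membrane),
k_b = 2.7e-19 J, c0 = 0, interior viscosity 0.005 Pa·s.  All are
constructor arguments.

## Discretizations

**Membrane.**  The surface is a subdivided icosahedron mapped to the
biconcave profile (642 vertices at the default subdivision level 3; the
geometry checks use level 5).  Skalak forces are the exact gradient of the
linear-triangle finite-element energy built from reference metrics stored
per triangle.  Bending uses the discrete mean-curvature vector
`m_v = (L0 x)_v / A_v(x)` with the cotangent Laplacian `L0` assembled on
the resting shape and barycentric vertex areas `A_v` of the current shape;
the energy `(k_b/2) Σ_v A_v (|m_v| - c0)²` is scale invariant for c0 = 0
(any sphere scores 8π k_b) and its gradient is closed form, so both force
operators satisfy a central finite-difference check of `force = -∇energy`
to 1e-5 relative.  Freezing the cotangent weights at the reference metric
is accurate here because C_dil = 100 keeps local strains at the percent
level.  Discrete mean curvature carries an O(1) pointwise error at the 12
valence-5 vertices of the icosphere (a documented property of cotangent
operators); residual sphere forces therefore converge in the RMS sense, not
in the max norm.

**Fluid.**  Uniform staggered (MAC) grid, default spacing h = 0.5 µm.  Time
stepping is a delta-form Douglas–Gunn ADI factorization of backward Euler
for the direction-split viscous operator, followed by an incremental
pressure projection; at a fixed point the unsplit steady discrete momentum
equation holds exactly, so steady fixtures are independent of the time
step.  Viscosity coefficients are harmonic means at staggered locations.
The pressure Poisson problem is solved on fluid cells with wall links
dropped (homogeneous Neumann); for axially invariant periodic geometries it
is diagonalized by FFT in x with one factorized 2D system per wavenumber,
otherwise a sparse LU of the 3D operator is used.  The discrete divergence
on fluid cells after projection is zero to solver precision (~1e-12); a
global wall-flux balance projection (an O(h²) correction distributed over
wall-adjacent faces) makes the singular Neumann system exactly compatible.

**Walls (sharp interface).**  Cells of the box with signed distance >= 0
are solid; solid faces within 2h of the wall are ghost faces whose values
are rebuilt every stage by mirror-image reflection `u_ghost = -u(image)`
with the image point at equal depth inside the fluid (trilinear
interpolation, two fixed-point sweeps because images may touch other
ghosts).  The reflection places the no-slip zero at the wall midpoint,
which is second order: the Poiseuille fixture shows observed order >= 1.8
in max-norm velocity error.  Mirror reflection never amplifies interior
values, which keeps the lagged ghost update stable at viscous numbers of
order 100; in the implicit line solves ghost faces are frozen Dirichlet
rows.

**Cell–fluid coupling.**  Continuous-forcing immersed boundary method with
the standard Peskin 4-point kernel (partition of unity, zero first moment:
spreading conserves total force exactly and interpolation is exact on
globally linear fields).  Membrane vertices advect with the interpolated
velocity (forward Euler).  The viscosity indicator is a cosine-smoothed
Heaviside of the signed distance to each membrane (half-width h, i.e. a
transition band of 2h), evaluated inside each cell's bounding box; the same
indicator is the local hematocrit field.

**Boundary conditions.**  Two driving kinds, matching microvascular
practice: a prescribed axial pressure gradient (0.3–1.0 Pa/µm is the
physiological range; tube fixtures default to 0.1 Pa/µm to stay in the
desk-scale velocity range), or a prescribed inlet volumetric flow rate.
In periodic tube boxes the pressure drop is realized as the equivalent
uniform body force and the flow rate by a feedback-controlled body force
holding the metered flux; in capped boxes the flow rate is a prescribed
Poiseuille-like inlet profile with a flux-corrected zero-gradient outflow.
Cells leaving a capped outlet are reinserted at the inlet with their
current shape at a seeded random off-axis position, maintaining the feed
hematocrit; periodic tubes recycle naturally.

**Time step.**  `stable_dt` takes the minimum of a membrane-elastic bound
`0.4 h sqrt(rho h / G_s) / sqrt(mu_int/mu_pl)`, a bending bound
`0.5 h² sqrt(rho h / k_b)` and a plasma accuracy cap (default 25 µs), times
a safety factor 0.5.  The leading constants were calibrated once against
bisection blow-up scans of the coupled tube run at the default moduli and
h = 0.5 µm: without viscosity contrast blow-up sits near 2.8 µs; the 5x
interior/exterior contrast lowers it to ~1.4 µs (harmonic and arithmetic
face averaging behave alike here), hence the 1/sqrt(contrast) factor and a
default coupled step of ~0.63 µs.  C_dil enters through the calibrated
constant.

**Contact handling.**  Lubrication films thinner than the grid spacing are
under-resolved by the 4-point kernel, so membranes carry a short-range
quadratic repulsion (0.3 µm cutoff, 2e-11 N per vertex at full
compression) against the wall and pairwise between cells — the standard
immersed-boundary suspension guard.  Seeding keeps 0.3 µm wall and
pairwise clearances, with whole-configuration restarts until the requested
cell count fits.

## WSS / WSSG pipeline

The time-averaged WSS is computed from the time-averaged velocity field
(samples every 0.5 ms).  At every wall-mesh vertex a local cylindrical
frame is built: ê_r is the inward normal, ê_s the tangential projection of
the velocity probed one stencil-span inside the wall (flagged geometric
fallback at stagnation vertices), ê_θ = ê_r × ê_s.  Traction components
`t_s = mu du_s/dr`, `t_θ = mu du_θ/dr`, viscous `t_r = 2 mu du_r/dr` come
from the one-sided second-order stencil over probe points at 0, span/2 and
span along ê_r, with span 0.3 µm — inside the cell-free layer, hence with
plasma viscosity regardless of cell proximity.  Only t_s (denoted τ) is
dynamically significant; t_θ and viscous t_r sit four or more orders below
it in the straight-tube fixture.  WSS is reported in dyne/cm² (1 Pa = 10).

WSSG components are second-order central differences of τ along ê_s and
ê_θ with endpoints stepped ±span/2, projected back onto the surface
(closest point on the triangulation) and τ interpolated there with the
barycentric weights of the containing triangle — linear-exact on the
surface, which inverse-distance weighting is not.  The difference is
divided by the projected endpoint separation, which also makes the
circumferential `sin θ → cos θ / R` closed form exact on ring meshes.

ROI statistics: `τ̄ = Σ τ dA / A` with barycentric vertex areas as dA; the
per-vessel variability `τ' = sqrt(Σ(τ_i - τ̄)²/(N-1)) / τ̄` (unweighted, as
printed; a coefficient of variation); temporal absolute RMS (vertex mean of
per-vertex fluctuation RMS) and relative RMS (each vertex scaled by the
magnitude of the ROI time-averaged value — magnitude, because signed WSSG
means can vanish).  The RBC-influence map τ̄_RBC/τ̄_pl is defined only for
pairs run under the flow-rate BC (enforced from run metadata) and per-ROI
as the ratio of ROI averages.  Note the deliberate naming split: the
symbol τ' is used in the literature both for the per-vessel spatial
standard deviation and for the absolute temporal RMS; here they are
distinct functions (`vessel_std` vs `temporal_rms`).

Junction statistics: flux gates are discs one feeder diameter downstream
of the junction center (mid-vessel for feeders), flow by polar quadrature
of the time-averaged normal velocity, RBC flux by signed centroid
crossings with the first 20% of the window discarded as transient.  The
disc quadrature against the staircase lumen carries an O(h/R) bias (about
5% per gate at h = 0.5 µm in an 8 µm vessel); partitioning ratios cancel
most of it.  In capped boxes the lateral box faces are solid walls, so
vessels grazing a box edge are walled off and in/outflow happens only
through the x faces; cross-sectional flux on the grid is conserved exactly
because wall (ghost) faces carry the viscous no-slip reconstruction but no
mass flux.  In the
phase-separation regression of N1*-Q1* against τ̄_D1-τ̄_D2, branch 1 is the
higher-Q* daughter (the sign convention is otherwise arbitrary).

## Synthetic geometry (the study conditions)

The generator emulates in-vivo-like microvascular morphometry rather than
any specific imaged network: diameters within 6–24 µm and vessel lengths
within 25–165 µm (enforced invariants), three Strahler orders spanning the
arterial and venous sides, Horton diameter ratio between consecutive
orders (default 1.6, capillary diameter 7 µm, venous vessels 15% wider),
tortuous centerlines (sinusoidal perturbation of amplitude
tortuosity × diameter, default tortuosity 0.3), equal numbers of
bifurcations and convergences, and watertight triangulated walls with open
inlet/outlet caps.  Junction ROI labels extend one feeder diameter from
the junction center (configurable); the visual extent of bifurcation
regions in intravital WSS maps motivates that default.  Tubes are swept
ring meshes (vertices exactly at radius D/2); junctions and networks are
marching-cubes surfaces of capsule-union signed-distance fields, so the
wall mesh, the solver's distance field and the vertex normals are mutually
consistent.  The capsule union blends sharply at junction apexes; apex
fillet geometry is unspecified in the underlying morphometry and sharp
apexes locally exaggerate WSS maxima.

## Desk-scale problem sizes

The package's own study conditions are chosen so every quantity is
recomputable on a single CPU:

- straight-tube fixture: D = 10 µm, L = 24 µm periodic, h = 0.5 µm
  (48×24×24 cells, ~15k fluid cells);
- curved-tube fixture: D = 8 µm, L = 48 µm, sinusoidal bend amplitude 3 µm;
- paired RBC/plasma tube run: feed hematocrit 0.2 (4 cells), matched inlet
  flow rate 2.5e-14 m³/s (mean velocity ~0.3 mm/s), horizon 10 ms (20
  sampling cadences, several viscous relaxation times; cells traverse the
  periodic segment more than once), samples every 0.5 ms, dt from
  `stable_dt` (~0.63 µs with the viscosity contrast);
- networks: 2–3 Strahler orders, ~10 vessels — two to three orders of
  magnitude below the cluster-scale networks (~1.6e6 µm³, 8e7 grid points,
  0.7 s horizons) the full-physiology magnitudes come from.

What passing the desk-scale suite shows: the discrete operators match
their closed forms, conservation holds, and the cell-induced mechanisms
point the right way (profile blunting, WSS increase at matched flow, a
cell-free layer, higher WSS on the high-curvature side of a bent vessel,
larger spatial WSS variability with cells).  What it does not show:
network-level magnitude distributions (e.g. capillary WSS ranges,
venular ratio ~3, circumferential-dominance percentages), which require
the full-scale geometry, hematocrit and averaging horizon.

## Numerical choices and degenerate inputs

- Seeding is random sequential insertion with 0.15 µm wall and 0.1 µm
  pairwise clearances; an unplaceable request returns the achieved count
  (and hence hematocrit) rather than failing.
- Stagnation vertices in the frame builder (tangential probe speed below
  1e-6 of the field maximum) fall back to the owning vessel's centerline
  tangent and are flagged.
- Traction probes that would exit a thin lumen shrink the span by halves
  (at most twice); vertices that still fail are flagged invalid and are
  excluded from ROI statistics.
- WSSG stencils touching cap rings or invalid vertices are flagged.
- The relative temporal RMS is undefined (None) when the ROI time average
  vanishes; `vessel_std` raises on a zero mean.
- Degenerate (zero-area) deformed membrane triangles abort force
  evaluation with the triangle id; NaNs detected during a run abort it
  with the last-good status string.

## Known limitations

- Rigid walls; no glycocalyx/endothelial surface layer, no EC nucleus
  topology, no RBC aggregation, no membrane viscosity or thermal
  fluctuations.
- The bending operator's frozen cotangent weights linearize the curvature
  metric about the resting shape (adequate at percent-level strains).
- The variable-viscosity transpose stress term is omitted (see above).
- Capped-box runs support the flow-rate BC; pressure-driven runs use the
  periodic realization, which is exact for straight/curved tubes only.
- The phase-separation slope and network magnitude distributions at desk
  scale are mechanism demonstrations, not quantitative reproductions.

## Output files and columns

- `roi_summary.csv` (wss/stats/mini-paper): `roi` — ROI label
  (`vessel:<id>`, `bifurcation:<id>`, `convergence:<id>`); `tau_bar` —
  area-weighted mean WSS, dyne/cm²; `tau_std_norm` — normalized per-vessel
  WSS standard deviation τ′ (dimensionless); `wssg_s`, `wssg_theta`,
  `wssg_mag` — ROI-mean WSSG components/magnitude, dyne/cm²/µm; mini-paper
  adds `tau_rbc`, `tau_pl`, `tau_ratio`, `tau_std_rbc`, `tau_std_pl`.
- `rms_summary.csv`: `tau_rms_abs` — vertex-averaged temporal RMS of WSS,
  dyne/cm²; `tau_rms_rel` — the same scaled by the ROI time-averaged WSS.
- `bifurcation_fluxes.csv` (netstats): `junction_id`; `feeder_diameter`
  (µm); `Q_F` — feeder flow, µm³/s; `Q1_star`, `Q2_star` — daughter flow
  fractions; `N1_star`, `N2_star` — daughter RBC-flux fractions (cell-laden
  runs only).
- `vessel_table.csv`: per-vessel geometry (`diameter_um`, `length_um`,
  `order`, `class`) plus `tau_rbc`/`tau_pl` ROI means, `tau_std_*`
  variabilities, `wssg_mag_rbc`, `tau_ratio`, and the `paired` flag.
- `monitors_*.csv` (simulate): per-sample `t` (s), `flow_rate` (m³/s),
  `divergence` (relative), `body_force` (N/m³), total `cell_area` (µm²)
  and `cell_volume` (µm³).
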