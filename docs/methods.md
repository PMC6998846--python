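# Methods

This note records the models behind `valveforge`, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
emulate.

## Coordinate and unit conventions

Right-handed coordinates, z along the flow axis, z = 0 at the valve
annulus plane, positive toward the ascending aorta. Lengths in mm,
velocities in cm/s (the native unit of phase-contrast MRI), flow in mL/s,
pressure in mmHg. STL files are unit-less; every export writes a JSON
sidecar recording the convention and the generating parameters.

## Root geometry

The lumen is described by an inner radius function r(z, θ) built from an
axisymmetric backbone r_base(z):

- LVOT cylinder of radius `lvot_diameter/2` below the annulus, blended to
  the annulus radius over min(0.4·lvot_length, 6 mm) with a C¹ cosine
  ramp. (The backbone must be continuous yet match both the LVOT and
  annulus radii; a short blend reconciles the two.)
- Sinus segment 0 ≤ z ≤ `sinus_height`: cosine blend from annulus to
  sinotubular radius, multiplied by
  1 + a(z)·max(0, cos(nθ − π))^p, with a(z) = A·sin(πz/sinus_height) and
  p = 2 so the bulge meets the inter-sinus lines with C¹ continuity.
  The amplitude A is solved (bracketing + Newton polish) so the maximal
  lumen radius equals `sinus_max_diameter/2` to ~1e−9 mm.
- Sinotubular junction blended to the ascending aorta radius over
  min(0.4·aorta_length, 8 mm); constant beyond.

With all diameters equal the solve returns A = 0 and the profile
degenerates to a straight tube — used as a test fixture throughout.

Default dimensions are literature-typical adult values (annulus 23 mm,
sinus max 34 mm, sinus height 20 mm, STJ 26 mm, ascending aorta 28 mm,
LVOT 22 mm); wall 2.0 mm and leaflet 0.6 mm are the anchored thicknesses.
All are overridable via JSON config, and the STL sidecar records them.

### Wall shell

The printable wall is the solid between the lumen surface and its offset
by `wall_thickness` along the exact surface normals of the implicit
surface r = ρ(z, θ) (n ∝ ê_r − (ρ_θ/ρ)ê_θ − ρ_z ê_z), closed by annular
caps at the inlet and outlet rims. Offsetting along true normals makes
the inner-to-outer distance equal the nominal thickness up to curvature
terms of order t²·κ (≪ 1 % here). The shell of an open tube is
topologically a torus: watertight with Euler characteristic 0. Mesh
orientation is fixed by construction and verified by the signed volume.
Default resolution 120 axial × 192 circumferential stations.

### Leaflets

The closed leaflet is a *graph* over its 2π/n sector in polar
coordinates: z(ρ, θ) = z_apex + ρ²·(z_att(θ) − z_apex), where ρ is the
radius normalized by the attachment radius at θ, z_apex =
`leaflet_height − leaflet_free_edge_sag` is the coaptation apex on the
axis, and the attachment height z_att(θ) = h·cos²(πθ/Δθ) − drop·K(θ)
arches from the commissures (top) to the annulus nadir, with a Gaussian
blend K (σ = 0.18 of the sector) dropping the commissure ends by
0.35·`coaptation_height` to the coaptation level. The attachment row
lies exactly on the lumen wall (radius = r(z_att, θ)).

Why a graph and not a lofted ruled surface: a loft between the attachment
and free-edge curves concentrates twist at the commissure corners, where
its curvature is unbounded; offsetting such a sheet by ±t/2 self-
intersects there, and no uniform-thickness shell exists. The graph has a
bounded Hessian, hence bounded curvature (max ≈ 0.45 mm⁻¹ with the
defaults, comfortably below the 1/(t/2) ≈ 3.3 mm⁻¹ limit), so the ±t/2
offset along its *analytic* normals is globally valid. Measured by
inward ray casting, the shell is 0.6 mm within a fraction of a percent
everywhere, including the coaptation apex (welded into a single vertex)
and the commissures.

The free edges of the closed valve are the radial sector borders — the
Y-shaped closure pattern seen from above — so adjacent free-edge
midpoints coincide on the axis (within 0.05 mm by construction; the
shells of coapting leaflets interpenetrate slightly, as touching leaflets
should in a kinematic model).

The open state is a ruled loft from the same attachment row to a
wall-hugging free-edge arc just below the commissure level with a 1.8 mm
radial clearance (smaller clearances degenerate the sheet where the
attachment crosses the free-edge level). `open(fraction)` blends the
closed and open grids linearly — a kinematic morph for visualization and
orifice-area estimates, not leaflet mechanics; intermediate shapes carry
no physical meaning.

Leaflet i is leaflet 0 rotated by i·2π/n, so the n-fold symmetry of the
assembly is exact. The assembly is a labelled collection of disjoint
watertight bodies (wall + n leaflets), matching a multi-material print;
no boolean union is performed.

### Diagnostics

`mesh_diagnostics` reports watertightness, Euler characteristic, volume
(via trimesh) and minimum shell thickness by casting a ray from each face
centroid along the inward normal to the first self-hit (chunked
Möller–Trumbore; components of an assembly are cast against themselves
only, since coapting components legitimately overlap). Ray counts are
configurable; the full-face census on a default leaflet takes a few
seconds.

## Pump waveform and afterload

q(t) is a half-sine lobe q = peak·sin(πt/T_sys) on [0, T_sys], optionally
followed by a negative half-sine dicrotic lobe (depth fraction < 0.2,
default off), zero through diastole. Three settings pin the default:
peak 100 mL/s, 60 beats/min, and cycle-mean 27.74 mL/s; the closed-form
mean 2·peak·T_sys/(π·period) is inverted to get T_sys = 0.43574 s. The
sampled cycle (1000 points) integrates by the periodic trapezoid rule to
the target within ~1e−4 mL/s. The waveform object also carries the exact
analytic evaluator, whose maximum is exactly `peak_flow`.

The open-circuit afterload converts a water column to pressure with the
fixed density ratio 13.5951 mm H₂O per mmHg (reference conditions;
temperature correction out of scope): 1088 mm → 80.03 mmHg.

## Velocity synthesis

The voxel grid stores, per frame, three velocity components (cm/s) plus a
lumen mask (voxel-center membership; no partial-volume weighting). Frames
are instantaneous samples of q at uniform frame centers over one cycle —
no view-sharing or temporal blur.

Bulk flow runs in the axisymmetric backbone tube R(z) = r_base(z):

- parabolic (default): v_z = 2q/(πR²)·(1 − (r/R)²),
- plug: v_z = q/(πR²),

both with the radial closure v_r = v_z·r·R′(z)/R(z). That closure is the
exact solution of the continuity equation for either profile (integrate
(1/r)·∂(r v_r)/∂r = −∂v_z/∂z), so the analytic field is divergence-free
and every transverse plane carries exactly q(t). Sinus bulge pockets
outside the backbone hold no bulk flow — physically the recirculation
region — which keeps the flux statement exact for any plane. A Womersley
profile is a possible extension; the parabolic default was chosen because
its closed-form flux relation anchors the quadrature oracles.

The sinus vortex is an azimuthal swirl about the circumferential axis
through each sinus center (placed at the axial station of maximal bulge,
45 % into the pocket): v_φ(ρ, s) = 10·Γ/(2πρ)·(1 − e^(−ρ²/a²))·taper(ρ)·
taper(|s|), with Γ = 10 cm²/s (swirl speeds ~9 cm/s at the 1.8 mm
reference loop — the order of diastolic sinus vortex speeds), core
a = 0.75 mm, smootherstep tapers holding the support inside the pocket
(plateau 1.9 mm, zero at 2.4 mm radially; 1.5/3.0 mm axially). Any field
of the form v_φ(ρ, s)·φ̂ is exactly solenoidal, so the circulation is
prescribed analytically and verified by a Stokes-loop integral. The
vortex is gated on smoothly when q(t) < 10 % of peak (full strength below
2 %), i.e. in diastole.

Phase-contrast encoding: phase = wrap(π·v/venc) to the half-open interval
(−π, π]; decode multiplies back. v = +venc and −venc both map to +π —
the boundary convention is fixed and tested. Velocities beyond ±venc
alias by multiples of 2·venc; no unwrapping is provided (a documented,
tested failure mode of plane quantification). Default vencs: 100 cm/s
(volume protocol), 70 cm/s (single-slice protocol). Gaussian noise of
configurable SD is added per component inside the lumen only, seeded.

The default desk-scale grid is 64³ over the phantom (≈ 0.7 mm in-plane,
1.9 mm axial); the tabulated full-protocol sizes (e.g. 1.6 mm isotropic)
are available through `AcquisitionParams`. NIfTI-1 is the interchange
format (one 4D file per component + mask + JSON manifest with venc, frame
times and units).

## Quantification

Plane flow: a square window of samples (default step 0.2 mm) masked by
trilinear lumen-mask interpolation ≥ 0.5; Q = Σ (v·n)·step² with the
cm/s·mm² → mL/s conversion. The quadrature error is O(step²) on smooth
fields; the voxelized rim contributes ~h/(2R) relative error, so oracle
comparisons against analytic fluxes use grids fine enough for the stated
tolerances. Net flow = cycle mean (uniform periodic frames → plain frame
average; "net flow" is reported in mL/s to match the pump programming,
with per-beat forward/backward volumes in mL alongside). Regurgitant
fraction = backward/forward volume (0 when no forward volume).
Conservation = |net_a − net_b| / max(|net_a|, |net_b|); on the noise-free
default dataset it is ~5e−4, and plane position anywhere in the straight
segments changes net flow by ≪ 2 %.

Pathlines: classical fixed-step RK4 on dx/dt = v(x, t), trilinear in
space, linear in time between frame centers with periodic wrap; default
dt = period/200. Particles terminate on leaving the lumen mask
(`left_mask`) or the grid (`left_grid`); seeds outside the grid terminate
immediately rather than raising. RK4 is exact for uniform fields and
conserves a solid-body-rotation orbit radius to O(dt⁴); both serve as
oracles, as does the winding number of a seed captured by the diastolic
sinus vortex.

Circulation: the line integral of trilinear velocity around a circle
(default radius 1.8 mm, 720 samples) centered on the sinus vortex in the
plane normal to the local circumferential direction; positive for
counter-clockwise swirl about that direction (right-hand rule). On the
analytic vortex this equals Γ·(1 − e^(−ρ₀²/a²)) ≈ 0.997·Γ at the default
loop. A λ2-style vortex detector is deliberately not provided; the
circulation loop is the quantitative metric.

## Fixtures and problem sizes

`make_fixture` returns self-contained configurations: `straight_tube`
(32³, 10 frames small), `default_phantom` (48³, 12 frames small; 64³,
20 frames full) and `vortex_only` (48³ zoom over one sinus at 0.33 mm).
The acceptance computation uses 64³ × 20 frames with 0.2 mm plane
sampling; each small fixture completes in seconds on one CPU. These sizes
were chosen so quadrature and interpolation errors sit well inside the
stated tolerances while the whole suite stays desk-scale.

## What the synthetic data are not

No MR physics: no k-space, parallel-imaging reconstruction, eddy-current
or background-phase models, no intravoxel dephasing, no partial-volume
averaging, no view sharing. No fluid–structure interaction: leaflet
motion is a kinematic morph and the velocity model does not react to
leaflet position. Flow profiles are idealized (parabolic/plug, no
Womersley inertia, no turbulence or valve jet). Consequently, passing
tests demonstrate that the *measurement machinery* (quadrature,
integration, encoding, meshing) is correct against known ground truth —
not that real scanner data would yield these numbers. The in-scanner
measurements of a physical phantom depend on hardware and reconstruction
and are out of scope; the corresponding consistency properties
(proximal/distal agreement, program-vs-measurement agreement) are what
the package reproduces.
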