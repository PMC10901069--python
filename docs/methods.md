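# Methods

This note records the models, numerical choices, and limitations behind
`scan2fem`, in the order the pipeline runs.

## Scan model and I/O

A scan is a triangulated surface with one RGB color per vertex, read
from ASCII or binary-little-endian PLY (big-endian files are rejected
explicitly rather than silently mis-parsed; handheld scanner apps emit
little-endian).  Coordinates are millimeters; a file whose bounding-box
diagonal is under 10 units is interpreted as meters and scaled, since a
thorax is never 10 mm across.  Zero-area triangles are removed on read.

Cropping keeps vertices inside an optional projected polygon and/or a
z-slab, drops faces touching removed vertices (no clipping — the belt
margin makes partial faces irrelevant), and keeps only the largest
face-connected component, which removes floating scan debris.  Crop is
idempotent by construction.

## Fiducial detection and numbering

Sticker pixels are classified by nearest reference color in RGB space,
gated by a Euclidean tolerance (default 60; the stickers are saturated
primaries while skin is not, so generous tolerance beats per-scan
tuning).  Clusters are connected components over mesh edges; those
below a minimum vertex count (default 5) are discarded and the rest are
reduced to centroids projected back onto the surface.

Numbering sorts all candidate points by azimuth about their centroid in
the plane normal to the leveling axis.  The winding direction is the one
along which the anchor numbers (7, 12, 17, 22, 27, 32) increase
cyclically; no global handedness convention is assumed, so mirrored or
upside-down scans label identically.  Whites between consecutive anchors
receive the interpolated numbers; when a segment holds fewer points than
slots (occluded stickers), the assignment that minimizes the variance of
per-label-step angular spacing is chosen by exhaustive enumeration
within the segment (at most C(6, k) candidates).  An inconsistent anchor
ordering or an overfull segment is a hard error — both indicate a
mis-detected anchor.

## Leveling

The electrode plane is the total-least-squares plane (smallest right
singular vector of the centered electrode matrix).  The rigid map is the
minimal rotation taking that normal to +z — no in-plane spin — plus the
translation taking the electrode centroid to the origin.  The azimuth of
electrode 1 after leveling is stored as transform metadata for
consumers that want a body-fixed angular origin; nothing downstream
requires it to be applied.

## Boundary model

The fitted surface is the star-shaped radius field

r(θ, z) = Σ_{m=0..2N} Σ_{k=1..M} C[m,k] ψ_m(θ) φ_k(z)

with ψ the real Fourier basis and φ a **constant plus M−1 Gaussian
kernels** at uniform heights, width 1.5× the kernel spacing.  The
constant term matters: a pure wide-Gaussian basis cannot represent a
z-independent radius better than ~0.6% ripple, so a plain cylinder would
fit with ~1 mm bias; the polynomial augmentation (standard in RBF
approximation) removes it while keeping the parameter count
(2N+1)·M = 175 at the defaults N = 12, M = 7.

The fit is linear least squares on all vertices converted to
(θ, z, r), solved by blocked QR accumulation — the Gaussian height basis
is nearly collinear, and normal equations would square an ~1e8 condition
number into noticeable error — with a tiny ridge (1e-10, conditioning
only).  Consequences of the collinearity: individual coefficients are
only identifiable up to the basis's near-null space; the radius field is
what is reproducible.  The star-shape assumption (single-valued r per
(θ, z) about the leveled centroid) holds for a thorax at belt level;
violations are averaged by the least squares.

`signed_distance` defaults to the radial gauge ρ − r(θ, z): exact on the
surface, negative inside, cheap enough for remeshing loops.  The exact
variant refines the magnitude by nearest-point optimization seeded from
a KD-tree over a dense surface sampling, and is used for
contour-to-fit distances.

## Remeshing

Force-equilibrium (truss) remeshing: Delaunay connectivity, bar forces
F = max(ℓ₀ − ℓ, 0) toward a sizing field h(x), explicit Euler steps
(dt = 0.2, Fscale = 1.2), nodes reprojected to the geometry each
iteration.  For the belt-band tube, connectivity comes from a periodic
2D Delaunay triangulation in an arc-length × height parameterization
(ghost copies across the seam); for closed convex surfaces (the sphere
used in calibration tests), from the convex hull.  The sizing field is
h_electrode inside one disc radius of any electrode center, ramping
linearly to h_background at three radii; the ramp extent is a mesh
grading choice, not a physical one.  Electrode centers and rim rings
(circle of geodesic radius in the tangent plane, reprojected) are fixed
nodes, so each disc boundary is resolved by edges.  Boundary rings at
both z limits are fixed too, with a small seeded inward z-jitter, and
free nodes clamp to per-node randomized margins — exactly coplanar
rings otherwise produce degenerate flat tetrahedra downstream.
Iteration stops when the largest displacement falls below
1e-3·h_background or at the iteration cap; the report carries the
movement log and a convergence flag, and only a NaN collapse (or
`strict=True`) raises.

## Volume meshing

The spec of the original workflow delegates tetrahedralization to an
external generator; here an internal one is used: 3D Delaunay of the
surface nodes plus graded interior seeds (an inward offset layer
mirroring the surface spacing, a jittered background grid, and cap
seeds with a small inward offset), keeping tetrahedra whose centroid is
inside the capped solid.  Two robustness passes follow: *peeling* of
tets whose boundary face has edges far larger than the local sizing
(on nearly developable patches the hull can glue a flat tet over a
finely sampled disc), and *pinch repair* that re-adds dropped slivers at
non-manifold boundary edges.  Surface nodes get a ~2e-3·h tangential
jitter (reprojected onto the model, so geometry is preserved) to break
cospherical degeneracies of idealized inputs.  Electrode labels
transfer to boundary facets by the same geometric disc rule used on the
surface: a facet belongs to a disc if all vertices are within 1.05 r
and its centroid inside, or if it crosses the rim with its majority
inside.

Known limitation: on noisy scans a handful of near-degenerate slivers
can remain (the builder logs a warning when the minimum radius-ratio
quality falls below `quality_floor`); they are harmless for volume and
boundary statistics but locally degrade FEM accuracy.

## EIT forward model and imaging

Linear (P1) finite elements with the complete electrode model: per-tet
stiffness σ∇u·∇v, boundary mass and coupling terms on each electrode
patch with contact impedance z_c (default 1e-3 Ω·m² for every
electrode), electrode potentials as unknowns, and a Lagrange multiplier
enforcing the zero-mean electrode-potential gauge.  Coordinates convert
to meters internally; conductivity is real-valued at a single frequency
(the 195 kHz carrier is metadata).  The protocol is pairwise skip-4
injection on 32 electrodes at 3 mA, with voltages read on the same skip
pattern excluding pairs touching the injecting electrodes
(29 × 32 = 928 channels).  Reciprocity holds to solver precision
(~1e-11) because the assembled system is symmetric.

The sensitivity matrix uses the adjoint formula
J[m,e] = −(1/I)∫_e ∇u_drive·∇u_meas dV; measurement pairs reuse the 32
injection-pattern solves.  The exact linearity that "doubling σ halves
the voltages" requires co-scaling 1/z_c; with fixed contact impedance it
holds to a few percent.

One-step Gauss–Newton difference reconstruction normalizes by the
baseline — b = (v₁−v₀)/v₀, J row-normalized by v₀ — and solves
δσ = Jₙᵀ(JₙJₙᵀ + λ s I)⁻¹ b via the push-through identity (measurement
space, 928², instead of element space).  λ is expressed relative to the
mean diagonal s of JₙJₙᵀ; the default 0.03 was fixed once by an L-curve
sweep on synthetic two-lung data and is deliberately not auto-tuned per
data set.  Tidal images average the frames at inhale peaks and exhale
troughs of the global signal Σ|v| (prominence-based peak detection,
minimum breath separation 0.5 s) and reconstruct inhale against exhale,
so air-filled lungs appear as negative δσ.  The channel filter masks
channels whose temporal standard deviation exceeds 25% of their mean
magnitude — breathing modulates channels by a few percent, so anything
larger is electrode noise — and errors out if fewer than half survive.

CEM voltages converge slowly in h near the electrode rims (the current
density is singular there); meaningful convergence checks need
h_electrode ≲ r/5, which is why the production sizing is 0.5 mm on 5 mm
discs and why the refinement test runs on a small 8-electrode tube.

## Synthetic phantom

The generator emulates the study conditions: an elliptic cylinder
(perimeter solved by bisection to the requested value, axis ratio
1.0–2.0) plus two low-order azimuthal bumps varying smoothly with
height, triangulated at 1 mm resolution by default; 32 stickers of 6 mm
radius at equal arc spacing on the mid-band, anchors colored per the
belt scheme; skin-colored elsewhere.  Defaults (1000 mm perimeter,
axis ratio 1.2, 130 mm band) sit in the adult range of belt perimeters
77–105 cm and axis ratios 1.1–1.5.

Scanner noise is a smooth random displacement field (8 seeded
low-order Fourier modes in θ and z, 90% of the variance) plus i.i.d.
jitter (the rest), summing in quadrature to `vertex_noise_sd`.  This is
deliberate: handheld scans err mainly through slowly varying
registration drift; i.i.d. noise alone would average out over a
sticker's ~100 vertices and make electrode localization unrealistically
easy.  Color noise is i.i.d. Gaussian applied after sticker painting.
What the phantom does **not** model: photographic texture, scanner loop-
closure artifacts, holes, clothing, or breathing motion during the
scan — so passing tests bound algorithmic error, not device error.

Tracked ground truth adds isotropic noise to the analytic electrode
centers and removes an occlusion set (mirroring electrodes hidden by
the belt buckle); front/back contours sample the analytic surface above
the belt.  EIT sequences oscillate two ellipsoidal lung regions as
σ(t) = σ₀(1 − depth·(1+sin 2πft)/2), solving the forward model at 9
inflation levels and interpolating to the ~48 Hz frame clock, then
applying multiplicative noise.  Everything is deterministic per seed.

## Problem sizes

Tests and the acceptance script run at reduced scale chosen as the
package's own trade-off between coverage and turnaround: phantoms at
2 mm scan resolution (~35 k vertices), meshes at h = 2–3 mm near
electrodes and 10–15 mm background (~10⁴ nodes, ~5–7·10⁴ tets), 20-seed
noise ensembles, and 20–50 reconstruction trials.  The production
defaults (1 mm scans, 0.5/5 mm meshing, ~10⁵–10⁶ elements) exercise the
same code paths.
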