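# Methods

This note documents the models, parameter choices and numerical decisions
behind `cranioplan`, and what the synthetic phantom does and does not show
about clinical data.

## Coordinate and unit conventions

All geometry is in world millimetres, right-handed. STL itself carries no
units; the package fixes mm because CT-derived skull surfaces are exported
that way and because evaluation volumes are reported in mm³. Stored STL
facet normals are ignored everywhere — orientation comes from the
counter-clockwise vertex winding, since exporters frequently write
inconsistent normals. Vertex welding merges coordinates equal after
rounding to the weld tolerance (default 1e-6 mm); grid rounding rather than
nearest-neighbor search keeps the result deterministic and independent of
vertex order.

## Mirror template

The template is the defect skull reflected across the midsagittal plane.
The plane is part of the *input* specification (a point and unit normal in
input coordinates, or three landmark points); the pipeline translates it
along with its internal bounding-box centering. This matters: centering a
defect skull by its bounding box is biased toward the intact side (the
missing bone shifts the box), and a plane interpreted in the centered frame
would displace the template by twice that bias. There is no automatic
midsagittal-plane detection; an optional closed-form Procrustes (Kabsch)
landmark registration can rigidly refine the template, replacing the manual
re-translation a user would do interactively. Clipping against a plane
drops faces that straddle it instead of splitting them — clipping is only a
candidate filter / inspection aid, never part of the implant geometry.

## Markers

Markers carry a type in {0, 1, 2, 3} = outer edge, inner edge, outer
surface, inner surface. Layer (outer {0, 2} / inner {1, 3}) and border
(types {0, 1}) are derived from the type. Interactive clicking is replaced
by two deterministic operations:

* **Edge markers** resample a detected rim loop at arc-length-uniform
  positions, starting at the loop's first vertex, so they lie exactly on
  the rim polyline. Rim loops come from boundary-edge traversal (edges used
  by exactly one face), ordered along face winding and sorted by descending
  polyline length; on the standard phantom the longest loop is the outer
  table rim.
* **Surface markers** are drawn area-weighted and uniformly within faces of
  the template whose centroids lie inside a sphere around the defect
  (center: outer-rim centroid; radius: 0.9× the max center-to-rim distance,
  keeping samples inside the defect footprint). Inner-surface markers are
  outer samples offset inward along the face normal by the shell thickness
  (default 4 mm). This offset is this package's construction: mirrored STL
  templates frequently do not resolve the inner table, so the inner layer
  is synthesized from the outer one.

The CSV format (`x,y,z,type`, 12 significant digits) round-trips
byte-identically; a JSON variant mirrors the same fields.

## Constrained Laplacian smoothing

One iteration replaces every surface marker simultaneously (Jacobi) by

x_i = Σ_j w_j x_j / Σ_j w_j

over its neighbors j: markers of the same layer within radius `radius_x`
(inclusive ≤), excluding i itself; w_j = `border_weight_y` ≥ 1 for edge
markers and 1 otherwise. With all weights 1 this is the plain Laplacian
mean x_i = (1/N) Σ x_j. Edge markers never move. A surface marker with no
neighbor in radius keeps its position; coincident markers contribute like
any neighbor. The operation refuses to run on fewer than three markers.
Simultaneous updating was chosen over in-place sequential updating because
it makes the result independent of marker order and directly testable;
neighborhoods are recomputed from current positions each iteration.

Defaults: `radius_x` 6 mm, `border_weight_y` 2, 1 iteration. The radius is
deliberately *below* the mean inter-marker spacing of the default marker
budget (~10 mm): at that scale one pass consolidates locally clumped
samples and damps sampling jitter, whereas radii of one-to-two spacings
average across the patch and measurably contract the thin shell toward its
rim (smoothing-induced shrinkage that the fixed edge markers can bound only
at the boundary). These defaults are the package's standing replacement for
the per-case interactive tuning of x and y, calibrated once on the standard
phantom.

## Implant meshing

The marker cloud is deduplicated (1e-6 mm grid rounding) and
tetrahedralized with Qhull's Delaunay construction; input with affine rank
< 3 is rejected, and a cospherical degeneracy reported by the backend
triggers one retry with a deterministic 1e-9 mm jitter from a fixed seed.
Alpha filtering keeps tetrahedra with circumradius ≤ α (α = `None` keeps
the convex hull); removing every tet is an error that reports the minimum
circumradius so the user can pick a feasible α. The boundary surface is the
set of triangles incident to exactly one kept tet, wound away from the
owning tet's centroid, so its signed volume equals the summed tet volumes.

Two cleanups make the exported implant a single printable solid: only the
largest face-connected tet component is kept, and "pinched" boundary edges
(an edge where four boundary triangles meet because the tet ring around it
was only partially kept) are repaired by discarding, per pinched edge, the
incident tet with the largest circumradius until the boundary is
edge-manifold. Both steps are deterministic and are applied (iterated to a
fixed point) in the pipeline; the low-level operations are also available
separately.

The pipeline's default α is 20 mm, about twice the expected inter-marker
spacing at the default marker budget: large enough that the two-layer shell
stays one solid, small enough to carve the template's concave inner side
out of the hull. An unfiltered triangulation (α = `None`, the low-level
default) reproduces the convex hull of the markers, which fills the skull's
concavity and is not a usable thin-shell implant — α, like the smoothing
parameters, is a method parameter meant to be adjusted per case.

## Voxel metrics

Meshes are voxelized on an isotropic grid (default spacing 0.5 mm,
bounding box padded by one voxel, or a caller-supplied shared grid). A
voxel is occupied iff its center is inside the surface by parity ray
casting along +x; the ray origins are offset by 1.0e-7 mm in y and
1.618e-7 mm in z — deterministic and incommensurate, so a ray can never
track a mesh edge (such as the diagonal of a quad split into two
triangles, where a symmetric offset would count the crossing twice).
Non-watertight meshes are rejected since containment is undefined. Dice is
reported in percent to two decimals; the Hausdorff distance is the
symmetric max-min distance between occupied-voxel *center* sets divided by
the spacing, i.e. in voxel units. Volumes are voxel count and
count × spacing³. The spacing default is a package choice; published
voxel-unit distances from other planning studies depend on their
(often unreported) spacing and are not comparable across grids.

## Synthetic phantom

The phantom emulates exactly the geometric features the pipeline relies
on, and nothing else: an ellipsoidal outer table (subdivided icosphere
scaled to semiaxes 75 × 95 × 70 mm), an inner table offset 4 mm inward
along area-weighted vertex normals (locally uniform thickness, unlike a
scaled ellipsoid), an optional left/right asymmetry (x-coordinates of the
x > 0 half scaled by a factor; real heads are asymmetric enough that pure
mirroring never fits exactly), and a defect wedge: all faces whose outward
centroid direction lies within 25° of the +x axis are removed, leaving two
open rim loops. The removed wedge closed by a rim wall is the ground-truth
patch; the complementary closed solid is also returned, and the three
signed volumes satisfy truth + rest = intact exactly by construction. At
subdivision 4 the defect spans ≈ 65 mm across — a moderate lateral defect —
and generation takes well under a second.

What passing the phantom tests does **not** show: performance on real CT
anatomy (no sutures, no variable table thickness, no irregular rim
geometry, no noise or segmentation artifacts), robustness of midsagittal
plane estimation (the phantom's symmetry plane is known), and nothing about
clinical usability. The phantom's role is to verify the pipeline's
geometric contracts and give a reproducible end-to-end fidelity score
(Dice ≥ 85 % against the ground-truth patch at 0.5 mm spacing across
seeds, typically 85–91).

## Questionnaire statistics

The bundled fixture holds the raw 1–6 Likert ratings of three raters on 11
usability items. The summary reports the arithmetic mean and the standard
error of the mean computed from the population standard deviation
(divide by n), both rounded half-up to two decimals — this convention
reproduces the published two-decimal summary for every mean and for 9 of
the 11 error values; the remaining two (computed 0.8165) appear truncated
to 0.81 in print rather than rounded to 0.82 and are kept as documented
exceptions. The published per-rater planning times are not part of the
fixture: their printed mean (17.83 min) is inconsistent with the printed
raw times (30, 20, 4 → 18.00), so no statistic over them is asserted.

## Problem sizes and determinism

Default test and acceptance runs use the subdivision-4 phantom
(10 240 shell faces), 128 markers (24 + 24 edge, 40 + 40 surface) and
0.5 mm voxel grids (~2–3 × 10⁵ occupied voxels), which keeps a full
pipeline-plus-scoring run in the low seconds on one CPU. One top-level
seed fans out (via seed sequences) to every stochastic substep — surface
marker sampling and the degeneracy jitter — so a given config and seed
produce byte-identical STL output.

## Known limitations

* No DICOM/CT input and no surface extraction from volumes; STL only.
* Clipping never splits triangles; clipped surfaces are for inspection and
  candidate filtering, not measurement.
* The smoother acts on the marker point cloud, not on mesh connectivity;
  there is no Taubin-style shrinkage compensation beyond the fixed rim.
* Alpha filtering with a poorly chosen α can disconnect the complex; the
  pipeline then keeps the largest component, which may be smaller than
  intended — inspect the per-stage tet counts in the plan report.
* Inner-table markers are synthesized by a constant-thickness offset; real
  skull tables vary in thickness.
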