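# Methods

`mouldforge` turns a segmented CT or MRI volume of a pelvic lesion into a
3D-printable tumour replica, a patient-specific slicing mould, and
real-size per-slice outline drawings.  The mould constrains tissue
slicing to the anatomical axial plane so that each physical tissue slice
corresponds to an axial imaging plane, making radiology–pathology
co-registration a single fixed in-plane rotation per case.  This note
documents the model, the conventions, the tunable parameters, and the
limits of what the synthetic tests demonstrate.

## Coordinate model

Arrays are indexed `(slice, row, col)`; patient space is DICOM LPS in
millimetres.  An `ImageVolume` carries origin, per-axis spacing and an
orthonormal direction matrix whose *columns* are the patient-space unit
vectors of the array axes.  Inside/outside questions are always decided
by voxel-centre sampling, which matches the 0.5 iso-level convention of
marching cubes; one rasterisation convention is used throughout.

The print-bed world coordinate system (WCS) has **x** along the patient
craniocaudal axis (+x superior; slicing planes are constant-x planes,
i.e. anatomical axial planes), **z** vertical (up; the mould base faces
−z) and **y** completing a right-handed frame.  Oriented masks are
stored as `(x, y, z)`-indexed 1 mm arrays with an explicit WCS origin
and an exact rigid transform back to patient coordinates.

## Orientation

1. **Isotropic resampling.**  Image and masks are re-sliced to an
   axis-aligned 1×1×1 mm LPS grid with zero-order (nearest-neighbour)
   interpolation, making downstream geometry independent of the scan's
   reconstructed slice thickness.  The grid is anchored to integer
   patient-space millimetres; this phase-locking makes the sampling
   lattice reproducible across rigidly related inputs, so the pipeline
   is exactly equivariant under lattice rotations of its input.
2. **Base-at-bottom rotation.**  A single in-plane rotation about the
   craniocaudal axis aligns the unit vector from the tumour centroid to
   the base-ROI centroid with "down".  Centroids are taken from the
   native-resolution masks (typically 0.7–0.9 mm in-plane), not the
   1 mm resampled ones, because the angle estimate inherits their finer
   quantisation; the lever arm between the two centroids is short, so
   centroid noise converts directly into angle error.  The rotation
   pivot is snapped to the mm lattice to avoid systematic half-voxel
   sampling ties.  Without a base ROI the angle is supplied manually
   (`manual_rotation_deg`; 0 keeps the axial plane untouched, positive
   angles rotate the assumed base direction from patient-posterior
   towards patient-left).  If both are given, the base ROI wins.
3. **WCS permutation and crop.**  A pure axis permutation/flip (no
   resampling) brings the arrays into WCS order; they are cropped to
   the tumour bounding box plus `crop_margin_mm` (default 5 mm).  Every
   step composes its exact rigid transform into `to_image`, verified to
   invert to 1e-6 mm.

## Tumour modelling

The 0.5-level surface of the (zero-padded) binary mask is extracted
with the classic Lorensen–Cline marching cubes and relaxed with
uniform-weight ("umbrella") Laplacian smoothing: each pass moves every
vertex by λ·(neighbour mean − vertex), λ = 1 by default.  Note that
marching cubes on a binary field cuts voxel corners: an isolated voxel
meshes to the octahedron through its face centres (1/6 mm³), and small
spheres are undershot by up to ~10 % at r = 5 mm, shrinking to ~2 % by
r = 20 mm.

**Smoothing iterations** default to 3.  λ = 1 smoothing shrinks a
lesion-sized blob by roughly 0.8–0.9 % in volume per pass; three passes
remove most of the 1 mm staircase (the surface-distance RMS roughly
halves and the surface area plateaus) while keeping the smallest
pilot-scale lesions (≈7 cm³, where smoothing bites proportionally
hardest) within a 4 % volume error.  More iterations give a visually
smoother replica at the price of shrinkage; the count is exposed as
`smoothing_iterations`.  A warning is raised for lesions under 15 cm³.

The convex hull of the smoothed replica is the shape the cavity is
carved around: bridging concavities gives the specimen an unambiguous
resting position and a cavity the knife can pass through.

## Mould design

All lengths in mm; defaults in parentheses.

| parameter | default | meaning |
|---|---|---|
| `slice_thickness_mm` | 10.0 | tissue slice width; 5.0 for finer sampling |
| `slit_width_mm` | 1.0 | knife slit width (0.5 proved too narrow for a tissue knife) |
| `cavity_height_fraction` | 0.8 | fraction of tumour height the cavity walls cover |
| `wall_thickness_mm` | 3.0 | cavity/guide wall thickness |
| `baseplate_offset_mm` | 5.0 | in-plane rim the baseplate extends beyond the structures |
| `baseplate_thickness_mm` | 3.0 | plate thickness |
| `guide_height_clearance_mm` | 2.0 | guide walls rise this much above the specimen |
| `incision_depth_fraction` | 0.25 | orientation-incision depth as a fraction of tumour height; 0 disables, ≥0.5 rejected (would bisect slices) |
| `cavity_clearance_mm` | 0.5 | inflation of the hull so the specimen drops in |
| `voxel_pitch_mm` | 0.5 | CSG evaluation grid pitch |

Wall thickness, plate offset/thickness, clearances and the incision
depth are printability-driven choices for desktop FDM printers, not
measured quantities; all are exposed in the configuration.

**Slit plan.**  One slit at the tumour centre, further slits at
`slice_thickness_mm` intervals either side while they fall within the
tumour's x-extent.  This reproduces the length ÷ thickness count when
the quotient is odd and deviates by one for even quotients — central
alignment takes precedence.  A lesion shorter than one slice thickness
gets a single central slit with a warning.

**Cavity.**  The void is the clearance-inflated hull, accumulated as a
running union from the cavity floor upward, then truncated by the block
at rim height `z_floor + cavity_height_fraction × height`.  The running
union is what makes the walls rise vertically above the widest
horizontal contour instead of following a narrowing hull; the void
cross-section is non-decreasing with height *by construction*, so the
rim opening is never narrower than the widest part of the specimen and
slices cannot overspill.  For a widest-at-base dome this correctly
degenerates to a cylindrical cup.  Hull inflation offsets vertices
along outward normals — for a convex solid this approximates the
Minkowski sphere sum, under-reaching only at sharp edges, and keeps the
void expressible as an OpenSCAD `polyhedron`.

**Guides.**  The slicing guide is a wall along the −y side carrying one
slit per plan entry; slit voids span the full y-extent and run from
above the guide top to the cavity floor, so a knife reaches the
baseplate everywhere ("projected" slits).  The two orientation guides
are end walls perpendicular to x whose collinear slits sit at the
tumour centroid y, with the void bottom at
`z_top − incision_depth_fraction × height`; a knife drawn between them
scores one straight partial-depth line across the top of every slice.
The incision void is cut through the whole assembly above its bottom so
the knife path is not blocked by the cavity end walls.

**Baseplate.**  A plate whose footprint is the union of the structure
footprints dilated in-plane by `baseplate_offset_mm` — a rim following
the structures, not a solid bounding block.

**Boolean engine.**  The mould is described as a CSG tree (boxes,
extruded footprint polygons, convex polyhedra, union/difference).  The
same tree renders to an OpenSCAD script (the reference, human-editable
description) and evaluates itself on a voxel grid (pitch 0.5 mm,
snapped to the absolute lattice), from which watertight meshes are
recovered by marching cubes.  Voxel CSG was chosen as the engine
because it is robust for arbitrary inputs and exactly reproducible; the
emitted SCAD differs from the engine only in two documented
approximations (sharp instead of rounded inflation edges; the vertical
extension as a single widest-contour prism instead of a running union),
verified to agree in volume within 2 %.

## Slice outlines and co-registration

Each slab between consecutive slits gets a 2D outline: the mask
cross-section at the slab mid-plane (default — the cut face a
pathologist sees) or the slab's maximum-area projection
(`outline_mode=projection`), contoured at the 0.5 level for sub-voxel
precision.  Annotations: the **base arc** (contour points within
`cavity_clearance_mm + 1 mm` of the cavity floor) and the **incision
marker** (the centroid-y position and the single knife plane shared by
all slabs).  SVG pages are written at true scale (1 user unit = 1 mm
with explicit mm page size), labelled with the slab index, its WCS
x-interval and the original-image axial plane it maps onto.  Slabs are
numbered 1-based, inferior → superior.

`map_slice_to_image` returns the exact rigid map from outline
coordinates to patient coordinates, restricted to the matched axial
plane.  Its rotation angle is identical for every slab — the single
fixed rotation that aligns any tissue slice with its imaging plane —
and round-trips onto the working-grid mask boundary within about one
voxel.

## Phantoms

Synthetic cases stand in for patient imaging: spheres and ellipsoids
(closed-form volumes — the whole-pipeline oracle), lumpy blobs
(ellipsoid radius modulated by seeded Gaussian-filtered white noise on
a 7³ lattice, linearly interpolated — documented so an oracle can
regenerate it), bilobed masses, and a solid nodule on a thin cystic
shell where only the solid component is the tumour ROI.  Default grid
5.0 × 0.7 × 0.7 mm (routine CT); an MRI-like 3.0 × 0.9 × 0.9 mm variant
exercises the second modality.  The base ROI is painted as the surface
patch within `base_patch_angle_deg` (default 40°) of a requested
direction.  The fixed regression suite spans 7–133 cm³ — sphere radii
11.85 and 31.71 mm reproduce the extremes — both slice-thickness
regimes, and includes a no-base case for the manual-rotation path.

What the phantoms do **not** emulate: realistic tissue contrast and
noise, segmentation error, partial-volume effects, multi-focal or
highly concave lesions, deformation of the resected specimen (gravity,
cyst collapse) and growth between imaging and surgery.  Passing tests
therefore demonstrate geometric correctness and reproducibility of the
pipeline, not clinical fit of a printed mould to a real specimen.

## Numerical choices and degenerate inputs

* Voxel-centre sampling everywhere; contour fill by the even–odd rule
  (nested RT-STRUCT contours produce holes).
* Sampling lattices (1 mm working grid, 0.5 mm mould grid) anchored to
  absolute coordinates; rotation pivots snapped to the mm lattice.
  This removes systematic half-voxel tie-breaking shifts and makes
  equivalent runs bit-identical.
* Base centroid within 2 mm of the tumour centroid → "base direction
  undefined" error; manual angles outside ±180° are normalised with a
  warning; a tumour that vanishes at 1 mm resolution is rejected.
* ROI components smaller than 1 % of the largest are dropped as
  segmentation noise (warning).
* A cavity rim below 10 % of tumour height is rejected; slits that
  would overlap the cavity end walls are trimmed with a warning.
* Runs are deterministic: identical inputs and configuration give
  byte-identical reports (timings aside) and identical STL vertex sets.

## Known limitations

* Pipeline equivariance under *arbitrary* in-plane input rotations is
  limited by input rasterisation: the voxel staircase genuinely changes
  shape when a phantom is re-voxelised at 37°, and the convex hull
  (max-biased over staircase peaks) carries ~0.2–0.5 mm of that into
  the mould walls.  Mould voxel agreement across rotated runs is exact
  at lattice angles (90°, 180°) and plateaus near 98 % at oblique
  angles; oriented masks themselves stay above 99 %.  The
  co-registration *angle* is recovered to well under 1° at all angles.
* The orientation incision is a single straight knife plane; specimens
  whose top surface dips below the knife plane in some slabs simply
  receive no notch there (the outline then carries no marker).
* Mesh booleans are voxel-based at 0.5 mm; sub-voxel features of the
  printed mould (e.g. exact sharp slit corners) are only represented to
  that resolution.  The OpenSCAD script can be rendered externally when
  an exact-boolean mesh is preferred.
* No deformable modelling of the specimen and no decimation or repair
  of arbitrary broken input meshes.
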