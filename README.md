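# mouldforge

Lesion-specific 3D-printed slicing moulds for image-guided tissue
multi-sampling of pelvic and ovarian tumours.

Correlating radiological imaging with tissue-derived data (radiogenomics)
requires knowing *where* in the imaging volume each tissue sample came
from.  Ovarian resection specimens make this hard: once detached, they
have almost no anatomical landmarks, so slice position and orientation
are lost the moment the specimen leaves the table.  `mouldforge`
addresses this with a patient-specific mould computed from the
preoperative segmentation: the specimen sits in a cavity carved around
the convex hull of its own 3D model, a slicing guide constrains every
knife cut to an anatomical axial plane, and paired orientation guides
score a partial-depth notch across the top of all slices so their
rotation is recoverable after removal.  A 3D-printed tumour replica
helps place the real specimen correctly, and real-size per-slice
outline drawings — annotated with the mould-base contact and the
notch — let the pathologist map every tissue slice back to its axial
image plane with a single fixed in-plane rotation.

It is intended for imaging scientists and pathology research teams
building radiology–pathology co-registration pipelines; inputs are a
DICOM series with a DICOM-RT Structure Set (or NIfTI image + masks),
outputs are print-ready STL/OpenSCAD files, SVG slice sheets and a
machine-readable report.

## The model in brief

Given a tumour ROI (and optionally a "base of mould" ROI marking the
surface the specimen should rest on):

1. resample image and masks to an isotropic 1 mm grid
   (nearest-neighbour);
2. rotate in the axial plane so the base ROI faces down, and transform
   to the print-bed frame (WCS: x = craniocaudal slicing axis, z = up);
3. extract the tumour surface with Lorensen–Cline marching cubes at the
   0.5 level and smooth it with uniform Laplacian smoothing
   (λ = 1) — this smoothed mesh is the printable replica;
4. carve the mould cavity around the clearance-inflated convex hull of
   the replica, with walls rising vertically above the widest
   horizontal contour (rim opening never narrower than the specimen);
5. place knife slits at the tumour centre and at `slice_thickness_mm`
   intervals either side, projected down to the cavity floor; add the
   orientation guides and a baseplate; evaluate the boolean assembly on
   a 0.5 mm voxel grid and emit both STL and an OpenSCAD CSG script;
6. extract one annotated outline per tissue slab and the rigid map
   from each outline to its axial image plane.

See `docs/methods.md` for conventions, parameters and limitations.

## Worked example

Generate a synthetic case (a 25 mm radius spherical lesion on a
CT-like 5.0 × 0.7 × 0.7 mm grid, with a posterior base ROI) and build
its mould:

```sh
mouldforge phantom make --shape sphere --radius 25 --seed 7 --out demo/case
mouldforge build --image demo/case/image.nii.gz \
                 --tumour-mask demo/case/tumour.nii.gz \
                 --base-mask demo/case/base.nii.gz \
                 --out demo/out
```

which prints

```
case out: tumour 65.1 cm³, 5 slits, outputs in demo/out
```

and writes `replica.stl`, `mould.stl`, `mould.scad`,
`slices/slab_01.svg … slab_06.svg`, `slices/index.json` and
`report.json`.  Key numbers from `report.json` for this run:

```
tumour_volume_mm3        65074.2      # vs 4/3·π·25³ = 65449.8 (0.6 % low)
tumour_x_extent_mm       [-25.5, 24.5]
slit_positions_mm        [-20.5, -10.5, -0.5, 9.5, 19.5]
coregistration_angle_deg -0.0
cavalieri_volume_mm3     65505.0
```

The replica volume is within 0.6 % of the analytic sphere volume
(voxelisation plus smoothing shrinkage).  Five slits span the 50 mm
lesion at exactly 10 mm spacing with the middle slit on the tumour
centre, cutting it into six slabs; `slices/index.json` maps each slab
to the original axial plane it came from (planes 2–11 here).  The
co-registration angle is 0° because the phantom's base was already
posterior; a rotated base produces the matching fixed angle on every
slice sheet.  The Cavalieri estimate — slab outline areas × slab
thicknesses — agrees with the tumour volume to 0.7 %, a cross-check
that outlines and slabs are consistent.

Each `slab_NN.svg` prints at true scale (1 SVG unit = 1 mm): the black
contour is the expected cut face, the blue arc is where the slice
rested on the mould base, and the red segment marks the position and
depth of the orientation notch.

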