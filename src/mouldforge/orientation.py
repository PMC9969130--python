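"""Isotropic resampling and orientation into the print-bed frame.

The mould is printed and used in a world coordinate system (WCS) fixed
to the print bed:

* WCS **x** — patient craniocaudal axis (+x = superior).  Slicing
  planes are the constant-x planes, i.e. anatomical axial planes.
* WCS **z** — print-bed vertical, up.  The mould base faces -z.
* WCS **y** — completes a right-handed frame.

Orientation happens in three steps, mirroring how a case is processed:

1. :func:`resample_isotropic` re-slices everything to 1x1x1 mm with
   zero-order (nearest-neighbour) interpolation on an axis-aligned LPS
   grid, so downstream geometry is independent of the scan's
   reconstructed slice thickness.
2. :func:`rotate_base_to_bottom` (or :func:`manual_rotation` when no
   base ROI was segmented) applies a single in-plane rotation about the
   craniocaudal axis so the tumour region adjacent to the base ROI sits
   at the bottom.
3. :func:`to_world_coordinates` permutes/flips the array axes into the
   WCS convention and crops to the tumour bounding box plus a margin.

Every step composes its exact rigid transform into
``OrientedMask.to_image`` so any WCS point can be mapped back to
patient (LPS) millimetre coordinates — this is what makes slice-by-slice
co-registration a single fixed rotation at the end of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from mouldforge.imaging_io import (
    CANONICAL_DIRECTION,
    ImageVolume,
    RoiMask,
    SegmentationCase,
)

__all__ = [
    "RigidTransform",
    "OrientedMask",
    "resample_isotropic",
    "rotate_base_to_bottom",
    "manual_rotation",
    "to_world_coordinates",
]

# antidiagonal permutation: array index order (slice,row,col)=(z,y,x)
# <-> coordinate order (x, y, z)
_J = np.array([[0.0, 0.0, 1.0],
               [0.0, 1.0, 0.0],
               [1.0, 0.0, 0.0]])

WCS_AXES_DOC = (
    "x = patient craniocaudal (+x superior) = slicing axis; "
    "z = print-bed vertical (up); y completes the right-handed frame"
)


@dataclass
class RigidTransform:
    """A rigid map ``p_out = rotation @ p_in + translation`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (self.rotation @ pts.T).T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(
            rotation=Rinv,
            translation=-Rinv @ self.translation,
            description=f"inverse({self.description})",
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
            description=f"{self.description} ∘ {other.description}",
        )


@dataclass
class OrientedMask:
    """Tumour (and base) masks on a 1 mm grid in an oriented frame.

    After :func:`to_world_coordinates` the arrays are indexed
    ``(x, y, z)`` in WCS with ``origin_mm`` the WCS position of voxel
    (0, 0, 0); before that (``stage == "rotated"``) they are still in
    scanner axis order ``(slice, row, col)`` of the rotated frame.

    ``to_image`` maps frame millimetre coordinates back to patient LPS
    millimetre coordinates of the (isotropic) input.
    """

    tumour: np.ndarray
    base: Optional[np.ndarray]
    origin_mm: np.ndarray
    to_image: RigidTransform
    stage: str  # "rotated" | "wcs"
    wcs_axes: str = WCS_AXES_DOC
    source_geometry: dict = field(default_factory=dict)
    image: Optional[np.ndarray] = None  # intensities, carried for QC only

    def __post_init__(self) -> None:
        self.tumour = np.asarray(self.tumour, dtype=bool)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.base is not None:
            self.base = np.asarray(self.base, dtype=bool)

    # -- geometry helpers (valid in the "wcs" stage, arrays (x, y, z)) --

    def voxel_centres_mm(self, mask: np.ndarray) -> np.ndarray:
        idx = np.argwhere(mask)
        return idx + self.origin_mm

    def tumour_centroid_mm(self) -> np.ndarray:
        return np.mean(np.argwhere(self.tumour), axis=0) + self.origin_mm

    def base_centroid_mm(self) -> Optional[np.ndarray]:
        if self.base is None or not self.base.any():
            return None
        return np.mean(np.argwhere(self.base), axis=0) + self.origin_mm

    def x_extent_mm(self) -> tuple[float, float]:
        """Occupied tumour extent along the WCS slicing axis (voxel bounds)."""
        xs = np.where(self.tumour.any(axis=(1, 2)))[0]
        return (float(xs[0] + self.origin_mm[0] - 0.5),
                float(xs[-1] + self.origin_mm[0] + 0.5))

    def z_extent_mm(self) -> tuple[float, float]:
        zs = np.where(self.tumour.any(axis=(0, 1)))[0]
        return (float(zs[0] + self.origin_mm[2] - 0.5),
                float(zs[-1] + self.origin_mm[2] + 0.5))

    def height_mm(self) -> float:
        lo, hi = self.z_extent_mm()
        return hi - lo

    def in_plane_angle_deg(self) -> float:
        """The in-plane rotation applied at orientation time.

        Recovered from ``to_image``: the patient-frame direction the
        mould base faces is ``-R[:, 2]`` (the WCS -z axis); the angle is
        measured from the posterior (+y, "straight down" on a supine
        axial view) reference.
        """
        d = -self.to_image.rotation[:, 2]
        return float(np.degrees(np.arctan2(d[0], d[1])))


# ---------------------------------------------------------------------------
# Step 1: isotropic resampling
# ---------------------------------------------------------------------------

def _resample_to_grid(array: np.ndarray, image_like: ImageVolume,
                      new_origin: np.ndarray, new_shape: tuple,
                      order: int = 0) -> np.ndarray:
    """Sample ``array`` (on ``image_like``'s grid) onto an axis-aligned
    canonical 1 mm grid with the given origin/shape, nearest-neighbour."""
    # output index -> LPS mm: p = new_origin + CANONICAL @ idx
    # input index  -> idx_in = diag(1/sp) D^T (p - origin)
    D_in = image_like.direction
    sp = image_like.spacing
    A = (D_in.T @ CANONICAL_DIRECTION) / sp[:, None]
    b = (D_in.T @ (new_origin - image_like.origin)) / sp
    is_bool = array.dtype == bool
    out = ndimage.affine_transform(
        array.astype(np.uint8 if is_bool else np.float32),
        matrix=A, offset=b, output_shape=new_shape,
        order=order, mode="constant", cval=0, prefilter=False,
    )
    return out.astype(bool) if is_bool else out


def resample_isotropic(case: SegmentationCase,
                       voxel_size_mm: float = 1.0) -> SegmentationCase:
    """Re-slice a case to an axis-aligned 1x1x1 mm LPS grid.

    Zero-order (nearest-neighbour) interpolation is used for the image
    and all masks, so exactly one rasterisation convention is carried
    through the pipeline.
    """
    if voxel_size_mm != 1.0:
        raise ValueError("the pipeline operates on a 1 mm isotropic grid")
    img = case.image
    # physical bounding box of the input grid (all 8 corners)
    n = np.array(img.shape) - 1
    corners = np.array([[i, j, k] for i in (0, n[0]) for j in (0, n[1])
                        for k in (0, n[2])], dtype=float)
    pts = img.index_to_physical(corners)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    # canonical grid: index (i,j,k) -> origin + (k, j, i) mm.  The grid
    # is anchored to integer patient-space mm so that the sampling
    # lattice is reproducible across rigidly related inputs (this makes
    # orientation equivariant under exact in-plane input rotations).
    new_origin = np.floor(lo)
    extent = hi - new_origin
    new_shape = tuple(int(np.floor(e)) + 1 for e in extent[::-1])

    vox = _resample_to_grid(img.voxels, img, new_origin, new_shape)
    new_img = ImageVolume(
        voxels=vox, spacing=np.ones(3), origin=new_origin,
        direction=CANONICAL_DIRECTION.copy(), modality=img.modality,
    )
    tum = _resample_to_grid(case.tumour.mask, img, new_origin, new_shape)
    if not tum.any():
        raise ValueError("tumour empty after resampling (sub-voxel lesion)")
    new_tumour = RoiMask(tum, case.tumour.name, case.tumour.source)
    new_base = None
    if case.base is not None:
        bm = _resample_to_grid(case.base.mask, img, new_origin, new_shape)
        new_base = RoiMask(bm, case.base.name, case.base.source)
    meta = dict(case.meta)
    # remember the original acquisition grid: slice outlines report the
    # original-image axial plane each slab maps onto
    meta.setdefault("source_geometry", {
        "origin": img.origin.tolist(),
        "spacing": img.spacing.tolist(),
        "direction": img.direction.tolist(),
        "shape": list(img.shape),
    })
    # physical centroids from the native grid: finer in-plane sampling
    # than the 1 mm working grid, so the base-direction estimate (and
    # hence the in-plane rotation angle) is not degraded by resampling
    meta.setdefault("native_centroids", {
        "tumour": img.index_to_physical(
            case.tumour.centroid_index()).tolist(),
        "base": (img.index_to_physical(case.base.centroid_index()).tolist()
                 if case.base is not None else None),
    })
    return SegmentationCase(
        image=new_img, tumour=new_tumour, base=new_base,
        case_id=case.case_id, meta=meta,
        base_touch_radius=case.base_touch_radius,
    )


def _check_isotropic(case: SegmentationCase) -> None:
    if not np.allclose(case.image.spacing, 1.0):
        raise ValueError("case must be resampled to 1 mm isotropic first")
    if not np.allclose(case.image.direction, CANONICAL_DIRECTION, atol=1e-9):
        raise ValueError("case must be on the canonical axis-aligned grid")


# ---------------------------------------------------------------------------
# Step 2: in-plane rotation (base at bottom)
# ---------------------------------------------------------------------------

def _rotate_case(case: SegmentationCase, base_dir_xy: np.ndarray,
                 description: str) -> OrientedMask:
    """Rasterise the case into a frame rotated about the craniocaudal
    axis so that ``base_dir_xy`` (patient axial-plane unit vector) maps
    to the +row (posterior) direction of the new frame."""
    img = case.image
    d = np.array([base_dir_xy[0], base_dir_xy[1], 0.0])
    d /= np.linalg.norm(d)
    z_p = np.array([0.0, 0.0, 1.0])
    # new frame axes in patient coords: rows along d, slices along z
    y_new = d
    x_new = np.cross(y_new, z_p)
    R = np.column_stack([x_new, y_new, z_p])  # frame coords -> patient coords

    tum_idx = np.argwhere(case.tumour.mask).astype(float)
    pts = img.index_to_physical(tum_idx)
    # pivot: tumour centroid snapped to the integer-mm lattice, so the
    # resampling lattice stays phase-locked to the isotropic grid (no
    # systematic half-voxel ties; exact under 90-degree rotations)
    c = np.round(pts.mean(axis=0))
    if case.base is not None:
        base_pts = img.index_to_physical(
            np.argwhere(case.base.mask).astype(float))
        all_pts = np.vstack([pts, base_pts])
    else:
        all_pts = pts
    rel = (R.T @ (all_pts - c).T).T  # frame coords relative to centroid
    margin = 2.0
    lo = np.floor(rel.min(axis=0) - margin)
    hi = np.ceil(rel.max(axis=0) + margin)
    origin = lo  # frame mm of voxel (0,0,0), array order (slice,row,col)
    shape = tuple(int(v) + 1 for v in (hi - lo)[::-1])

    def sample(arr: np.ndarray) -> np.ndarray:
        # out idx -> frame coords p' = origin + J idx; patient p = R p' + c
        # in idx = J (p - img.origin)   (unit spacing, canonical direction)
        A = _J @ R @ _J
        b = _J @ (R @ origin + c - img.origin)
        is_bool = arr.dtype == bool
        out = ndimage.affine_transform(
            arr.astype(np.uint8 if is_bool else np.float32),
            matrix=A, offset=b, output_shape=shape,
            order=0, mode="constant", cval=0, prefilter=False,
        )
        return out.astype(bool) if is_bool else out

    tum = sample(case.tumour.mask)
    base = sample(case.base.mask) if case.base is not None else None
    intens = sample(img.voxels)
    src_geo = dict(case.meta.get("source_geometry", {}))
    if not src_geo:
        src_geo = {
            "origin": img.origin.tolist(),
            "spacing": img.spacing.tolist(),
            "direction": img.direction.tolist(),
            "shape": list(img.shape),
        }
    return OrientedMask(
        tumour=tum, base=base, origin_mm=origin,
        to_image=RigidTransform(R, c, description),
        stage="rotated", source_geometry=src_geo, image=intens,
    )


def rotate_base_to_bottom(case: SegmentationCase) -> OrientedMask:
    """Rotate in the axial plane so the base ROI faces the mould floor.

    The in-plane angle is derived from centroid geometry: the axial
    projection of the vector from tumour centroid to base-ROI centroid
    becomes the "down" direction of the mould.
    """
    _check_isotropic(case)
    if case.base is None:
        raise ValueError(
            "no base ROI present; use manual_rotation(case, angle_deg)"
        )
    img = case.image
    native = case.meta.get("native_centroids") or {}
    if native.get("base") is not None:
        tc = np.asarray(native["tumour"], dtype=float)
        bc = np.asarray(native["base"], dtype=float)
    else:
        tc = img.index_to_physical(case.tumour.centroid_index())
        bc = img.index_to_physical(case.base.centroid_index())
    v = bc - tc
    if np.linalg.norm(v) < 2.0:
        raise ValueError(
            "base direction undefined: base centroid within 2 mm of "
            "tumour centroid"
        )
    v_xy = v[:2]
    if np.linalg.norm(v_xy) < 1e-9:
        raise ValueError(
            "base direction undefined: base centroid lies on the "
            "craniocaudal axis through the tumour centroid"
        )
    return _rotate_case(case, v_xy / np.linalg.norm(v_xy),
                        "rotate_base_to_bottom")


def manual_rotation(case: SegmentationCase, angle_deg: float) -> OrientedMask:
    """In-plane rotation with a user-supplied angle (no base ROI).

    Angle 0 leaves the axial plane untouched (the mould base faces the
    patient-posterior direction); positive angles rotate the assumed
    base direction from posterior towards the patient's left.
    """
    _check_isotropic(case)
    if case.base is not None:
        warnings.warn(
            "base ROI present: ignoring manual angle and using the base ROI",
            stacklevel=2,
        )
        return rotate_base_to_bottom(case)
    if not -180.0 <= angle_deg <= 180.0:
        normalised = (angle_deg + 180.0) % 360.0 - 180.0
        warnings.warn(
            f"manual rotation angle {angle_deg} normalised to {normalised}",
            stacklevel=2,
        )
        angle_deg = normalised
    th = np.radians(angle_deg)
    base_dir = np.array([np.sin(th), np.cos(th)])
    return _rotate_case(case, base_dir, f"manual_rotation({angle_deg})")


# ---------------------------------------------------------------------------
# Step 3: WCS axis permutation + crop
# ---------------------------------------------------------------------------

def to_world_coordinates(oriented: OrientedMask,
                         crop_margin_mm: float = 5.0) -> OrientedMask:
    """Permute the rotated frame into WCS order and crop to the tumour.

    WCS axes in terms of the rotated patient frame:
    ``x_w = +z`` (superior), ``z_w = -y`` (up = away from the base),
    ``y_w = -x`` (completes right-handed).  This is a pure array
    permutation/flip — no resampling — so voxel values are exact.
    """
    if oriented.stage != "rotated":
        raise ValueError("to_world_coordinates expects a 'rotated' mask")

    def permute(arr):
        if arr is None:
            return None
        return np.flip(np.transpose(arr, (0, 2, 1)), axis=(1, 2))

    tum = permute(oriented.tumour)
    base = permute(oriented.base)
    intens = permute(oriented.image)
    n0, n1, n2 = oriented.tumour.shape
    o = oriented.origin_mm  # rotated-frame mm of voxel (0,0,0), (z', y', x') coords via J
    # WCS coords of new voxel (0,0,0) = old voxel (0, n1-1, n2-1)
    # origin_mm components are p'-frame (x', y', z') coordinates
    xw0 = o[2]                      # z' coordinate of slice 0
    yw0 = -(o[0] + (n2 - 1))        # -x' of last column
    zw0 = -(o[1] + (n1 - 1))        # -y' of last row
    origin_w = np.array([xw0, yw0, zw0])

    # rotation A: p_rotated-frame = A @ p_wcs
    A = np.array([[0.0, -1.0, 0.0],
                  [0.0, 0.0, -1.0],
                  [1.0, 0.0, 0.0]])
    to_image = oriented.to_image.compose(
        RigidTransform(A, np.zeros(3), "wcs_axes"))

    # crop to tumour bbox + margin (clipped to array bounds)
    m = int(round(crop_margin_mm))
    occ = np.argwhere(tum)
    lo = np.maximum(occ.min(axis=0) - m, 0)
    hi = np.minimum(occ.max(axis=0) + m + 1, tum.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    tum = tum[sl]
    base = base[sl] if base is not None else None
    intens = intens[sl] if intens is not None else None
    origin_w = origin_w + lo

    out = OrientedMask(
        tumour=tum, base=base, origin_mm=origin_w, to_image=to_image,
        stage="wcs", source_geometry=oriented.source_geometry, image=intens,
    )
    bc = out.base_centroid_mm()
    if bc is not None:
        tc = out.tumour_centroid_mm()
        if not bc[2] < tc[2]:
            raise AssertionError(
                "orientation failed: base centroid is not below the "
                "tumour centroid in WCS"
            )
    return out


def orient_case(case: SegmentationCase,
                manual_rotation_deg: Optional[float] = None,
                crop_margin_mm: float = 5.0) -> OrientedMask:
    """Convenience: resample + rotate + WCS in one call."""
    iso = resample_isotropic(case)
    if iso.base is not None:
        rot = rotate_base_to_bottom(iso)
    elif manual_rotation_deg is not None:
        rot = manual_rotation(iso, manual_rotation_deg)
    else:
        raise ValueError(
            "no base ROI and no manual angle: supply --manual-rotation-deg"
        )
    return to_world_coordinates(rot, crop_margin_mm=crop_margin_mm)
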