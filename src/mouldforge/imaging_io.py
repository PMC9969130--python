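"""Imaging input/output and the internal data model.

Conventions used throughout the package:

* voxel arrays are indexed ``(slice, row, col)`` — axis 0 is the scanner
  slice direction;
* all physical quantities are millimetres;
* patient space is DICOM LPS.  The physical position of array index
  ``(i, j, k)`` is ``origin + direction @ (spacing * (i, j, k))`` where
  ``direction`` has the patient-space unit vectors of the three array
  axes as its *columns*.

Inside/outside tests use voxel-centre sampling: a voxel belongs to an
ROI iff its centre lies inside the contour polygon (even-odd rule).
This matches the 0.5 iso-level convention used by marching cubes
downstream, so a rasterised contour and the reconstructed surface agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ImageVolume",
    "RoiMask",
    "SegmentationCase",
    "read_dicom_series",
    "rasterise_rtstruct",
    "read_mask_file",
    "write_mesh",
    "read_mesh",
]

# patient-space unit vectors of array axes (slice, row, col) for a
# canonical axis-aligned LPS volume: slices advance superiorly, rows
# advance posteriorly, columns advance to the patient's left.
CANONICAL_DIRECTION = np.array(
    [[0.0, 0.0, 1.0],
     [0.0, 1.0, 0.0],
     [1.0, 0.0, 0.0]]
).T  # columns: axis0 -> +S, axis1 -> +P, axis2 -> +L


@dataclass
class ImageVolume:
    """A 3D imaging volume with its physical grid geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nslices, nrows, ncols)
        Image intensities, arbitrary units.
    spacing : (3,) array
        mm per voxel along each *array* axis.
    origin : (3,) array
        Patient-space (LPS) position in mm of voxel (0, 0, 0).
    direction : (3, 3) array
        Orthonormal matrix whose columns are the patient-space unit
        vectors of the array axes.
    modality : str
        "CT", "MR" or "OTHER".
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    modality: str = "OTHER"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must all be > 0")
        if abs(abs(np.linalg.det(self.direction)) - 1.0) > 1e-6:
            raise ValueError("direction matrix must be orthonormal (|det| = 1)")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) array indices (..., 3) to LPS mm."""
        idx = np.asarray(idx, dtype=float)
        return self.origin + (self.direction @ (self.spacing * idx).T).T

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map LPS mm points (..., 3) to fractional array indices."""
        pts = np.asarray(pts, dtype=float)
        rel = (self.direction.T @ (pts - self.origin).T).T
        return rel / self.spacing


@dataclass
class RoiMask:
    """A boolean region-of-interest mask on an ImageVolume grid."""

    mask: np.ndarray
    name: str
    source: str = "MASK_FILE"  # RTSTRUCT | MASK_FILE | SYNTHETIC

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def centroid_index(self) -> np.ndarray:
        return np.mean(np.argwhere(self.mask), axis=0)


@dataclass
class SegmentationCase:
    """A co-registered image + tumour (and optional mould-base) ROI.

    The base ROI marks the tumour surface that should rest on the mould
    floor; it drives the automatic in-plane rotation.  It must touch the
    tumour (within ``base_touch_radius`` voxels of dilation).
    """

    image: ImageVolume
    tumour: RoiMask
    base: Optional[RoiMask] = None
    case_id: str = "case"
    meta: dict = field(default_factory=dict)
    base_touch_radius: int = 3

    def __post_init__(self) -> None:
        from scipy import ndimage

        if self.tumour.mask.shape != self.image.shape:
            raise ValueError(
                f"tumour mask shape {self.tumour.mask.shape} does not match "
                f"image shape {self.image.shape}"
            )
        if self.tumour.n_voxels == 0:
            raise ValueError("empty ROI: tumour mask has no true voxels")
        if self.base is not None:
            if self.base.mask.shape != self.image.shape:
                raise ValueError("base mask grid does not match image grid")
            dilated = ndimage.binary_dilation(
                self.tumour.mask, iterations=self.base_touch_radius
            )
            if not np.any(self.base.mask & dilated):
                raise ValueError(
                    "base ROI does not touch the tumour surface "
                    f"(within {self.base_touch_radius} voxels)"
                )


def drop_small_components(mask: np.ndarray, min_fraction: float = 0.01) -> np.ndarray:
    """Remove connected components smaller than ``min_fraction`` of the largest.

    Small islands are treated as segmentation noise; a warning is issued
    when any component is dropped.
    """
    from scipy import ndimage

    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask.astype(bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = sizes >= min_fraction * sizes.max()
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} small ROI component(s) "
            f"(< {min_fraction:.0%} of largest)",
            stacklevel=2,
        )
    out = np.isin(labels, [i + 1 for i, k in enumerate(keep) if k])
    return out


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def read_dicom_series(directory) -> ImageVolume:
    """Read a single-frame DICOM series from a directory.

    Slices are sorted by their projection onto the slice normal
    (cross product of the row and column direction cosines).  The series
    must be single-UID and uniformly spaced (1% tolerance).
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise ValueError(f"no DICOM image files found in {directory}")

    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise ValueError(f"mixed series UIDs in {directory}: {sorted(uids)}")

    iop = np.array(datasets[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = iop[:3], iop[3:]
    normal = np.cross(row_dir, col_dir)
    datasets.sort(key=lambda ds: float(np.dot(ds.ImagePositionPatient, normal)))

    positions = np.array([ds.ImagePositionPatient for ds in datasets], dtype=float)
    if len(datasets) > 1:
        gaps = np.diff(positions @ normal)
        mean_gap = gaps.mean()
        if mean_gap <= 0:
            raise ValueError("degenerate slice positions")
        if np.any(np.abs(gaps - mean_gap) > 0.01 * abs(mean_gap)):
            raise ValueError(
                "non-uniform slice spacing: gaps "
                f"{np.round(gaps, 3).tolist()} exceed 1% tolerance"
            )
        slice_gap = float(mean_gap)
    else:
        slice_gap = float(getattr(datasets[0], "SliceThickness", 1.0))

    px_spacing = np.array(datasets[0].PixelSpacing, dtype=float)  # (row, col)
    voxels = np.stack(
        [ds.pixel_array.astype(np.float32) for ds in datasets], axis=0
    )
    spacing = np.array([slice_gap, px_spacing[0], px_spacing[1]])
    # columns of direction: slice, row, col axes in patient space
    direction = np.column_stack([normal, row_dir, col_dir])
    modality = str(getattr(datasets[0], "Modality", "OTHER"))
    if modality not in ("CT", "MR"):
        modality = "OTHER"
    return ImageVolume(
        voxels=voxels,
        spacing=spacing,
        origin=positions[0],
        direction=direction,
        modality=modality,
    )


# ---------------------------------------------------------------------------
# RT-STRUCT rasterisation
# ---------------------------------------------------------------------------

def _points_in_polygon(px: np.ndarray, py: np.ndarray,
                       poly: np.ndarray) -> np.ndarray:
    """Vectorised even-odd (crossing-number) point-in-polygon test.

    ``poly`` is (N, 2); points on the boundary follow the half-open
    edge convention of the crossing test.
    """
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    inside = np.zeros(px.shape, dtype=bool)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        if ay == by:
            continue
        cond = (py < max(ay, by)) & (py >= min(ay, by))
        # x of edge at height py
        xint = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= cond & (px < xint)
    return inside


def rasterise_rtstruct(rtstruct_path, image: ImageVolume,
                       roi_names: Sequence[str]) -> list[RoiMask]:
    """Fill DICOM-RT Structure Set contours into boolean masks.

    Per-slice closed contours are filled by the even-odd rule over voxel
    centres; multiple contours on one slice are combined by XOR, so
    nested contours produce holes and disjoint contours produce separate
    components.
    """
    import pydicom

    ds = pydicom.dcmread(str(rtstruct_path))
    by_name = {}
    numbers = {}
    for roi in ds.StructureSetROISequence:
        numbers[int(roi.ROINumber)] = str(roi.ROIName)
    contour_sets = {}
    for rc in ds.ROIContourSequence:
        name = numbers.get(int(rc.ReferencedROINumber))
        contour_sets[name] = rc
        by_name[name] = rc

    available = sorted(by_name)
    masks = []
    for want in roi_names:
        if want not in by_name:
            raise ValueError(
                f"ROI {want!r} not found in structure set; available: {available}"
            )
        rc = by_name[want]
        seq = getattr(rc, "ContourSequence", None)
        if not seq:
            raise ValueError(f"ROI {want!r} has no contours")
        mask = np.zeros(image.shape, dtype=bool)
        # voxel-centre physical coordinates per slice, computed lazily
        for contour in seq:
            pts = np.array(contour.ContourData, dtype=float).reshape(-1, 3)
            if len(pts) < 3:
                continue
            # locate the image slice this planar contour lies on
            idx = image.physical_to_index(pts)
            slice_f = idx[:, 0]
            k = int(round(float(np.mean(slice_f))))
            if abs(float(np.mean(slice_f)) - k) > 0.5:
                warnings.warn(
                    f"contour of ROI {want!r} lies between slices; "
                    "assigned to nearest", stacklevel=2,
                )
            if not (0 <= k < image.shape[0]):
                continue
            poly = idx[:, 1:]  # (row, col) fractional indices in-plane
            jj, kk = np.meshgrid(
                np.arange(image.shape[1], dtype=float),
                np.arange(image.shape[2], dtype=float),
                indexing="ij",
            )
            inside = _points_in_polygon(kk, jj, poly[:, ::-1])
            mask[k] ^= inside  # even-odd across contours on a slice
        masks.append(RoiMask(mask=mask, name=want, source="RTSTRUCT"))
    return masks


# ---------------------------------------------------------------------------
# NIfTI masks (convenience dialect for phantom and test inputs)
# ---------------------------------------------------------------------------

_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0])


def read_nifti_volume(path, modality: str = "OTHER") -> ImageVolume:
    """Read a NIfTI file as an ImageVolume (RAS affine converted to LPS)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError("only 3D NIfTI volumes are supported")
    affine = img.affine.copy()
    affine[:3] = _RAS_TO_LPS @ affine[:3]  # now index -> LPS
    # nibabel arrays are (i, j, k) with affine columns per index axis;
    # reorder to our (slice, row, col) = (k, j, i) convention.
    data = np.transpose(data, (2, 1, 0))
    A = affine[:3, :3][:, ::-1]  # columns now for (k, j, i)
    spacing = np.linalg.norm(A, axis=0)
    direction = A / spacing
    return ImageVolume(
        voxels=data.astype(np.float32),
        spacing=spacing,
        origin=affine[:3, 3],
        direction=direction,
        modality=modality,
    )


def write_nifti(path, volume: ImageVolume) -> None:
    """Write an ImageVolume to NIfTI (LPS geometry converted to RAS)."""
    import nibabel as nib

    data = np.transpose(volume.voxels, (2, 1, 0))
    A = (volume.direction * volume.spacing)[:, ::-1]
    affine = np.eye(4)
    affine[:3, :3] = A
    affine[:3, 3] = volume.origin
    affine[:3] = _RAS_TO_LPS @ affine[:3]
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def read_mask_file(path, image: ImageVolume, name: str) -> RoiMask:
    """Read a NIfTI mask co-registered to ``image``; nonzero voxels are true."""
    vol = read_nifti_volume(path)
    if vol.shape != image.shape:
        raise ValueError(
            f"mask grid {vol.shape} does not match image grid {image.shape}"
        )
    aff_ok = (
        np.allclose(vol.origin, image.origin, atol=1e-3)
        and np.allclose(vol.spacing, image.spacing, atol=1e-3)
        and np.allclose(vol.direction, image.direction, atol=1e-3)
    )
    if not aff_ok:
        raise ValueError(
            "mask affine does not match image affine within 1e-3 mm: "
            f"mask origin {vol.origin}, image origin {image.origin}"
        )
    mask = vol.voxels != 0
    if not mask.any():
        raise ValueError(f"empty ROI: mask file {path} has no nonzero voxels")
    return RoiMask(mask=mask, name=name, source="MASK_FILE")


# ---------------------------------------------------------------------------
# Mesh export
# ---------------------------------------------------------------------------

def write_mesh(mesh, path, format: Optional[str] = None) -> None:
    """Write a mesh to binary STL or OBJ (units: mm).

    Non-watertight meshes are written with a warning — they may not be
    printable as-is.
    """
    import trimesh

    if not isinstance(mesh, trimesh.Trimesh):
        raise TypeError("expected a trimesh.Trimesh")
    if len(mesh.faces) == 0:
        raise ValueError("refusing to write an empty (zero-face) mesh")
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("stl", "obj"):
        raise ValueError(f"unsupported mesh format: {fmt}")
    if fmt == "stl" and not mesh.is_watertight:
        warnings.warn(f"mesh written to {path} is not watertight", stacklevel=2)
    mesh.export(str(path), file_type=fmt)


def read_mesh(path):
    """Read an STL/OBJ mesh back as a trimesh.Trimesh."""
    import trimesh

    loaded = trimesh.load(str(path), process=False)
    if isinstance(loaded, trimesh.Scene):
        loaded = trimesh.util.concatenate(list(loaded.geometry.values()))
    return loaded
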