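"""Shared fixtures: synthetic DICOM writers and phantom-derived objects.

Everything is generated programmatically at test time; no binary
fixtures are stored.  Expensive objects (oriented masks, meshes, a full
mould assembly) are session-scoped so the many tests that inspect them
pay the build cost once.
"""

from __future__ import annotations

import numpy as np
import pytest

import mouldforge as mf
from mouldforge.orientation import OrientedMask, RigidTransform


# ---------------------------------------------------------------------------
# synthetic DICOM series / RT-STRUCT writers
# ---------------------------------------------------------------------------

def write_dicom_series(directory, voxels, pixel_spacing=(0.7, 0.7),
                       slice_gap=5.0, origin=(0.0, 0.0, 0.0),
                       series_uid=None, positions=None, modality="CT"):
    """Write a minimal single-frame CT series (one file per slice)."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory.mkdir(parents=True, exist_ok=True)
    series_uid = series_uid or generate_uid()
    study_uid = generate_uid()
    voxels = np.asarray(voxels)
    paths = []
    for k in range(voxels.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = modality
        ds.Rows, ds.Columns = voxels.shape[1], voxels.shape[2]
        ds.PixelSpacing = [str(pixel_spacing[0]), str(pixel_spacing[1])]
        ds.SliceThickness = str(slice_gap)
        if positions is not None:
            z = positions[k]
        else:
            z = origin[2] + k * slice_gap
        ds.ImagePositionPatient = [str(origin[0]), str(origin[1]), str(z)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.InstanceNumber = k + 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = voxels[k].astype(np.uint16).tobytes()
        path = directory / f"slice_{k:03d}.dcm"
        pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
        paths.append(path)
    return paths


def write_rtstruct(path, rois):
    """Write a minimal RT Structure Set.

    ``rois`` maps ROI name -> list of contours, each an (N, 3) array of
    patient-space mm points (planar, on an image slice).
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.sequence import Sequence
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetROISequence = Sequence()
    ds.ROIContourSequence = Sequence()
    for num, (name, contours) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = Sequence()
        for pts in contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            pts = np.asarray(pts, dtype=float)
            c.NumberOfContourPoints = len(pts)
            c.ContourData = [f"{v:.4f}" for v in pts.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# synthetic oriented masks (cheap inputs for mould/slice tests)
# ---------------------------------------------------------------------------

def oriented_from_mask(mask, origin_mm=None):
    """Wrap a WCS-frame boolean array (x, y, z) as an OrientedMask with
    an identity patient transform — a shortcut for geometry tests."""
    mask = np.asarray(mask, dtype=bool)
    if origin_mm is None:
        origin_mm = -(np.array(mask.shape) - 1) / 2.0
    # the canonical zero-rotation WCS->patient map: x_w = superior,
    # z_w = anterior (base faces posterior), y_w completes right-handed
    R = np.array([[0.0, -1.0, 0.0],
                  [0.0, 0.0, -1.0],
                  [1.0, 0.0, 0.0]])
    return OrientedMask(
        tumour=mask, base=None, origin_mm=np.asarray(origin_mm, float),
        to_image=RigidTransform(R, np.zeros(3), "synthetic"),
        stage="wcs",
        source_geometry={
            "origin": [0.0, 0.0, -200.0],
            "spacing": [1.0, 1.0, 1.0],
            "direction": np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]],
                                  dtype=float).T.tolist(),
            "shape": [400, 400, 400],
        },
    )


def ball_mask(radius_mm, pad=6, centre_offset=(0, 0, 0)):
    n = int(2 * (radius_mm + pad)) + 1
    c = (n - 1) / 2.0 + np.asarray(centre_offset, float)
    idx = np.indices((n, n, n)).astype(float)
    d2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
    return d2 < radius_mm ** 2


@pytest.fixture(scope="session")
def sphere_case():
    """20 mm radius sphere phantom with posterior base ROI (CT grid)."""
    return mf.make_phantom(
        mf.PhantomSpec(shape="SPHERE", size_mm={"radius": 20.0}, seed=11)
    )


@pytest.fixture(scope="session")
def oriented_sphere(sphere_case):
    from mouldforge.orientation import orient_case

    return orient_case(sphere_case)


@pytest.fixture(scope="session")
def sphere_replica(oriented_sphere):
    raw = mf.marching_cubes(oriented_sphere)
    return mf.laplacian_smooth(raw, lam=1.0)


@pytest.fixture(scope="session")
def sphere_assembly(oriented_sphere, sphere_replica):
    hull = mf.convex_hull(sphere_replica)
    spec = mf.MouldSpec()
    return mf.build_mould(oriented_sphere, sphere_replica, hull, spec)


@pytest.fixture()
def default_spec():
    return mf.MouldSpec()
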