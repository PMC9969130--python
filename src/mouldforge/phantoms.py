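"""Synthetic tumour phantoms standing in for patient imaging.

Patient scans cannot be shipped, so every pipeline stage is exercised
on seeded geometric phantoms voxelised on a realistic anisotropic grid
(default 5.0 x 0.7 x 0.7 mm, mimicking routine CT reconstruction; an
MRI-like 3.0 x 0.9 x 0.9 mm variant is used in the regression suite).
The shape menu mirrors the compositions seen in pelvic tumours: solid
spheres/ellipsoids, lumpy blobs (smoothly perturbed radius), bilobed
masses, and a solid nodule on a thin cystic shell where only the solid
part is the tumour ROI (cysts collapse on slicing and are not
modelled).

Sphere and ellipsoid phantoms have closed-form volumes, which makes
them whole-pipeline oracles: the replica volume the pipeline reports
must match ``4/3 π a b c`` to within the voxelisation/smoothing budget.
The pilot volume range the suite spans is 7–133 cm³
(sphere radii 11.85 and 31.71 mm).

The optional mould-base ROI is painted as the patch of tumour surface
voxels within ``base_patch_angle_deg`` of ``base_direction`` — the
same annotation a radiologist would add as an extra ROI.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from mouldforge.imaging_io import (
    CANONICAL_DIRECTION,
    ImageVolume,
    RoiMask,
    SegmentationCase,
    write_nifti,
)

__all__ = ["PhantomSpec", "make_phantom", "make_regression_suite",
           "write_phantom_case"]

SHAPES = ("SPHERE", "ELLIPSOID", "LUMPY", "BILOBED", "SOLID_ON_CYST")

# radii reproducing the pilot study's volume extremes (7 and 133 cm³)
RADIUS_7_CM3 = (3.0 * 7000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
RADIUS_133_CM3 = (3.0 * 133000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    ``size_mm`` is shape-specific:
    SPHERE: ``{"radius": r}``;
    ELLIPSOID / LUMPY: ``{"semi_axes": (a, b, c)}`` along patient
    (L, P, S);
    BILOBED: ``{"radii": (r1, r2), "separation": d}`` (two overlapping
    spheres offset along P);
    SOLID_ON_CYST: ``{"solid_radius": r, "cyst_radius": R}``.
    ``base_direction`` is a patient-space (LPS) unit vector pointing
    from the tumour centre towards the surface patch that should rest
    on the mould floor; ``None`` omits the base ROI (the manual-rotation
    path).
    """

    shape: str = "SPHERE"
    size_mm: dict = field(default_factory=lambda: {"radius": 20.0})
    bumpiness: float = 0.15
    base_direction: Optional[tuple] = (0.0, 1.0, 0.0)
    base_patch_angle_deg: float = 40.0
    spacing_mm: tuple = (5.0, 0.7, 0.7)
    seed: int = 0
    modality: str = "CT"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if not (0.0 <= self.bumpiness < 0.5):
            raise ValueError("bumpiness must be in [0, 0.5)")
        for v in self.size_mm.values():
            arr = np.atleast_1d(np.asarray(v, dtype=float))
            if np.any(arr <= 0):
                raise ValueError("all phantom dimensions must be > 0")


def _extent_mm(spec: PhantomSpec) -> float:
    s = spec.size_mm
    if spec.shape == "SPHERE":
        return s["radius"]
    if spec.shape in ("ELLIPSOID", "LUMPY"):
        return float(max(s["semi_axes"])) * (1.0 + spec.bumpiness + 0.05)
    if spec.shape == "BILOBED":
        r1, r2 = s["radii"]
        return max(r1, r2) + s["separation"] / 2.0
    if spec.shape == "SOLID_ON_CYST":
        return s["solid_radius"] + 2.0 * s["cyst_radius"]
    raise AssertionError


def _smooth_noise(shape_xyz, rng: np.random.Generator,
                  coarse: int = 7) -> np.ndarray:
    """Seeded Gaussian-filtered white noise interpolated to the grid,
    normalised to roughly [-1, 1].  Documented so an oracle can
    regenerate it: white noise on a ``coarse``³ lattice, σ=1 Gaussian
    filter, linear interpolation."""
    field_c = ndimage.gaussian_filter(
        rng.standard_normal((coarse, coarse, coarse)), sigma=1.0
    )
    field_c /= max(np.abs(field_c).max(), 1e-9)
    idx = np.meshgrid(
        *[np.linspace(0, coarse - 1, n) for n in shape_xyz], indexing="ij"
    )
    return ndimage.map_coordinates(field_c, np.array(idx), order=1,
                                   mode="nearest")


def make_phantom(spec: PhantomSpec, case_id: Optional[str] = None
                 ) -> SegmentationCase:
    """Voxelise a phantom onto its anisotropic grid (deterministic in
    ``spec.seed``); returns a SegmentationCase with analytic truths in
    ``meta["truth"]`` where a closed form exists."""
    rng = np.random.default_rng(spec.seed)
    sp = np.asarray(spec.spacing_mm, dtype=float)  # (slice,row,col)=(S,P,L)
    half = _extent_mm(spec) + 6.0
    n = np.ceil(2 * half / sp[::-1]).astype(int) + 1  # (L, P, S) counts -> reversed
    n = n[::-1]
    # voxel-centre coordinates relative to the phantom centre
    zc = (np.arange(n[0]) - (n[0] - 1) / 2.0) * sp[0]
    yc = (np.arange(n[1]) - (n[1] - 1) / 2.0) * sp[1]
    xc = (np.arange(n[2]) - (n[2] - 1) / 2.0) * sp[2]
    Z = zc[:, None, None]
    Y = yc[None, :, None]
    X = xc[None, None, :]

    s = spec.size_mm
    shell = None
    truth_volume = None
    if spec.shape == "SPHERE":
        r = float(s["radius"])
        mask = X ** 2 + Y ** 2 + Z ** 2 < r ** 2
        truth_volume = 4.0 / 3.0 * np.pi * r ** 3
    elif spec.shape == "ELLIPSOID":
        a, b, c = (float(v) for v in s["semi_axes"])
        mask = (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 < 1.0
        truth_volume = 4.0 / 3.0 * np.pi * a * b * c
    elif spec.shape == "LUMPY":
        a, b, c = (float(v) for v in s["semi_axes"])
        m = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
        noise = _smooth_noise(tuple(n), rng)
        mask = m < 1.0 + spec.bumpiness * noise
    elif spec.shape == "BILOBED":
        r1, r2 = (float(v) for v in s["radii"])
        d = float(s["separation"])
        m1 = X ** 2 + (Y + d / 2.0) ** 2 + Z ** 2 < r1 ** 2
        m2 = X ** 2 + (Y - d / 2.0) ** 2 + Z ** 2 < r2 ** 2
        mask = m1 | m2
    elif spec.shape == "SOLID_ON_CYST":
        rs = float(s["solid_radius"])
        rc = float(s["cyst_radius"])
        thick = 2.0
        cy = rs + rc - thick  # shell tangent to (slightly fused with) solid
        mask = X ** 2 + Y ** 2 + Z ** 2 < rs ** 2  # the solid alone is the ROI
        rho2 = X ** 2 + (Y - cy) ** 2 + Z ** 2
        shell = (rho2 < rc ** 2) & (rho2 > (rc - thick) ** 2)
    else:  # pragma: no cover
        raise AssertionError

    if not mask.any():
        raise ValueError("phantom produced an empty tumour mask")
    vox_vol = float(mask.sum()) * float(np.prod(sp))
    if vox_vol < 1000.0:
        warnings.warn(
            f"phantom volume {vox_vol / 1000.0:.2f} cm³ is below the "
            "1 cm³ floor of the pilot range", stacklevel=2,
        )

    intensity = np.where(mask, 100.0, 0.0)
    if shell is not None:
        intensity = np.where(shell, 60.0, intensity)
    intensity += rng.normal(0.0, 2.0, size=mask.shape)

    origin = np.array([-(n[2] - 1) / 2.0 * sp[2],
                       -(n[1] - 1) / 2.0 * sp[1],
                       -(n[0] - 1) / 2.0 * sp[0]])
    image = ImageVolume(
        voxels=intensity.astype(np.float32), spacing=sp, origin=origin,
        direction=CANONICAL_DIRECTION.copy(), modality=spec.modality,
    )

    base = None
    if spec.base_direction is not None:
        d = np.asarray(spec.base_direction, dtype=float)
        d = d / np.linalg.norm(d)
        surf = mask & ~ndimage.binary_erosion(mask)
        # direction of each surface voxel from the tumour centroid
        ci = np.array(ndimage.center_of_mass(mask))
        P = np.stack(np.nonzero(surf), axis=1).astype(float)
        vec = (P - ci) * sp  # mm, (S, P, L) order
        vec_lps = vec[:, ::-1]  # -> (L, P, S)
        norms = np.linalg.norm(vec_lps, axis=1)
        norms[norms == 0] = 1.0
        cosang = (vec_lps @ d) / norms
        keep = cosang >= np.cos(np.radians(spec.base_patch_angle_deg))
        bm = np.zeros_like(mask)
        bm[tuple(P[keep].astype(int).T)] = True
        bm = ndimage.binary_dilation(bm) & mask
        base = RoiMask(bm, name="base of mould", source="SYNTHETIC")

    cx = 0.0  # phantom centre is the grid centre -> patient (0, 0, 0)
    truth = {
        "shape": spec.shape,
        "voxel_volume_mm3": vox_vol,
        "centroid_lps_mm": [cx, cx, cx] if spec.shape != "BILOBED" else None,
        "seed": spec.seed,
    }
    if truth_volume is not None:
        truth["analytic_volume_mm3"] = float(truth_volume)
    return SegmentationCase(
        image=image,
        tumour=RoiMask(mask, name="tumour", source="SYNTHETIC"),
        base=base,
        case_id=case_id or f"{spec.shape.lower()}_seed{spec.seed}",
        meta={"truth": truth, "phantom": spec.shape},
    )


def make_regression_suite() -> list:
    """A fixed seeded set of phantoms spanning the pilot conditions:
    the 7–133 cm³ volume range, both slice-thickness regimes, CT- and
    MRI-like grids, with and without a base ROI."""
    mri = (3.0, 0.9, 0.9)
    specs = [
        ("upper_bound_sphere", PhantomSpec(
            shape="SPHERE", size_mm={"radius": RADIUS_133_CM3}, seed=1), 10.0),
        ("lower_bound_sphere", PhantomSpec(
            shape="SPHERE", size_mm={"radius": RADIUS_7_CM3}, seed=2,
            spacing_mm=mri, modality="MR"), 5.0),
        ("ellipsoid_cc_long", PhantomSpec(
            shape="ELLIPSOID", size_mm={"semi_axes": (20.0, 15.0, 30.0)},
            seed=3), 10.0),
        ("lumpy_blob", PhantomSpec(
            shape="LUMPY", size_mm={"semi_axes": (22.0, 18.0, 20.0)},
            bumpiness=0.15, seed=4), 10.0),
        ("bilobed_no_base", PhantomSpec(
            shape="BILOBED", size_mm={"radii": (18.0, 14.0),
                                      "separation": 20.0},
            base_direction=None, seed=5), 10.0),
        ("solid_on_cyst", PhantomSpec(
            shape="SOLID_ON_CYST",
            size_mm={"solid_radius": 16.0, "cyst_radius": 30.0},
            spacing_mm=mri, modality="MR", seed=6), 5.0),
        ("oblique_base_sphere", PhantomSpec(
            shape="SPHERE", size_mm={"radius": 20.0},
            base_direction=(np.sin(np.radians(37.0)),
                            np.cos(np.radians(37.0)), 0.0),
            seed=7), 10.0),
        ("small_ovoid_5mm", PhantomSpec(
            shape="ELLIPSOID", size_mm={"semi_axes": (13.0, 12.0, 18.0)},
            spacing_mm=mri, modality="MR", seed=8), 5.0),
    ]
    cases = []
    for cid, spec, thickness in specs:
        case = make_phantom(spec, case_id=cid)
        case.meta["slice_thickness_mm"] = thickness
        cases.append(case)
    return cases


def write_phantom_case(case: SegmentationCase, out_dir) -> dict:
    """Write a phantom as NIfTI image + masks with a sidecar JSON of
    analytic truths; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img = case.image
    paths = {"image": out_dir / "image.nii.gz",
             "tumour": out_dir / "tumour.nii.gz"}
    write_nifti(paths["image"], img)
    write_nifti(paths["tumour"], ImageVolume(
        voxels=case.tumour.mask.astype(np.float32), spacing=img.spacing,
        origin=img.origin, direction=img.direction, modality=img.modality))
    if case.base is not None:
        paths["base"] = out_dir / "base.nii.gz"
        write_nifti(paths["base"], ImageVolume(
            voxels=case.base.mask.astype(np.float32), spacing=img.spacing,
            origin=img.origin, direction=img.direction,
            modality=img.modality))
    sidecar = out_dir / "truth.json"
    sidecar.write_text(json.dumps(case.meta.get("truth", {}), indent=2))
    paths["truth"] = sidecar
    return {k: str(v) for k, v in paths.items()}
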