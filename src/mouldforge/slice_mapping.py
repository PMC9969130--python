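"""Per-slice outlines: the radiology–pathology co-registration artefact.

For every tissue slab delimited by the slicing plan, a real-size 2D
outline of the expected cut face is extracted from the oriented
segmentation and annotated with

* the **base arc** — the part of the contour resting on the mould
  floor, and
* the **orientation-incision marker** — the y position and depth of the
  notch the orientation guides score into the top of every slice.

Printed at 100% scale (1 SVG user unit = 1 mm), these pages let the
pathologist match each physical tissue slice to its outline using the
notch and base, and — because slicing is constrained to the anatomical
axial plane — map it back onto the source image with a single fixed
in-plane rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from skimage import measure

from mouldforge.mould_design import MouldSpec, SlitPlan
from mouldforge.orientation import OrientedMask

__all__ = [
    "SliceOutline",
    "SliceToImageMap",
    "extract_outlines",
    "annotate_outline",
    "export_outlines_svg",
    "map_slice_to_image",
    "cavalieri_volume",
]


def _polygon_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class SliceOutline:
    """Outline of one expected tissue slice, in slice-plane (y, z) mm."""

    slab_index: int  # 1-based, inferior -> superior
    x_interval_mm: tuple
    polygons: list  # list of closed (N, 2) arrays, (y, z) mm
    patient_plane: int
    empty: bool = False
    area_mm2: float = 0.0
    base_arc: list = field(default_factory=list)
    incision_marker: Optional[dict] = None
    annotated: bool = False

    @property
    def x_mid_mm(self) -> float:
        return 0.5 * (self.x_interval_mm[0] + self.x_interval_mm[1])

    @property
    def thickness_mm(self) -> float:
        return self.x_interval_mm[1] - self.x_interval_mm[0]


def _patient_plane_index(oriented: OrientedMask, x_mid: float) -> int:
    """Original-image axial slice index a WCS slab mid-plane maps onto."""
    geo = oriented.source_geometry
    c = oriented.tumour_centroid_mm()
    p = oriented.to_image.apply(np.array([x_mid, c[1], c[2]]))
    origin = np.asarray(geo["origin"], dtype=float)
    direction = np.asarray(geo["direction"], dtype=float)
    spacing = np.asarray(geo["spacing"], dtype=float)
    normal = direction[:, 0]
    k = float(np.dot(p - origin, normal) / spacing[0])
    ki = int(round(k))
    if not (0 <= ki < int(geo["shape"][0])):
        raise ValueError(
            f"slab at WCS x={x_mid:.1f} mm maps outside the original "
            f"volume (plane {ki} of {geo['shape'][0]})"
        )
    return ki


def extract_outlines(oriented: OrientedMask, plan: SlitPlan,
                     spec: MouldSpec, mode: str = "midplane") -> list:
    """One outline per tissue slab.

    ``mode="midplane"`` (default) contours the mask cross-section at
    the slab mid-plane — the cut face shown to the pathologist;
    ``mode="projection"`` contours the slab's maximum-area projection
    (union of all planes in the slab).  Contours are extracted at the
    0.5 level, i.e. at sub-voxel precision on the 1 mm grid.
    """
    if mode not in ("midplane", "projection"):
        raise ValueError("mode must be 'midplane' or 'projection'")
    outlines = []
    ox = oriented.origin_mm[0]
    nx = oriented.tumour.shape[0]
    for i, (lo, hi) in enumerate(plan.slab_intervals, start=1):
        mid = 0.5 * (lo + hi)
        if mode == "midplane":
            xi = int(round(mid - ox))
            xi = min(max(xi, 0), nx - 1)
            section = oriented.tumour[xi]
        else:
            i0 = max(int(np.ceil(lo - ox - 0.5)), 0)
            i1 = min(int(np.floor(hi - ox + 0.5)), nx - 1)
            section = oriented.tumour[i0:i1 + 1].any(axis=0)
        polys = []
        if section.any():
            padded = np.pad(section, 1).astype(float)
            for c in measure.find_contours(padded, 0.5):
                polys.append(c - 1.0 + oriented.origin_mm[1:])
        area = float(sum(_polygon_area(p) for p in polys))
        outlines.append(SliceOutline(
            slab_index=i,
            x_interval_mm=(float(lo), float(hi)),
            polygons=polys,
            patient_plane=_patient_plane_index(oriented, mid),
            empty=not polys,
            area_mm2=area,
        ))
    return outlines


def annotate_outline(outline: SliceOutline, oriented: OrientedMask,
                     spec: MouldSpec) -> SliceOutline:
    """Overlay the mould-base contact arc and the orientation-incision
    marker on an outline.

    The base arc is every contour point within ``cavity_clearance_mm +
    1 mm`` of the cavity floor.  The incision marker sits at the tumour
    centroid y (identical across slabs — the two guide slits are
    collinear) and descends from the slice top to the knife depth,
    ``incision_depth_fraction`` of the tumour height below the tumour
    top.  A zero depth fraction disables the marker.
    """
    z_floor, z_top = oriented.z_extent_mm()
    height = z_top - z_floor
    z_band = z_floor + spec.cavity_clearance_mm + 1.0
    outline.base_arc = [
        poly[poly[:, 1] <= z_band] for poly in outline.polygons
        if (poly[:, 1] <= z_band).any()
    ]
    outline.incision_marker = None
    if spec.incision_depth_fraction > 0 and not outline.empty:
        yc = float(oriented.tumour_centroid_mm()[1])
        z_knife = z_top - spec.incision_depth_fraction * height
        # slice top at the incision y (points within the slit width)
        half = max(spec.slit_width_mm, 1.0)
        tops = [
            poly[np.abs(poly[:, 0] - yc) <= half, 1]
            for poly in outline.polygons
        ]
        tops = [t for t in tops if len(t)]
        if tops:
            z_slice_top = float(max(t.max() for t in tops))
            if z_slice_top > z_knife:
                outline.incision_marker = {
                    "y_mm": yc,
                    "z_top_mm": z_slice_top,
                    "z_bottom_mm": float(z_knife),
                    "depth_mm": z_slice_top - float(z_knife),
                }
    outline.annotated = True
    return outline


# ---------------------------------------------------------------------------
# SVG export (real size: 1 user unit = 1 mm)
# ---------------------------------------------------------------------------

_SVG_STYLE = (
    'fill="none" stroke="black" stroke-width="0.35"'
)


def _svg_path(poly: np.ndarray, to_page) -> str:
    pts = to_page(poly)
    d = "M " + " L ".join(f"{p[0]:.2f},{p[1]:.2f}" for p in pts) + " Z"
    return f'<path d="{d}" {_SVG_STYLE}/>'


def export_outlines_svg(outlines: list, out_dir) -> list:
    """Write one real-size SVG page per slab (``slab_NN.svg``).

    The page carries the outline (black), the base arc (blue, thick),
    the incision marker (red), the slab index, its WCS x interval and
    the original-image plane it maps to.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    margin = 10.0
    written = []
    for o in outlines:
        if not o.annotated and not o.empty:
            raise ValueError("outlines must be annotated before export")
        name = out_dir / f"slab_{o.slab_index:02d}.svg"
        label = (
            f"slab {o.slab_index}  x=[{o.x_interval_mm[0]:.1f}, "
            f"{o.x_interval_mm[1]:.1f}] mm  image plane {o.patient_plane}"
        )
        if o.empty:
            w, h = 120.0, 30.0
            body = (
                f'<text x="5" y="12" font-size="4">{label}</text>'
                f'<text x="5" y="20" font-size="4">no tumour in slab</text>'
            )
        else:
            allpts = np.vstack(o.polygons)
            ymin, zmin = allpts.min(axis=0)
            ymax, zmax = allpts.max(axis=0)
            w = (ymax - ymin) + 2 * margin
            h = (zmax - zmin) + 2 * margin + 8.0

            def to_page(pts):
                pts = np.atleast_2d(pts)
                return np.column_stack([
                    pts[:, 0] - ymin + margin,
                    (zmax - pts[:, 1]) + margin,
                ])

            parts = [_svg_path(p, to_page) for p in o.polygons]
            for arc in o.base_arc:
                pp = to_page(arc)
                d = "M " + " L ".join(f"{p[0]:.2f},{p[1]:.2f}" for p in pp)
                parts.append(
                    f'<path d="{d}" fill="none" stroke="blue" '
                    'stroke-width="1.0" class="base-arc"/>'
                )
            if o.incision_marker:
                m = o.incision_marker
                a = to_page([[m["y_mm"], m["z_top_mm"]]])[0]
                b = to_page([[m["y_mm"], m["z_bottom_mm"]]])[0]
                parts.append(
                    f'<line x1="{a[0]:.2f}" y1="{a[1]:.2f}" '
                    f'x2="{b[0]:.2f}" y2="{b[1]:.2f}" stroke="red" '
                    'stroke-width="0.7" class="incision"/>'
                )
            parts.append(
                f'<text x="5" y="{h - 3:.1f}" font-size="4">{label}</text>'
            )
            body = "".join(parts)
        svg = (
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.1f}mm" '
            f'height="{h:.1f}mm" viewBox="0 0 {w:.1f} {h:.1f}">{body}</svg>\n'
        )
        name.write_text(svg)
        written.append(name)
    return written


# ---------------------------------------------------------------------------
# mapping back to the image
# ---------------------------------------------------------------------------

@dataclass
class SliceToImageMap:
    """Fixed in-plane rotation + translation mapping an outline's (y, z)
    coordinates onto the original image's axial plane.

    The rotation angle is the single in-plane angle applied at
    orientation time — identical for every slab by construction, which
    is what makes tissue-to-image co-registration a one-step rotation.
    """

    angle_deg: float
    x_mid_mm: float
    rotation: np.ndarray     # (3, 3): WCS mm -> patient LPS mm
    translation: np.ndarray  # (3,)
    plane_index: int
    source_geometry: dict

    @property
    def matrix(self) -> np.ndarray:
        """(2, 2) in-plane map: (y, z) mm -> patient (L, P) mm."""
        return self.rotation[:2, 1:3]

    def to_patient(self, pts_yz: np.ndarray) -> np.ndarray:
        """Outline (y, z) points -> full patient LPS mm coordinates."""
        pts_yz = np.atleast_2d(pts_yz)
        p3 = np.column_stack([
            np.full(len(pts_yz), self.x_mid_mm), pts_yz
        ])
        return (self.rotation @ p3.T).T + self.translation

    def to_patient_xy(self, pts_yz: np.ndarray) -> np.ndarray:
        return self.to_patient(pts_yz)[:, :2]

    def to_pixel(self, pts_yz: np.ndarray) -> np.ndarray:
        """Outline points -> (row, col) pixel coordinates on the plane."""
        geo = self.source_geometry
        origin = np.asarray(geo["origin"], dtype=float)
        direction = np.asarray(geo["direction"], dtype=float)
        spacing = np.asarray(geo["spacing"], dtype=float)
        p3 = self.to_patient(pts_yz)
        rel = (direction.T @ (p3 - origin).T).T / spacing
        return rel[:, 1:]  # (row, col)


def map_slice_to_image(outline: SliceOutline,
                       oriented: OrientedMask) -> SliceToImageMap:
    """The transform carrying this slab's outline onto its image plane.

    Uses the exact rigid inverse recorded at orientation time: patient
    point = R @ (x_mid, y, z) + t, restricted to the axial in-plane
    components.  The angle reported is common to all slabs.
    """
    x_mid = outline.x_mid_mm
    return SliceToImageMap(
        angle_deg=oriented.in_plane_angle_deg(),
        x_mid_mm=x_mid,
        rotation=oriented.to_image.rotation,
        translation=oriented.to_image.translation,
        plane_index=_patient_plane_index(oriented, x_mid),
        source_geometry=oriented.source_geometry,
    )


def cavalieri_volume(outlines: list) -> float:
    """Sum of outline area x slab thickness (mm³) — a stereological
    estimate of tumour volume used as a cross-check."""
    return float(sum(o.area_mm2 * o.thickness_mm for o in outlines))
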