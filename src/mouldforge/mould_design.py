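"""Design of the four mould structures and their assembly.

The mould is an ensemble of
(i) the **cavity block** — a walled block whose void is carved around
the clearance-inflated convex hull of the tumour replica, truncated at
a tunable fraction of the tumour height;
(ii) the **slicing guide** — a wall along one side carrying evenly
spaced knife slits, one of which is aligned with the tumour centre,
each projected down through the cavity so the knife reaches the floor;
(iii) two **orientation guides** — single-slit end walls whose
collinear slits score a partial-depth "orientation incision" along the
top of the specimen, leaving a notch in every slice; and
(iv) a **baseplate** — a thin plate following the footprint of the
structures at a tunable offset (not a solid bounding block).

Above the height of the widest horizontal cross-section the cavity
walls rise vertically instead of following the narrowing hull, so the
rim opening is never narrower than the widest part of the specimen and
slices cannot overspill while being cut.  This is implemented as a
running union of cavity cross-sections from the floor upward, which
makes the void cross-section non-decreasing with height by
construction.

Booleans are evaluated on a voxel grid (default pitch 0.5 mm); the same
CSG tree is emitted as an OpenSCAD script for reference and manual
tweaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from mouldforge import csg
from mouldforge.csg import VoxelGrid, mask_to_mesh
from mouldforge.orientation import OrientedMask

__all__ = [
    "MouldSpec",
    "SlitPlan",
    "MouldAssembly",
    "plan_slits",
    "build_cavity",
    "build_slicing_guide",
    "build_orientation_guides",
    "build_baseplate",
    "assemble",
    "build_mould",
    "inflate_convex",
    "knife_path_clearance",
    "void_section_areas",
]


@dataclass
class MouldSpec:
    """Tunable parameters of the mould design (all lengths in mm).

    ``slice_thickness_mm`` is the tissue slice width (10 mm default,
    5 mm supported for higher sampling resolution);
    ``slit_width_mm`` the knife slit width (1 mm default — 0.5 mm
    proved too narrow for a tissue knife);
    ``cavity_height_fraction`` the fraction of tumour height covered by
    the cavity walls; ``incision_depth_fraction`` the depth of the
    orientation incision as a fraction of tumour height (0 disables it,
    0.5 or more would bisect the slices and is rejected).
    """

    slice_thickness_mm: float = 10.0
    slit_width_mm: float = 1.0
    cavity_height_fraction: float = 0.8
    wall_thickness_mm: float = 3.0
    baseplate_offset_mm: float = 5.0
    baseplate_thickness_mm: float = 3.0
    guide_height_clearance_mm: float = 2.0
    incision_depth_fraction: float = 0.25
    cavity_clearance_mm: float = 0.5
    voxel_pitch_mm: float = 0.5

    def __post_init__(self) -> None:
        lengths = dict(
            slice_thickness_mm=self.slice_thickness_mm,
            slit_width_mm=self.slit_width_mm,
            wall_thickness_mm=self.wall_thickness_mm,
            baseplate_offset_mm=self.baseplate_offset_mm,
            baseplate_thickness_mm=self.baseplate_thickness_mm,
            guide_height_clearance_mm=self.guide_height_clearance_mm,
            cavity_clearance_mm=self.cavity_clearance_mm,
            voxel_pitch_mm=self.voxel_pitch_mm,
        )
        for k, v in lengths.items():
            if v <= 0:
                raise ValueError(f"{k} must be > 0, got {v}")
        if self.slit_width_mm >= self.slice_thickness_mm:
            raise ValueError("slit width must be smaller than slice thickness")
        if not (0.0 < self.cavity_height_fraction <= 1.0):
            raise ValueError("cavity_height_fraction must be in (0, 1]")
        if self.incision_depth_fraction >= 0.5:
            raise ValueError(
                "incision would bisect slices: incision_depth_fraction "
                "must be < 0.5"
            )
        if self.incision_depth_fraction < 0.0:
            raise ValueError("incision_depth_fraction must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SlitPlan:
    """Slit-plane x positions and the tissue slabs they delimit."""

    slit_x_mm: np.ndarray
    slab_intervals: list
    centre_x_mm: float
    x_extent_mm: tuple

    def __post_init__(self) -> None:
        self.slit_x_mm = np.asarray(self.slit_x_mm, dtype=float)

    @property
    def n_slits(self) -> int:
        return len(self.slit_x_mm)


def plan_slits(x_extent, spec: MouldSpec) -> SlitPlan:
    """Place slits at the tumour centre and at thickness intervals
    either side, for as long as they fall within the tumour extent.

    A lesion shorter than one slice thickness gets a single central
    slit (with a warning); the slit count otherwise equals the
    length / thickness division rule whenever that quotient is odd, and
    deviates by one for even quotients because central alignment takes
    precedence.
    """
    x_min, x_max = float(x_extent[0]), float(x_extent[1])
    if not x_max > x_min:
        raise ValueError("x_max must exceed x_min")
    t = spec.slice_thickness_mm
    centre = 0.5 * (x_min + x_max)
    length = x_max - x_min
    eps = 1e-9
    if length < t:
        warnings.warn(
            f"single-slab lesion: extent {length:.1f} mm is shorter than "
            f"one slice thickness ({t} mm)",
            stacklevel=2,
        )
        ks = [0]
    else:
        kmax = int(np.floor((0.5 * length) / t + eps))
        ks = range(-kmax, kmax + 1)
    slits = np.array([centre + k * t for k in ks])
    edges = np.concatenate([[x_min], slits, [x_max]])
    slabs = [
        (float(a), float(b))
        for a, b in zip(edges[:-1], edges[1:])
        if b - a > eps
    ]
    return SlitPlan(
        slit_x_mm=slits, slab_intervals=slabs,
        centre_x_mm=centre, x_extent_mm=(x_min, x_max),
    )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def inflate_convex(hull: trimesh.Trimesh, clearance: float) -> trimesh.Trimesh:
    """Offset a convex mesh outward by ``clearance`` along vertex normals.

    For a convex solid this approximates the Minkowski sum with a
    sphere (it under-reaches only at sharp edges, by less than the
    clearance itself) and keeps the result a convex polyhedron, so it
    remains expressible as an OpenSCAD ``polyhedron``.
    """
    v = hull.vertices + clearance * hull.vertex_normals
    out = trimesh.convex.convex_hull(trimesh.PointCloud(v))
    if out.volume < 0:
        out.invert()
    return out


def _mask_polygons(mask2d: np.ndarray, grid: VoxelGrid) -> list:
    """Closed (x, y) mm contour polygons of a 2D footprint mask."""
    padded = np.pad(mask2d, 1).astype(float)
    polys = []
    for c in measure.find_contours(padded, 0.5):
        pts = (c - 1.0) * grid.pitch + grid.origin[:2]
        polys.append(pts)
    return polys


def _dilate2d(mask2d: np.ndarray, radius_mm: float, pitch: float) -> np.ndarray:
    if radius_mm <= 0:
        return mask2d.copy()
    dist = ndimage.distance_transform_edt(~mask2d, sampling=pitch)
    return dist <= radius_mm


def _extrude(mask2d: np.ndarray, grid: VoxelGrid, z0: float,
             z1: float) -> np.ndarray:
    out = grid.empty()
    zc = grid.axis_coords(2)
    zsel = np.where((zc >= z0) & (zc <= z1))[0]
    if len(zsel):
        out[:, :, zsel[0]:zsel[-1] + 1] = mask2d[:, :, None]
    return out


def _tumour_geometry(source) -> dict:
    """Extract the tumour's WCS bounding geometry from an OrientedMask
    or a replica mesh."""
    if isinstance(source, OrientedMask):
        x_lo, x_hi = source.x_extent_mm()
        z_lo, z_hi = source.z_extent_mm()
        c = source.tumour_centroid_mm()
        return dict(x=(x_lo, x_hi), z=(z_lo, z_hi), centroid_y=float(c[1]))
    mesh = source
    lo, hi = mesh.bounds
    centroid = mesh.center_mass if mesh.is_watertight else mesh.centroid
    return dict(x=(float(lo[0]), float(hi[0])),
                z=(float(lo[2]), float(hi[2])),
                centroid_y=float(centroid[1]))


def _assembly_grid(hull_infl: trimesh.Trimesh, geo: dict,
                   spec: MouldSpec) -> VoxelGrid:
    """One voxel grid large enough for every mould structure."""
    lo, hi = hull_infl.bounds
    pad = 2.0 * spec.voxel_pitch_mm
    margin_xy = (spec.wall_thickness_mm + spec.baseplate_offset_mm
                 + spec.wall_thickness_mm + pad)
    z_floor = geo["z"][0]
    height = geo["z"][1] - geo["z"][0]
    z_top = z_floor + height + spec.guide_height_clearance_mm + pad
    z_bot = z_floor - spec.baseplate_thickness_mm - pad
    return VoxelGrid.from_bounds(
        (lo[0] - margin_xy, lo[1] - margin_xy, z_bot),
        (hi[0] + margin_xy, hi[1] + margin_xy, z_top),
        spec.voxel_pitch_mm,
    )


# ---------------------------------------------------------------------------
# internal builder: all structures on one shared grid
# ---------------------------------------------------------------------------

class _MouldBuilder:
    """Computes every mould structure as a voxel mask plus its CSG node
    on a single shared grid."""

    def __init__(self, hull: trimesh.Trimesh, geo: dict, spec: MouldSpec,
                 grid: Optional[VoxelGrid] = None) -> None:
        self.spec = spec
        self.geo = geo
        self.hull_infl = inflate_convex(hull, spec.cavity_clearance_mm)
        self.grid = grid or _assembly_grid(self.hull_infl, geo, spec)
        g = self.grid
        self.z_floor = geo["z"][0]
        self.height = geo["z"][1] - geo["z"][0]
        self.z_top = geo["z"][1]
        self.z_guide_top = self.z_top + spec.guide_height_clearance_mm
        self.z_grid_top = float(g.axis_coords(2)[-1]) + g.pitch

        self._void = None
        self._cavity = None
        self.warnings: list[str] = []

    # -- cavity -----------------------------------------------------------

    def void(self) -> tuple[np.ndarray, csg.Node]:
        if self._void is not None:
            return self._void
        g, spec = self.grid, self.spec
        hull_vox = csg.ConvexPolyhedron(self.hull_infl).voxelise(g)
        # running union upward: walls rise vertically above the widest
        # cross-section instead of following the narrowing hull
        void = np.logical_or.accumulate(hull_vox, axis=2)
        zc = g.axis_coords(2)
        void[:, :, zc < self.z_floor - g.pitch / 2] = False
        areas = hull_vox.sum(axis=(0, 1))
        zi_widest = int(np.argmax(areas))
        widest_polys = _mask_polygons(hull_vox[:, :, zi_widest], g)
        node = csg.Union(
            [
                csg.ConvexPolyhedron(self.hull_infl,
                                     name="clearance-inflated hull"),
                csg.Prism(widest_polys, float(zc[zi_widest]),
                          self.z_grid_top,
                          name="vertical walls above widest contour"),
            ],
            name="cavity void",
        )
        self._hull_vox = hull_vox
        self._zi_widest = zi_widest
        self._void = (void, node)
        return self._void

    def cavity(self) -> tuple[np.ndarray, csg.Node]:
        if self._cavity is not None:
            return self._cavity
        g, spec = self.grid, self.spec
        void, void_node = self.void()
        z_rim = self.z_floor + spec.cavity_height_fraction * self.height
        if z_rim - self.z_floor < 0.10 * self.height:
            raise ValueError(
                "cavity too shallow: rim below 10% of tumour height"
            )
        self.z_rim = z_rim
        foot = void.any(axis=2)
        block_foot = _dilate2d(foot, spec.wall_thickness_mm, g.pitch)
        block = _extrude(block_foot, g, self.z_floor, z_rim) & ~void
        node = csg.Difference(
            csg.Prism(_mask_polygons(block_foot, g), self.z_floor, z_rim,
                      name="cavity block outer"),
            [void_node],
            name="cavity block",
        )
        self.block_foot = block_foot
        xs = np.where(block_foot.any(axis=1))[0]
        ys = np.where(block_foot.any(axis=0))[0]
        xc, yc = g.axis_coords(0), g.axis_coords(1)
        self.block_x = (float(xc[xs[0]]) - g.pitch / 2,
                        float(xc[xs[-1]]) + g.pitch / 2)
        self.block_y = (float(yc[ys[0]]) - g.pitch / 2,
                        float(yc[ys[-1]]) + g.pitch / 2)
        self._cavity = (block, node)
        return self._cavity

    # -- slicing guide ----------------------------------------------------

    def slicing_guide(self, plan: SlitPlan) -> tuple[np.ndarray, csg.Node]:
        g, spec = self.grid, self.spec
        self.cavity()
        y0 = self.block_y[0]
        wall = csg.Box(
            (self.block_x[0], y0 - spec.wall_thickness_mm, self.z_floor),
            (self.block_x[1], y0, self.z_guide_top),
            name="slicing guide wall",
        )
        return wall.voxelise(g), wall

    def slit_voids(self, plan: SlitPlan) -> tuple[np.ndarray, list]:
        g, spec = self.grid, self.spec
        self.cavity()
        w = spec.slit_width_mm / 2.0
        boxes = []
        ylo = g.origin[1] - g.pitch
        yhi = g.origin[1] + g.pitch * g.shape[1]
        for i, x in enumerate(plan.slit_x_mm):
            lo_x, hi_x = x - w, x + w
            if lo_x < self.block_x[0] or hi_x > self.block_x[1]:
                self.warnings.append(
                    f"slit at x={x:.1f} mm overlaps the cavity end wall; "
                    "trimmed to the block extent"
                )
                lo_x = max(lo_x, self.block_x[0])
                hi_x = min(hi_x, self.block_x[1])
            boxes.append(csg.Box(
                (lo_x, ylo - spec.wall_thickness_mm, self.z_floor),
                (hi_x, yhi, self.z_grid_top),
                name=f"slicing slit {i + 1}",
            ))
        mask = g.empty()
        for b in boxes:
            mask |= b.voxelise(g)
        return mask, boxes

    # -- orientation guides ----------------------------------------------

    def orientation_guides(self) -> tuple[list, list, Optional[csg.Box]]:
        """Two end walls plus the collinear incision slit void."""
        g, spec = self.grid, self.spec
        self.cavity()
        wt = spec.wall_thickness_mm
        walls = [
            csg.Box((self.block_x[0] - wt, self.block_y[0], self.z_floor),
                    (self.block_x[0], self.block_y[1], self.z_guide_top),
                    name="orientation guide (inferior)"),
            csg.Box((self.block_x[1], self.block_y[0], self.z_floor),
                    (self.block_x[1] + wt, self.block_y[1], self.z_guide_top),
                    name="orientation guide (superior)"),
        ]
        masks = [w.voxelise(g) for w in walls]
        slit = None
        if spec.incision_depth_fraction > 0:
            yc = self.geo["centroid_y"]
            w = spec.slit_width_mm / 2.0
            z_bottom = self.z_top - spec.incision_depth_fraction * self.height
            slit = csg.Box(
                (self.block_x[0] - wt - g.pitch, yc - w, z_bottom),
                (self.block_x[1] + wt + g.pitch, yc + w, self.z_grid_top),
                name="orientation incision slit",
            )
        return masks, walls, slit

    # -- baseplate --------------------------------------------------------

    def baseplate(self, part_masks: list) -> tuple[np.ndarray, csg.Node]:
        g, spec = self.grid, self.spec
        foot = np.zeros(g.shape[:2], dtype=bool)
        for m in part_masks:
            foot |= m.any(axis=2)
        foot = _dilate2d(foot, spec.baseplate_offset_mm, g.pitch)
        z0 = self.z_floor - spec.baseplate_thickness_mm
        plate = _extrude(foot, g, z0, self.z_floor - g.pitch / 2)
        node = csg.Prism(_mask_polygons(foot, g), z0, self.z_floor,
                         name="baseplate")
        return plate, node


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _attach(mesh: trimesh.Trimesh, builder: _MouldBuilder,
            mask: np.ndarray, node: csg.Node) -> trimesh.Trimesh:
    mesh.metadata["mould"] = {
        "builder": builder, "mask": mask, "node": node,
        "grid": builder.grid,
    }
    return mesh


def build_cavity(hull: trimesh.Trimesh, tumour, spec: MouldSpec,
                 grid: Optional[VoxelGrid] = None) -> trimesh.Trimesh:
    """Build the cavity block: outer walls following the hull footprint,
    inner void carved around the clearance-inflated hull, truncated at
    ``cavity_height_fraction`` of the tumour height, with vertical walls
    above the widest cross-section."""
    geo = _tumour_geometry(tumour)
    builder = _MouldBuilder(hull, geo, spec, grid)
    mask, node = builder.cavity()
    mesh = mask_to_mesh(mask, builder.grid, "MOULD_PART")
    return _attach(mesh, builder, mask, node)


def build_slicing_guide(plan: SlitPlan, cavity_block: trimesh.Trimesh,
                        spec: MouldSpec) -> trimesh.Trimesh:
    """Guide wall along the -y side of the cavity carrying one knife
    slit per plan entry, each projected through the full cavity."""
    meta = cavity_block.metadata.get("mould")
    if meta is None:
        raise ValueError(
            "cavity_block must come from build_cavity (shared-grid metadata)"
        )
    builder: _MouldBuilder = meta["builder"]
    wall_mask, wall_node = builder.slicing_guide(plan)
    slit_mask, slit_boxes = builder.slit_voids(plan)
    for w in builder.warnings:
        warnings.warn(w, stacklevel=2)
    mask = wall_mask & ~slit_mask
    node = csg.Difference(wall_node, list(slit_boxes), name="slicing guide")
    mesh = mask_to_mesh(mask, builder.grid, "MOULD_PART")
    mesh.metadata["slit_x_mm"] = plan.slit_x_mm.tolist()
    return _attach(mesh, builder, mask, node)


def build_orientation_guides(plan: SlitPlan, tumour, spec: MouldSpec,
                             cavity_block: Optional[trimesh.Trimesh] = None,
                             ) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Two single-slit end walls whose collinear slits define the
    orientation incision across the specimen top."""
    if cavity_block is not None and "mould" in cavity_block.metadata:
        builder = cavity_block.metadata["mould"]["builder"]
    else:
        from mouldforge.tumour_modelling import convex_hull as _ch, marching_cubes as _mc
        if isinstance(tumour, OrientedMask):
            hull = _ch(_mc(tumour))
        else:
            hull = _ch(tumour)
        builder = _MouldBuilder(hull, _tumour_geometry(tumour), spec)
    masks, walls, slit = builder.orientation_guides()
    out = []
    for m, w in zip(masks, walls):
        if slit is not None:
            m = m & ~slit.voxelise(builder.grid)
            node = csg.Difference(w, [slit], name=w.name)
        else:
            node = w
        mesh = mask_to_mesh(m, builder.grid, "MOULD_PART")
        out.append(_attach(mesh, builder, m, node))
    return out[0], out[1]


def build_baseplate(parts: list, spec: MouldSpec) -> trimesh.Trimesh:
    """A plate under the union of part footprints dilated in-plane by
    ``baseplate_offset_mm`` — a rim following the structures, not a
    bounding rectangle."""
    if not parts:
        raise ValueError("baseplate needs at least one part")
    metas = [p.metadata.get("mould") for p in parts]
    if all(m is not None for m in metas) and len(
        {id(m["grid"]) for m in metas}
    ) == 1:
        builder = metas[0]["builder"]
        mask, node = builder.baseplate([m["mask"] for m in metas])
        mesh = mask_to_mesh(mask, builder.grid, "MOULD_PART")
        return _attach(mesh, builder, mask, node)
    # standalone path: rasterise part footprints from their triangles
    from skimage.draw import polygon as _draw_poly

    pitch = spec.voxel_pitch_mm
    lo = np.min([p.bounds[0] for p in parts], axis=0)
    hi = np.max([p.bounds[1] for p in parts], axis=0)
    pad = spec.baseplate_offset_mm + 2 * pitch
    grid = VoxelGrid.from_bounds(
        (lo[0] - pad, lo[1] - pad, lo[2] - spec.baseplate_thickness_mm - pad),
        (hi[0] + pad, hi[1] + pad, hi[2] + pad), pitch,
    )
    foot = np.zeros(grid.shape[:2], dtype=bool)
    for p in parts:
        tri2d = p.vertices[:, :2][p.faces]
        for tri in tri2d:
            ij = (tri - grid.origin[:2]) / pitch
            rr, cc = _draw_poly(ij[:, 0], ij[:, 1], shape=foot.shape)
            foot[rr, cc] = True
    foot = _dilate2d(foot, spec.baseplate_offset_mm, pitch)
    z_floor = float(lo[2])
    z0 = z_floor - spec.baseplate_thickness_mm
    plate = _extrude(foot, grid, z0, z_floor - pitch / 2)
    mesh = mask_to_mesh(plate, grid, "MOULD_PART")
    mesh.metadata["footprint_area_mm2"] = float(foot.sum()) * pitch ** 2
    mesh.metadata["footprint_components"] = int(
        ndimage.label(foot)[1]
    )
    return mesh


@dataclass
class MouldAssembly:
    """The assembled mould, its constituent parts and CSG description."""

    cavity_block: trimesh.Trimesh
    slicing_guide: trimesh.Trimesh
    orientation_guides: tuple
    baseplate: trimesh.Trimesh
    assembled: trimesh.Trimesh
    scad_script: str
    plan: SlitPlan
    spec: MouldSpec
    grid: VoxelGrid
    masks: dict = field(default_factory=dict)
    tree: Optional[csg.Node] = None
    warnings: list = field(default_factory=list)

    @property
    def z_floor(self) -> float:
        return self.masks["z_floor"]


SCAD_HEADER = (
    "// mouldforge — lesion-specific slicing mould\n"
    "// units: mm; WCS: x = craniocaudal slicing axis, z = up\n"
)


def build_mould(oriented: OrientedMask, replica: trimesh.Trimesh,
                hull: trimesh.Trimesh, spec: MouldSpec,
                plan: Optional[SlitPlan] = None) -> MouldAssembly:
    """Build and assemble all four mould structures on one shared grid."""
    geo = _tumour_geometry(oriented)
    if plan is None:
        plan = plan_slits(geo["x"], spec)
    builder = _MouldBuilder(hull, geo, spec)
    g = builder.grid

    block_mask, block_node = builder.cavity()
    void_mask, void_node = builder.void()
    wall_mask, wall_node = builder.slicing_guide(plan)
    slit_mask, slit_boxes = builder.slit_voids(plan)
    og_masks, og_walls, inc_slit = builder.orientation_guides()

    guide_mask = wall_mask & ~slit_mask
    og_final = []
    for m in og_masks:
        mm = m & ~inc_slit.voxelise(g) if inc_slit is not None else m
        og_final.append(mm)

    plate_mask, plate_node = builder.baseplate(
        [block_mask, guide_mask] + og_final
    )

    solid = block_mask | wall_mask | og_masks[0] | og_masks[1] | plate_mask
    voids = slit_mask | void_mask
    if inc_slit is not None:
        voids |= inc_slit.voxelise(g)
    assembled_mask = solid & ~voids

    subtract = [void_node] + list(slit_boxes)
    if inc_slit is not None:
        subtract.append(inc_slit)
    tree = csg.Difference(
        csg.Union([block_node, wall_node] + og_walls + [plate_node],
                  name="mould structures"),
        subtract,
        name="assembled mould",
    )
    scad = SCAD_HEADER + tree.to_scad()

    def mesh_of(mask, name):
        return mask_to_mesh(mask, g, name)

    cavity_mesh = _attach(mesh_of(block_mask, "MOULD_PART"), builder,
                          block_mask, block_node)
    guide_mesh = _attach(mesh_of(guide_mask, "MOULD_PART"), builder,
                         guide_mask, wall_node)
    og_meshes = tuple(
        _attach(mesh_of(m, "MOULD_PART"), builder, m, w)
        for m, w in zip(og_final, og_walls)
    )
    plate_mesh = _attach(mesh_of(plate_mask, "MOULD_PART"), builder,
                         plate_mask, plate_node)
    assembled_mesh = mesh_of(assembled_mask, "MOULD_PART")

    return MouldAssembly(
        cavity_block=cavity_mesh,
        slicing_guide=guide_mesh,
        orientation_guides=og_meshes,
        baseplate=plate_mesh,
        assembled=assembled_mesh,
        scad_script=scad,
        plan=plan,
        spec=spec,
        grid=g,
        masks={
            "assembled": assembled_mask,
            "void": void_mask,
            "cavity_block": block_mask,
            "slicing_guide": guide_mask,
            "orientation_guides": og_final,
            "baseplate": plate_mask,
            "z_floor": builder.z_floor,
            "z_rim": builder.z_rim,
            "zi_widest": builder._zi_widest,
            "block_y": builder.block_y,
            "block_x": builder.block_x,
            "hull_infl_vox": builder._hull_vox,
            "hull_infl": builder.hull_infl,
        },
        tree=tree,
        warnings=list(builder.warnings),
    )


def assemble(cavity_block, slicing_guide, orientation_guides, baseplate,
             replica_inflated=None) -> trimesh.Trimesh:
    """Union the parts and subtract the cavity/slit voids.

    Parts must share the grid they were built on (they do when produced
    by the build_* functions of this module with a common cavity block).
    """
    parts = [cavity_block, slicing_guide, *orientation_guides, baseplate]
    metas = [p.metadata.get("mould") for p in parts]
    if any(m is None for m in metas):
        raise ValueError("assemble expects parts built by this module")
    if len({id(m["grid"]) for m in metas}) != 1:
        raise ValueError("parts were not built on a shared grid")
    builder: _MouldBuilder = metas[0]["builder"]
    g = builder.grid
    solid = np.zeros(g.shape, dtype=bool)
    for m in metas:
        solid |= m["mask"]
    void_mask, _ = builder.void()
    assembled = solid & ~void_mask
    return mask_to_mesh(assembled, g, "MOULD_PART")


# ---------------------------------------------------------------------------
# verification helpers (used by tests and the run report)
# ---------------------------------------------------------------------------

def knife_path_clearance(assembly: MouldAssembly) -> list:
    """For every slit, check the vertical strip at the slit's x is void
    from above the rim down to the cavity floor across the cavity width.

    Returns one dict per slit with the number of obstructing voxels.
    """
    g = assembly.grid
    mask = assembly.masks["assembled"]
    z_floor = assembly.masks["z_floor"]
    y0, y1 = assembly.masks["block_y"]
    spec = assembly.spec
    zc = g.axis_coords(2)
    yc = g.axis_coords(1)
    zsel = (zc >= z_floor + g.pitch / 2) & (zc <= assembly.masks["z_rim"])
    ysel = (yc >= y0 - spec.wall_thickness_mm) & (yc <= y1)
    out = []
    for x in assembly.plan.slit_x_mm:
        xi = g.index_of(float(x), 0)
        # voxel columns strictly inside the slit width
        half = spec.slit_width_mm / 2.0 - g.pitch / 2.0
        xc = g.axis_coords(0)
        xsel = np.abs(xc - x) <= max(half, 1e-9)
        if not xsel.any():
            xsel = np.zeros_like(xc, dtype=bool)
            xsel[xi] = True
        strip = mask[np.ix_(xsel, ysel, zsel)]
        out.append({
            "x_mm": float(x),
            "obstructing_voxels": int(strip.sum()),
            "clear": bool(strip.sum() == 0),
        })
    return out


def void_section_areas(assembly: MouldAssembly) -> tuple[np.ndarray, np.ndarray]:
    """Cross-section areas (mm²) of the cavity void per z level."""
    g = assembly.grid
    void = assembly.masks["void"]
    areas = void.sum(axis=(0, 1)).astype(float) * g.pitch ** 2
    return g.axis_coords(2), areas


def containment_penetration(assembly: MouldAssembly) -> float:
    """Worst-case penetration depth (mm) of the assembled solid into
    the clearance-inflated hull of the replica.

    The inflated hull contains the inflated replica, so this bounds the
    replica penetration from above.  Depth is measured at solid voxel
    centres against the hull's facet planes (convex: depth inside =
    -max signed plane distance).  A well-formed mould touches the
    inflated replica only where the baseplate meets the specimen base,
    i.e. by at most the cavity clearance.
    """
    from scipy.spatial import ConvexHull as _CH

    g = assembly.grid
    solid = assembly.masks["assembled"]
    hull_vox = assembly.masks["hull_infl_vox"]
    pen = solid & hull_vox
    if not pen.any():
        return 0.0
    pts = np.argwhere(pen) * g.pitch + g.origin
    eq = _CH(np.asarray(assembly.masks["hull_infl"].vertices)).equations
    d = pts @ eq[:, :3].T + eq[:, 3]
    depth = -d.max(axis=1)  # positive inside the inflated hull
    return float(max(0.0, depth.max()))
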