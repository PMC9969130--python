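"""Constructive solid geometry for the mould structures.

The mould is described as a small CSG tree of axis-aligned boxes,
extruded 2D footprints (prisms) and convex polyhedra combined with
union/difference.  The same tree serves two purposes:

* it renders to an OpenSCAD script (``to_scad``) — the human-readable
  reference description of the mould, in millimetres;
* it evaluates itself onto a voxel grid (``voxelise``) — the boolean
  engine actually used to produce the printable STL, robust for any
  input geometry.  Meshes are recovered from the voxelisation by
  marching cubes at the 0.5 level.

Voxelisation uses voxel-centre sampling at a configurable pitch
(default 0.5 mm), consistent with the rasterisation convention used on
the imaging side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import trimesh
from skimage import measure

__all__ = [
    "VoxelGrid", "Node", "Box", "Prism", "ConvexPolyhedron",
    "Union", "Difference", "mask_to_mesh",
]


@dataclass
class VoxelGrid:
    """An axis-aligned WCS voxel grid, arrays indexed (x, y, z).

    ``origin`` is the WCS position (mm) of the centre of voxel (0,0,0);
    ``pitch`` is the edge length of a voxel in mm.
    """

    origin: np.ndarray
    pitch: float
    shape: tuple

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.shape = tuple(int(s) for s in self.shape)

    @classmethod
    def from_bounds(cls, lo, hi, pitch: float) -> "VoxelGrid":
        # snap to the absolute pitch lattice so grids built for nearly
        # identical geometry sample at identical positions (keeps
        # voxelisations reproducible across equivalent runs)
        lo = np.floor(np.asarray(lo, dtype=float) / pitch) * pitch
        hi = np.asarray(hi, dtype=float)
        shape = tuple(int(np.ceil((h - l) / pitch)) + 1
                      for l, h in zip(lo, hi))
        return cls(origin=lo + pitch / 2.0, pitch=pitch, shape=shape)

    def axis_coords(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.pitch * np.arange(self.shape[axis])

    def empty(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=bool)

    def index_of(self, coord: float, axis: int) -> int:
        return int(round((coord - self.origin[axis]) / self.pitch))

    def xy_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of voxel-centre (x, y) coordinates, shape (nx, ny)."""
        x = self.axis_coords(0)
        y = self.axis_coords(1)
        return np.meshgrid(x, y, indexing="ij")

    def voxel_volume_mm3(self, mask: np.ndarray) -> float:
        return float(mask.sum()) * self.pitch ** 3


def mask_to_mesh(mask: np.ndarray, grid: VoxelGrid,
                 provenance: str = "MOULD_PART") -> trimesh.Trimesh:
    """Marching-cubes surface of a voxel mask, vertices in WCS mm."""
    if not mask.any():
        raise ValueError("cannot mesh an empty voxel mask")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * grid.pitch + grid.origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    mesh.metadata["provenance"] = provenance
    return mesh


def _fmt(v: float) -> str:
    return f"{v:.3f}".rstrip("0").rstrip(".")


def _pts2d_scad(pts: np.ndarray) -> str:
    return "[" + ", ".join(f"[{_fmt(p[0])}, {_fmt(p[1])}]" for p in pts) + "]"


class Node:
    """Base CSG node."""

    name: str = ""

    def voxelise(self, grid: VoxelGrid) -> np.ndarray:
        raise NotImplementedError

    def to_scad(self, indent: int = 0) -> str:
        raise NotImplementedError

    def _comment(self, pad: str) -> str:
        return f"{pad}// {self.name}\n" if self.name else ""


@dataclass
class Box(Node):
    """Axis-aligned box [lo, hi] in WCS mm."""

    lo: Sequence[float]
    hi: Sequence[float]
    name: str = ""

    def voxelise(self, grid: VoxelGrid) -> np.ndarray:
        out = grid.empty()
        sl = []
        for ax in range(3):
            c = grid.axis_coords(ax)
            inside = (c >= self.lo[ax]) & (c <= self.hi[ax])
            idx = np.where(inside)[0]
            if len(idx) == 0:
                return out
            sl.append(slice(idx[0], idx[-1] + 1))
        out[tuple(sl)] = True
        return out

    def to_scad(self, indent: int = 0) -> str:
        pad = " " * indent
        lo = np.asarray(self.lo, dtype=float)
        size = np.asarray(self.hi, dtype=float) - lo
        return (
            self._comment(pad)
            + f"{pad}translate([{_fmt(lo[0])}, {_fmt(lo[1])}, {_fmt(lo[2])}]) "
            f"cube([{_fmt(size[0])}, {_fmt(size[1])}, {_fmt(size[2])}]);\n"
        )


@dataclass
class Prism(Node):
    """One or more 2D (x, y) polygons extruded from z0 to z1."""

    polygons: list  # list of (N, 2) arrays, mm
    z0: float
    z1: float
    name: str = ""

    def voxelise(self, grid: VoxelGrid) -> np.ndarray:
        import shapely
        from shapely.geometry import Polygon

        out = grid.empty()
        zc = grid.axis_coords(2)
        zsel = np.where((zc >= self.z0) & (zc <= self.z1))[0]
        if len(zsel) == 0:
            return out
        X, Y = grid.xy_points()
        foot = np.zeros(X.shape, dtype=bool)
        for poly in self.polygons:
            sp = Polygon(np.asarray(poly))
            if not sp.is_valid:
                sp = sp.buffer(0)
            foot |= shapely.contains_xy(sp, X.ravel(), Y.ravel()).reshape(X.shape)
        out[:, :, zsel[0]:zsel[-1] + 1] = foot[:, :, None]
        return out

    def to_scad(self, indent: int = 0) -> str:
        pad = " " * indent
        body = "".join(
            f"{pad}    polygon(points={_pts2d_scad(np.asarray(p))});\n"
            for p in self.polygons
        )
        return (
            self._comment(pad)
            + f"{pad}translate([0, 0, {_fmt(self.z0)}])\n"
            f"{pad}  linear_extrude(height={_fmt(self.z1 - self.z0)})\n"
            f"{pad}  union() {{\n{body}{pad}  }}\n"
        )


@dataclass
class ConvexPolyhedron(Node):
    """A convex solid given by a watertight convex mesh (mm)."""

    mesh: trimesh.Trimesh
    name: str = ""

    def voxelise(self, grid: VoxelGrid) -> np.ndarray:
        import shapely
        from shapely.geometry import Polygon
        from scipy.spatial import ConvexHull as _CH

        out = grid.empty()
        verts = np.asarray(self.mesh.vertices)
        edges = self.mesh.edges_unique
        a = verts[edges[:, 0]]
        b = verts[edges[:, 1]]
        X, Y = grid.xy_points()
        zc = grid.axis_coords(2)
        zmin, zmax = verts[:, 2].min(), verts[:, 2].max()
        for zi, z in enumerate(zc):
            if z < zmin or z > zmax:
                continue
            da, db = a[:, 2] - z, b[:, 2] - z
            crossing = (da * db) <= 0
            da_c, db_c = da[crossing], db[crossing]
            denom = da_c - db_c
            ok = np.abs(denom) > 1e-12
            t = np.where(ok, da_c / np.where(ok, denom, 1.0), 0.0)
            pts = a[crossing][:, :2] + t[:, None] * (
                b[crossing][:, :2] - a[crossing][:, :2]
            )
            if len(pts) < 3:
                continue
            try:
                h2 = _CH(pts)
            except Exception:
                continue
            ring = pts[h2.vertices]
            sp = Polygon(ring)
            if sp.area <= 0:
                continue
            out[:, :, zi] = shapely.contains_xy(
                sp, X.ravel(), Y.ravel()
            ).reshape(X.shape)
        return out

    def to_scad(self, indent: int = 0) -> str:
        pad = " " * indent
        v = np.asarray(self.mesh.vertices)
        f = np.asarray(self.mesh.faces)
        pts = ", ".join(
            f"[{_fmt(p[0])}, {_fmt(p[1])}, {_fmt(p[2])}]" for p in v
        )
        # OpenSCAD expects clockwise-from-outside faces (reverse winding)
        fcs = ", ".join(
            f"[{tri[2]}, {tri[1]}, {tri[0]}]" for tri in f
        )
        return (
            self._comment(pad)
            + f"{pad}polyhedron(points=[{pts}], faces=[{fcs}]);\n"
        )


@dataclass
class Union(Node):
    children: list
    name: str = ""

    def voxelise(self, grid: VoxelGrid) -> np.ndarray:
        out = grid.empty()
        for c in self.children:
            out |= c.voxelise(grid)
        return out

    def to_scad(self, indent: int = 0) -> str:
        pad = " " * indent
        inner = "".join(c.to_scad(indent + 2) for c in self.children)
        return self._comment(pad) + f"{pad}union() {{\n{inner}{pad}}}\n"


@dataclass
class Difference(Node):
    base: Node
    subtract: list
    name: str = ""

    def voxelise(self, grid: VoxelGrid) -> np.ndarray:
        out = self.base.voxelise(grid)
        for c in self.subtract:
            out &= ~c.voxelise(grid)
        return out

    def to_scad(self, indent: int = 0) -> str:
        pad = " " * indent
        inner = self.base.to_scad(indent + 2)
        inner += "".join(c.to_scad(indent + 2) for c in self.subtract)
        return self._comment(pad) + f"{pad}difference() {{\n{inner}{pad}}}\n"
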