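"""Parametric cartilage defects: carving, intact-surface reconstruction,
relocation at constant normalized penetration depth, and drainage
boundary conditions.

A defect is described by a closed footprint polygon in a 2-D tangent-plane
chart at its center plus a normalized penetration-depth profile (0 at the
intact surface, ``depth_fraction`` at the deepest point). Because the
profile lives in the chart, transporting the chart to a new surface
location relocates the defect with exactly preserved projected footprint
area and per-node penetration fractions; absolute depths then follow the
local tissue thickness at the new site.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshes import SurfaceMesh, VolumeMesh

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# footprint polygons
# --------------------------------------------------------------------------
def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (n, 2) vertices."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_is_simple(poly: np.ndarray) -> bool:
    """Check for self-intersection (O(n^2) segment test; footprints are small)."""
    n = len(poly)
    segs = np.stack([poly, np.roll(poly, -1, axis=0)], axis=1)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    for i in range(n):
        for j in range(i + 1, n):
            if abs(i - j) in (0, 1) or (i == 0 and j == n - 1):
                continue
            p1, p2 = segs[i]
            p3, p4 = segs[j]
            d1, d2 = cross(p3, p4, p1), cross(p3, p4, p2)
            d3, d4 = cross(p1, p2, p3), cross(p1, p2, p4)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return False
    return True


def points_in_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd rule point-in-polygon test."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    x1, y1 = poly[:, 0], poly[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for a1, b1, a2, b2 in zip(x1, y1, x2, y2):
        straddles = (b1 > y) != (b2 > y)
        if not straddles.any():
            continue  # horizontal edge or fully above/below
        with np.errstate(divide="ignore", invalid="ignore"):
            xc = (a2 - a1) * (y - b1) / (b2 - b1) + a1
        inside ^= straddles & (x < xc)
    return inside


def signed_distance_to_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance to the polygon boundary, positive inside, negative outside."""
    p1 = poly
    p2 = np.roll(poly, -1, axis=0)
    d = p2 - p1  # (m, 2)
    seg_len2 = np.einsum("mj,mj->m", d, d)
    w = pts[:, None, :] - p1[None, :, :]  # (n, m, 2)
    t = np.clip(np.einsum("nmj,mj->nm", w, d) / seg_len2, 0.0, 1.0)
    proj = p1[None] + t[..., None] * d[None]
    dist = np.linalg.norm(pts[:, None, :] - proj, axis=-1).min(axis=1)
    sign = np.where(points_in_polygon(pts, poly), 1.0, -1.0)
    return sign * dist


def _smoothstep(x: np.ndarray) -> np.ndarray:
    s = np.clip(x, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass
class DefectSpec:
    """Footprint polygon in the local chart (mm, relative to ``center``),
    maximum normalized penetration depth, and chart center on the surface."""

    footprint: np.ndarray
    depth_fraction: float
    center: np.ndarray
    label: str = "defect"
    rim_smoothing_mm: float = 0.1
    # wall-ramp width; resolved at carve time (depth / 3 slope cap) so the
    # carved wall keeps hex quality, then transported verbatim on relocation
    wall_ramp_mm: float | None = None

    def __post_init__(self):
        self.footprint = np.asarray(self.footprint, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if not 0 < self.depth_fraction <= 1:
            raise ValueError("depth_fraction must lie in (0, 1]")
        if not polygon_is_simple(self.footprint):
            raise ValueError("footprint polygon is self-intersecting")
        if polygon_area(self.footprint) <= 0:
            raise ValueError("footprint area must be positive")

    @property
    def area_mm2(self) -> float:
        return polygon_area(self.footprint)

    @property
    def full_thickness(self) -> bool:
        return self.depth_fraction >= 1.0

    def footprint_world(self) -> np.ndarray:
        return self.footprint + self.center[None, :]

    def penetration_profile(self, xy: np.ndarray) -> np.ndarray:
        """Normalized penetration fraction at plan coordinates (n, 2).

        ``depth_fraction`` over the footprint interior, blending smoothly
        to zero across the wall-ramp band inside the rim (the smoothed
        defect wall).
        """
        w = self.wall_ramp_mm if self.wall_ramp_mm is not None else self.rim_smoothing_mm
        d = signed_distance_to_polygon(xy - self.center[None, :], self.footprint)
        return self.depth_fraction * _smoothstep(d / max(w, 1e-12))


@dataclass
class DefectGeometry:
    """A carved realization of a :class:`DefectSpec` on a compartment."""

    mesh: VolumeMesh
    spec: DefectSpec
    inner_wall_faces: np.ndarray
    rim_nodes: np.ndarray
    node_penetration: np.ndarray  # per defect-surface node fraction
    defect_surface_nodes: np.ndarray
    projected_area_mm2: float
    removed_volume_mm3: float = 0.0

    def __post_init__(self):
        bset = {tuple(p) for p in self.mesh.boundary_faces().tolist()}
        for p in np.asarray(self.inner_wall_faces).reshape(-1, 2).tolist():
            if tuple(p) not in bset:
                raise ValueError(f"inner-wall face {p} is not a boundary face")


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------
def normalized_penetration(node_xyz, compartment) -> np.ndarray:
    """Penetration below the intact surface normalized by local thickness.

    0 on the intact articular surface, 1 at the bone interface; values are
    clamped to [0, 1] (clamping is logged).
    """
    p = np.atleast_2d(np.asarray(node_xyz, dtype=float))
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    zt = compartment.z_top_at(x, y)
    t = compartment.thickness_at(x, y)
    raw = (zt - z) / t
    if np.any(raw < -1e-6) or np.any(raw > 1 + 1e-6):
        raise ValueError("node lies outside the cartilage slab")
    clamped = np.clip(raw, 0.0, 1.0)
    n_cl = int(np.sum((raw < 0) | (raw > 1)))
    if n_cl:
        log.info("normalized_penetration: clamped %d of %d values", n_cl, len(raw))
    return clamped if np.ndim(node_xyz) > 1 else float(clamped[0])


def carve_defect(compartment, spec: DefectSpec) -> DefectGeometry:
    """Carve ``spec`` into the compartment's layered cartilage mesh.

    Material under the footprint is removed down to ``depth_fraction``
    times the local thickness by recessing the articular surface and
    re-grading the element layers of each affected node column; the mesh
    stays conformal at the rim by construction.
    """
    world = spec.footprint_world()
    ext = compartment.plan_bounds()
    if (world[:, 0].min() < ext[0][0] or world[:, 0].max() > ext[0][1]
            or world[:, 1].min() < ext[1][0] or world[:, 1].max() > ext[1][1]):
        raise ValueError(f"footprint '{spec.label}' extends off the surface patch")

    if spec.wall_ramp_mm is None:
        # cap the carved-wall slope near 3 so rim hexes keep positive quality
        t_c = float(np.atleast_1d(
            compartment.thickness_at(spec.center[0], spec.center[1]))[0])
        spec = replace(spec, wall_ramp_mm=max(
            spec.rim_smoothing_mm, spec.depth_fraction * t_c / 3.0))

    mesh = compartment.cartilage.copy()
    nx, ny, nz = mesh.meta["structured_dims"]
    npl = (nx + 1) * (ny + 1)
    plan = mesh.points[:npl, :2]
    # antialiased column sampling: average the profile over each column's
    # tributary cell so the carved mesh volume tracks the continuum integral
    hx = (ext[0][1] - ext[0][0]) / nx
    hy = (ext[1][1] - ext[1][0]) / ny
    pen = np.zeros(npl)
    offs = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])
    for ox in offs * hx:
        for oy in offs * hy:
            pen += spec.penetration_profile(plan + np.array([ox, oy]))
    pen /= 9.0
    zt = compartment.z_top_at(plan[:, 0], plan[:, 1])
    th = compartment.thickness_at(plan[:, 0], plan[:, 1])
    z_bot = zt - th
    fractions = mesh.meta.get("layer_fractions", np.linspace(0.0, 1.0, nz + 1))
    for k in range(nz + 1):
        sel = slice(k * npl, (k + 1) * npl)
        mesh.points[sel, 2] = z_bot + fractions[k] * th * (1.0 - pen)

    vol_intact = compartment.cartilage.cell_volumes().sum()
    removed = vol_intact - mesh.cell_volumes().sum()

    q = mesh.min_scaled_jacobian()
    if q <= 0.1:
        raise RuntimeError(
            f"remeshing failure for footprint '{spec.label}': "
            f"min scaled Jacobian {q:.3f} <= 0.1"
        )

    surf_nodes = mesh.node_sets["articular_surface"]
    pen_surf = pen[surf_nodes % npl]
    touched = pen_surf > 1e-12
    defect_nodes = surf_nodes[touched]

    # inner-wall faces: articular-surface faces with any recessed node
    top_faces = mesh.face_sets["articular_surface"]
    fn = mesh.face_nodes(top_faces)
    face_touched = np.any(np.isin(fn, defect_nodes), axis=1)
    inner_wall = top_faces[face_touched]
    mesh.face_sets["defect_inner_wall"] = inner_wall

    # rim nodes: untouched surface nodes belonging to an inner-wall face
    rim = np.setdiff1d(np.unique(fn[face_touched]), defect_nodes)
    mesh.node_sets["defect_rim"] = rim
    mesh.node_sets["defect_surface"] = defect_nodes

    pen_field = np.zeros(mesh.n_points)
    pen_field[surf_nodes] = pen_surf
    mesh.point_data["normalized_penetration"] = pen_field

    geo = DefectGeometry(
        mesh=mesh, spec=spec, inner_wall_faces=inner_wall, rim_nodes=rim,
        node_penetration=pen_surf[touched], defect_surface_nodes=defect_nodes,
        projected_area_mm2=spec.area_mm2, removed_volume_mm3=float(removed),
    )
    # rim nodes must sit on the intact surface
    rp = mesh.points[rim]
    dz = np.abs(rp[:, 2] - compartment.z_top_at(rp[:, 0], rp[:, 1]))
    if len(rim) and dz.max() > 1e-6:
        raise RuntimeError("rim nodes left the intact surface")
    # recomputed penetration sanity: deepest node within 2 % of the spec
    recomputed = normalized_penetration(mesh.points[defect_nodes], compartment)
    if abs(np.max(recomputed) - spec.depth_fraction) > 0.02 * spec.depth_fraction:
        if np.max(pen_surf) < 0.999 * spec.depth_fraction:
            log.warning(
                "carve_defect '%s': mesh too coarse to sample the full-depth "
                "plateau (max recomputed penetration %.4f vs requested %.4f)",
                spec.label, float(np.max(recomputed)), spec.depth_fraction,
            )
        else:
            raise RuntimeError(
                f"carved penetration {np.max(recomputed):.4f} deviates from "
                f"requested {spec.depth_fraction:.4f} by more than 2 %"
            )
    return geo


def fill_defect_surface(damaged: SurfaceMesh, rim_nodes: np.ndarray) -> SurfaceMesh:
    """Reconstruct the intact surface over a defect by biharmonic hole fill.

    Works on structured heightfield surfaces (``grid_shape`` set): the
    height of every vertex strictly inside the rim loop is replaced by the
    solution of the discrete biharmonic equation clamped to the two rings
    of surrounding intact vertices, which interpolates both rim positions
    and rim slopes. Vertices outside the rim are untouched; with an empty
    hole the surface is returned unchanged.
    """
    if damaged.grid_shape is None:
        raise ValueError("fill_defect_surface requires a structured heightfield surface")
    rim_nodes = np.asarray(rim_nodes, dtype=int)
    pts = damaged.points.copy()
    gx, gy = damaged.grid_shape
    if len(rim_nodes) == 0:
        return SurfaceMesh(pts, damaged.faces.copy(), dict(damaged.point_data), damaged.grid_shape)
    if len(rim_nodes) < 3:
        raise ValueError("rim node set does not form a closed loop")

    rim_xy = pts[rim_nodes][:, :2]
    c = rim_xy.mean(axis=0)
    order = np.argsort(np.arctan2(rim_xy[:, 1] - c[1], rim_xy[:, 0] - c[0]))
    loop = rim_xy[order]
    if polygon_area(loop) <= 0:
        raise ValueError("rim node set does not form a closed loop")
    hole = points_in_polygon(pts[:, :2], loop)
    hole[rim_nodes] = False
    if not hole.any():
        return SurfaceMesh(pts, damaged.faces.copy(), dict(damaged.point_data), damaged.grid_shape)

    # 5-point Laplacian on the vertex grid (uniform spacing assumed per axis)
    idx = np.arange(gx * gy).reshape(gx, gy)
    hx = abs(pts[idx[1, 0], 0] - pts[idx[0, 0], 0]) or 1.0
    hy = abs(pts[idx[0, 1], 1] - pts[idx[0, 0], 1]) or 1.0
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i), cols.append(j), vals.append(v)

    for i in range(gx):
        for j in range(gy):
            me = idx[i, j]
            if i in (0, gx - 1) or j in (0, gy - 1):
                add(me, me, 1.0)  # boundary rows act as identity (clamped)
                continue
            add(me, me, -2.0 / hx**2 - 2.0 / hy**2)
            add(me, idx[i - 1, j], 1.0 / hx**2)
            add(me, idx[i + 1, j], 1.0 / hx**2)
            add(me, idx[i, j - 1], 1.0 / hy**2)
            add(me, idx[i, j + 1], 1.0 / hy**2)
    L = sp.csr_matrix((vals, (rows, cols)), shape=(gx * gy, gx * gy))
    B = (L @ L).tolil()
    known = ~hole
    z = pts[:, 2].copy()
    A = B[np.ix_(hole.nonzero()[0], hole.nonzero()[0])].tocsr()
    rhs = -B[np.ix_(hole.nonzero()[0], known.nonzero()[0])] @ z[known]
    z[hole] = spla.spsolve(A, np.asarray(rhs).ravel())
    pts[:, 2] = z
    return SurfaceMesh(pts, damaged.faces.copy(), dict(damaged.point_data), damaged.grid_shape)


def relocate_defect(compartment, geometry: DefectGeometry, target_center) -> tuple[DefectSpec, DefectGeometry]:
    """Move a carved defect to ``target_center`` on the same compartment.

    The footprint polygon and the normalized penetration profile are
    transported unchanged in the tangent-plane chart; node coordinates are
    rebuilt from the local surface height and thickness at the new
    location, so each node keeps its stored penetration fraction exactly
    while its absolute depth follows the local thickness.
    """
    target_center = np.asarray(target_center, dtype=float)
    new_spec = DefectSpec(
        footprint=geometry.spec.footprint.copy(),
        depth_fraction=geometry.spec.depth_fraction,
        center=target_center,
        label=geometry.spec.label,
        rim_smoothing_mm=geometry.spec.rim_smoothing_mm,
        wall_ramp_mm=geometry.spec.wall_ramp_mm,
    )
    new_geo = carve_defect(compartment, new_spec)
    return new_spec, new_geo


def defect_drainage_bcs(geometry: DefectGeometry):
    """Free-draining (p = 0) and sealed (no-flux) boundary face sets.

    Fluid may leave the tissue only through the inner defect surfaces;
    every other exterior face is sealed. The two sets are disjoint and
    jointly cover the boundary.
    """
    mesh = geometry.mesh
    all_faces = mesh.boundary_faces()
    drained = np.asarray(geometry.inner_wall_faces, dtype=int).reshape(-1, 2)
    dset = {tuple(p) for p in drained.tolist()}
    aset = {tuple(p) for p in all_faces.tolist()}
    if not dset <= aset:
        raise ValueError("drained face not on the boundary")
    sealed = np.array(sorted(aset - dset), dtype=int).reshape(-1, 2)
    return drained, sealed
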