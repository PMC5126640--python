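"""Mesh containers and geometry kernels.

Units are mm throughout. Hexahedra follow the VTK ``hexahedron`` node
ordering (nodes 0-3 on the bottom face, 4-7 on the top face); face sets are
stored as ``(element, local_face)`` pairs with the local-face convention of
:data:`HEX_FACES`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# local faces of a hex8: (name, node indices, outward for a right-handed cell)
HEX_FACES = np.array(
    [
        [0, 3, 2, 1],  # -z (bottom)
        [4, 5, 6, 7],  # +z (top)
        [0, 1, 5, 4],  # -y
        [1, 2, 6, 5],  # +x
        [2, 3, 7, 6],  # +y
        [3, 0, 4, 7],  # -x
    ],
    dtype=int,
)

# 2x2x2 Gauss quadrature on [-1,1]^3
_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = np.array(
    [[sx * _G, sy * _G, sz * _G] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)
GAUSS_WEIGHTS = np.ones(8)


def hex_shape(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for hex8, shape (..., 8)."""
    xi = np.asarray(xi, dtype=float)
    x, y, z = xi[..., 0], xi[..., 1], xi[..., 2]
    sx = np.array([-1, 1, 1, -1, -1, 1, 1, -1])
    sy = np.array([-1, -1, 1, 1, -1, -1, 1, 1])
    sz = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
    return 0.125 * (1 + x[..., None] * sx) * (1 + y[..., None] * sy) * (1 + z[..., None] * sz)


def hex_shape_grad(xi: np.ndarray) -> np.ndarray:
    """Parent-space gradients dN_a/dxi, shape (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    x, y, z = xi[..., 0], xi[..., 1], xi[..., 2]
    sx = np.array([-1, 1, 1, -1, -1, 1, 1, -1])
    sy = np.array([-1, -1, 1, 1, -1, -1, 1, 1])
    sz = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
    gx = 0.125 * sx * (1 + y[..., None] * sy) * (1 + z[..., None] * sz)
    gy = 0.125 * sy * (1 + x[..., None] * sx) * (1 + z[..., None] * sz)
    gz = 0.125 * sz * (1 + x[..., None] * sx) * (1 + y[..., None] * sy)
    return np.stack([gx, gy, gz], axis=-1)


@dataclass
class SurfaceMesh:
    """Quad- or tri-faced surface with optional structured-grid layout.

    ``grid_shape`` is set when the surface is a structured heightfield
    (nx+1, ny+1 vertices); several reconstruction algorithms require it.
    """

    points: np.ndarray
    faces: np.ndarray
    point_data: dict = field(default_factory=dict)
    grid_shape: tuple | None = None

    @property
    def n_points(self) -> int:
        return len(self.points)

    def face_normals(self) -> np.ndarray:
        p = self.points
        f = self.faces
        if f.shape[1] == 3:
            n = np.cross(p[f[:, 1]] - p[f[:, 0]], p[f[:, 2]] - p[f[:, 0]])
        else:
            n = np.cross(p[f[:, 2]] - p[f[:, 0]], p[f[:, 3]] - p[f[:, 1]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def vertex_normals(self) -> np.ndarray:
        fn = self.face_normals()
        vn = np.zeros_like(self.points)
        for k in range(self.faces.shape[1]):
            np.add.at(vn, self.faces[:, k], fn)
        return vn / np.linalg.norm(vn, axis=1, keepdims=True)


@dataclass
class VolumeMesh:
    """Hex8-dominant volume mesh with named node/face sets.

    ``face_sets`` maps a name to an (k, 2) int array of (element, local
    face) pairs.  ``material_id`` is per element.
    """

    points: np.ndarray
    cells: np.ndarray
    cell_type: str = "hex8"
    node_sets: dict = field(default_factory=dict)
    face_sets: dict = field(default_factory=dict)
    material_id: np.ndarray | None = None
    point_data: dict = field(default_factory=dict)
    cell_data: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.cells = np.asarray(self.cells, dtype=int)
        if self.material_id is None:
            self.material_id = np.zeros(len(self.cells), dtype=int)
        # dict keys are unique within each family by construction; nothing
        # further to check beyond basic shape sanity
        if self.cells.ndim != 2:
            raise ValueError("cells must be a 2-D connectivity array")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def copy(self) -> "VolumeMesh":
        return VolumeMesh(
            points=self.points.copy(),
            cells=self.cells.copy(),
            cell_type=self.cell_type,
            node_sets={k: np.array(v) for k, v in self.node_sets.items()},
            face_sets={k: np.array(v) for k, v in self.face_sets.items()},
            material_id=self.material_id.copy(),
            point_data={k: np.array(v) for k, v in self.point_data.items()},
            cell_data={k: np.array(v) for k, v in self.cell_data.items()},
            meta=dict(self.meta),
        )

    # ---- geometry ----------------------------------------------------
    def gauss_jacobians(self, displaced: np.ndarray | None = None):
        """Jacobian matrices dX/dxi at the 8 Gauss points of every hex.

        Returns (J, detJ) with shapes (n_cells, 8, 3, 3) and (n_cells, 8).
        """
        pts = self.points if displaced is None else self.points + displaced
        xe = pts[self.cells]  # (ne, 8, 3)
        dN = hex_shape_grad(GAUSS_POINTS)  # (8, 8, 3)
        J = np.einsum("qam,ean->eqnm", dN, xe)  # dX_n/dxi_m
        detJ = np.linalg.det(J)
        return J, detJ

    def cell_volumes(self) -> np.ndarray:
        _, detJ = self.gauss_jacobians()
        return detJ @ GAUSS_WEIGHTS

    def min_scaled_jacobian(self) -> float:
        """Minimum over cells/Gauss points of detJ scaled by edge lengths."""
        J, detJ = self.gauss_jacobians()
        # columns J[:, m] = dX/dxi_m are the local edge vectors
        norms = np.linalg.norm(J, axis=-2)
        scale = np.prod(norms, axis=-1)
        return float(np.min(detJ / scale))

    def cell_centroids(self) -> np.ndarray:
        return self.points[self.cells].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """All exterior faces as (element, local_face) pairs."""
        faces = self.cells[:, HEX_FACES]  # (ne, 6, 4)
        key = np.sort(faces.reshape(-1, 4), axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        ext = counts[inv] == 1
        e, lf = np.divmod(np.nonzero(ext)[0], 6)
        return np.column_stack([e, lf])

    def face_nodes(self, face_pairs: np.ndarray) -> np.ndarray:
        """Global node ids (k, 4) for (element, local_face) pairs."""
        face_pairs = np.asarray(face_pairs, dtype=int).reshape(-1, 2)
        return self.cells[face_pairs[:, 0][:, None], HEX_FACES[face_pairs[:, 1]]]

    def face_areas_normals(self, face_pairs: np.ndarray, displaced=None):
        """Area and outward unit normal per quad face (flat-quad estimate)."""
        pts = self.points if displaced is None else self.points + displaced
        quads = pts[self.face_nodes(face_pairs)]
        d1 = quads[:, 2] - quads[:, 0]
        d2 = quads[:, 3] - quads[:, 1]
        cr = np.cross(d1, d2)
        area = 0.5 * np.linalg.norm(cr, axis=1)
        nrm = cr / np.linalg.norm(cr, axis=1, keepdims=True)
        return area, nrm

    def extract_surface(self, face_pairs: np.ndarray) -> SurfaceMesh:
        fn = self.face_nodes(face_pairs)
        uniq, inv = np.unique(fn, return_inverse=True)
        return SurfaceMesh(points=self.points[uniq], faces=inv.reshape(fn.shape))

    # ---- point location ----------------------------------------------
    def locate_points(self, pts: np.ndarray, tol: float = 1e-8,
                      outside_tol: float = 0.05):
        """Find the containing element and parent coordinates of each point.

        Returns (elem_ids, xi); elem_id is -1 for points outside the mesh.
        Trilinear inversion by Newton iteration over candidate elements
        selected by padded bounding boxes. Points within ``outside_tol``
        (parent coordinates) of the nearest element are clipped onto it,
        which absorbs the faceting gap between a curved analytic surface
        and its trilinear discretization.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        xe_all = self.points[self.cells]
        lo = xe_all.min(axis=1)
        hi = xe_all.max(axis=1)
        pad = 1e-9 + 1e-6 * (hi - lo).max()
        elem = np.full(len(pts), -1, dtype=int)
        xi_out = np.zeros((len(pts), 3))
        for ip, x in enumerate(pts):
            cand = np.nonzero(
                np.all(x >= lo - pad, axis=1) & np.all(x <= hi + pad, axis=1)
            )[0]
            best = (-1, None, np.inf)
            for e in cand:
                xe = xe_all[e]
                xi = np.zeros(3)
                for _ in range(30):
                    N = hex_shape(xi)
                    r = N @ xe - x
                    if np.linalg.norm(r) < tol:
                        break
                    dN = hex_shape_grad(xi)
                    J = dN.T @ xe  # d x_n / d xi_m -> (3,3) rows m? careful
                    # J[m, n] = sum_a dN_a/dxi_m * xe[a, n]; solve J^T dxi = r
                    xi = xi - np.linalg.solve(J.T, r)
                over = np.max(np.abs(xi)) - 1.0
                if over < 1e-6:
                    elem[ip] = e
                    xi_out[ip] = np.clip(xi, -1, 1)
                    best = (e, xi, 0.0)
                    break
                if over < best[2]:
                    best = (e, xi, over)
            else:
                # accept the nearest candidate if barely outside (face hits,
                # curvature faceting)
                if best[0] >= 0 and best[2] < outside_tol:
                    elem[ip] = best[0]
                    xi_out[ip] = np.clip(best[1], -1, 1)
        return elem, xi_out

    def interpolate(self, nodal_field: np.ndarray, elem: np.ndarray, xi: np.ndarray):
        """Evaluate a nodal field at located points (elem, xi)."""
        N = hex_shape(xi)  # (np, 8)
        vals = np.einsum("pa,pa...->p...", N, nodal_field[self.cells[elem]])
        return vals


def structured_hex_grid(x: np.ndarray, y: np.ndarray, z_of_xy_k) -> VolumeMesh:
    """Build a layered structured hex mesh over the tensor grid (x, y).

    ``z_of_xy_k(X, Y, k)`` returns nodal z for layer-interface k (0 at the
    bone interface, nz at the articular surface), X/Y being 2-D meshgrids.
    Standard node/face sets are attached: ``articular_surface``,
    ``bone_interface`` and the four side walls.
    """
    nx, ny = len(x) - 1, len(y) - 1
    X, Y = np.meshgrid(x, y, indexing="ij")
    nz = z_of_xy_k.n_layers
    npl = (nx + 1) * (ny + 1)
    pts = np.empty(((nz + 1) * npl, 3))
    for k in range(nz + 1):
        Z = z_of_xy_k(X, Y, k)
        pts[k * npl : (k + 1) * npl, 0] = X.ravel()
        pts[k * npl : (k + 1) * npl, 1] = Y.ravel()
        pts[k * npl : (k + 1) * npl, 2] = Z.ravel()

    def nid(i, j, k):
        return k * npl + i * (ny + 1) + j

    I, Jj, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    I, Jj, K = I.ravel(), Jj.ravel(), K.ravel()
    cells = np.column_stack(
        [
            nid(I, Jj, K),
            nid(I + 1, Jj, K),
            nid(I + 1, Jj + 1, K),
            nid(I, Jj + 1, K),
            nid(I, Jj, K + 1),
            nid(I + 1, Jj, K + 1),
            nid(I + 1, Jj + 1, K + 1),
            nid(I, Jj + 1, K + 1),
        ]
    )
    mesh = VolumeMesh(points=pts, cells=cells)
    ii, jj = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1), indexing="ij")
    mesh.node_sets["bone_interface"] = nid(ii, jj, 0).ravel()
    mesh.node_sets["articular_surface"] = nid(ii, jj, nz).ravel()

    def elem_id(i, j, k):
        return (i * ny + j) * nz + k

    Ie, Je = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    top = np.column_stack([elem_id(Ie, Je, nz - 1).ravel(), np.full(nx * ny, 1)])
    bot = np.column_stack([elem_id(Ie, Je, 0).ravel(), np.zeros(nx * ny, int)])
    mesh.face_sets["articular_surface"] = top
    mesh.face_sets["bone_interface"] = bot
    Ke = np.arange(nz)
    for name, (iis, jjs, lf) in {
        "side_xmin": (np.zeros(ny, int), np.arange(ny), 5),
        "side_xmax": (np.full(ny, nx - 1), np.arange(ny), 3),
        "side_ymin": (np.arange(nx), np.zeros(nx, int), 2),
        "side_ymax": (np.arange(nx), np.full(nx, ny - 1), 4),
    }.items():
        ee = elem_id(iis[:, None], jjs[:, None], Ke[None, :]).ravel()
        mesh.face_sets[name] = np.column_stack([ee, np.full(len(ee), lf)])
    mesh.meta["structured_dims"] = (nx, ny, nz)
    return mesh
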