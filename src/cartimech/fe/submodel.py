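"""Submodeling: re-solve a refined local region with boundary conditions
interpolated from a coarser global solution.

The global model's displacement and pressure histories are sampled with
the global element shape functions at the submodel's cut-boundary nodes;
the submodel interior is unconstrained and the rigid indenter follows the
axial position history solved globally (displacement control).
"""
from __future__ import annotations

import numpy as np

from ..meshes import VolumeMesh


def submodel_bcs(global_mesh: VolumeMesh, states, boundary_points: np.ndarray):
    """Interpolated (u, p) time series on submodel boundary points.

    Returns (u_series (n_t, nb, 3), p_series (n_t, nb)). Linear elements
    reproduce linear global fields exactly. A boundary point outside the
    global mesh is rejected with its index.
    """
    pts = np.atleast_2d(np.asarray(boundary_points, dtype=float))
    elem, xi = global_mesh.locate_points(pts)
    if np.any(elem < 0):
        bad = np.nonzero(elem < 0)[0]
        raise ValueError(f"submodel boundary node(s) {bad[:10].tolist()} outside the global mesh")
    u_series = np.stack([global_mesh.interpolate(s.u, elem, xi) for s in states])
    p_series = np.stack([global_mesh.interpolate(s.p, elem, xi) for s in states])
    return u_series, p_series


def boundary_node_set(mesh: VolumeMesh, exclude_sets=("articular_surface", "defect_inner_wall")):
    """Nodes on the submodel's cut boundary: all boundary-face nodes except
    those belonging only to the excluded (free/contact) surfaces."""
    all_faces = mesh.boundary_faces()
    excl = {tuple(p) for name in exclude_sets if name in mesh.face_sets
            for p in np.asarray(mesh.face_sets[name]).reshape(-1, 2).tolist()}
    cut = np.array([p for p in all_faces.tolist() if tuple(p) not in excl], dtype=int)
    cut_nodes = np.unique(mesh.face_nodes(cut))
    free_nodes = (
        np.unique(mesh.face_nodes(np.array(sorted(excl), dtype=int)))
        if excl else np.array([], dtype=int)
    )
    # nodes shared between cut and free surfaces stay constrained (cut wins)
    return cut_nodes


def build_submodel(compartment, bounds, element_size_mm, defect_spec=None):
    """Refined structured cartilage mesh over a plan-rectangle sub-region.

    ``bounds`` is ((x0, x1), (y0, y1)) in plan coordinates. The submodel
    reuses the compartment's analytic surface/thickness fields, so its
    geometry is exact rather than interpolated from the coarse mesh. If a
    defect spec is given the submodel is carved with it.
    """
    from dataclasses import replace

    from ..defects import carve_defect
    from ..meshes import structured_hex_grid
    from ..synthetic import Compartment, _LayerField, layer_fractions

    (x0, x1), (y0, y1) = bounds
    nx = max(2, round((x1 - x0) / element_size_mm))
    ny = max(2, round((y1 - y0) / element_size_mm))
    x = np.linspace(x0, x1, nx + 1)
    y = np.linspace(y0, y1, ny + 1)
    sub = Compartment(
        spec=compartment.spec, cartilage=None, intact_surface=None,
        thickness=None, split_lines=None, indenter=compartment.indenter,
        bounds_override=((x0, x1), (y0, y1)),
    )
    tmid = float(np.mean(compartment.thickness_at(
        *np.meshgrid(x, y, indexing="ij"))))
    fractions = layer_fractions(tmid, element_size_mm,
                                min_layers=compartment.spec.min_layers)
    mesh = structured_hex_grid(x, y, _LayerField(sub, fractions))
    mesh.meta["layer_fractions"] = fractions
    sub.cartilage = mesh
    geometry = None
    if defect_spec is not None:
        geometry = carve_defect(sub, defect_spec)
        sub.cartilage = geometry.mesh
    return sub, geometry


def solve_submodel(sub_compartment, material, global_mesh, global_states, protocol,
                   config, geometry=None, contact_penalty=None):
    """Solve the refined submodel driven by a global solution.

    Cut-boundary u and p follow the global interpolation; the articular
    surface keeps penalty contact against the same indenter at the
    globally solved axial positions; inner defect walls (if carved) are
    free-draining.
    """
    from .materials import PoroelasticCartilage
    from .model import ContactSpec, DirichletBC, FEModel, PressureBC, SolverConfig, solve_protocol
    from ..constitutive import build_architecture

    mesh = sub_compartment.cartilage
    cut_nodes = boundary_node_set(mesh)
    u_series, p_series = submodel_bcs(global_mesh, global_states, mesh.points[cut_nodes])
    times = np.asarray(protocol.times_s)

    def u_value(t):
        k = int(np.argmin(np.abs(times - t)))
        return u_series[k]

    def p_value(t):
        k = int(np.argmin(np.abs(times - t)))
        return p_series[k]

    arch = build_architecture(
        mesh, sub_compartment.normal_at, sub_compartment.split_line_at,
        sub_compartment.thickness_at, sub_compartment.z_top_at, material,
    )
    mat = PoroelasticCartilage(params=material, architecture=arch)

    dz_hist = np.array([s.indenter_dz_mm for s in global_states])

    def dz_value(t):
        k = int(np.argmin(np.abs(times - t)))
        return float(dz_hist[k])

    contact = ContactSpec(
        center0=sub_compartment.indenter.center,
        radius_mm=sub_compartment.indenter.radius_mm,
        faces=mesh.face_sets["articular_surface"],
        mode="displacement",
        axial_position=dz_value,
    )
    pressure_bcs = [PressureBC(cut_nodes, value=p_value)]
    if geometry is not None:
        wall_nodes = np.unique(mesh.face_nodes(geometry.inner_wall_faces))
        pressure_bcs.append(PressureBC(np.setdiff1d(wall_nodes, cut_nodes), value=0.0))
    model = FEModel(
        mesh=mesh,
        materials={0: mat},
        dirichlet=[DirichletBC(cut_nodes, (0, 1, 2), value=u_value)],
        pressure_bcs=pressure_bcs,
        contact=contact,
    )
    return solve_protocol(model, protocol, config)
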