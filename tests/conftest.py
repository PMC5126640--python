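"""Shared fixtures.

Heavy solver runs (consolidation column, toy defect scenario) are
session-scoped so several test modules can interrogate one solution.
"""
from __future__ import annotations

import numpy as np
import pytest

from cartimech.constitutive import FRPEParams, build_architecture
from cartimech.fe.materials import PoroelasticCartilage
from cartimech.fe.model import (
    ContactSpec,
    DirichletBC,
    FaceLoad,
    FEModel,
    PressureBC,
    SolverConfig,
    solve_protocol,
)
from cartimech.meshes import structured_hex_grid
from cartimech.synthetic import (
    CompartmentSpec,
    LoadProtocol,
    ThicknessProfile,
    make_compartment,
    make_defect,
)
from cartimech.defects import carve_defect


# ---------------------------------------------------------------------------
# geometry fixtures
# ---------------------------------------------------------------------------
@pytest.fixture(scope="session")
def small_compartment():
    """12 x 12 mm plateau at 1 mm elements: the smallest compartment that
    still resolves the default defect and a 1 mm rim ROI."""
    return make_compartment(CompartmentSpec(plateau_extent_mm=(12.0, 12.0)))


@pytest.fixture(scope="session")
def default_params():
    return FRPEParams()


def column_mesh(n_el=20, height=4.0, area=1.0):
    side = float(np.sqrt(area))

    class Layers:
        n_layers = n_el

        def __call__(self, X, Y, k):
            return np.full_like(np.asarray(X, dtype=float), height * k / n_el)

    return structured_hex_grid(np.array([0.0, side]), np.array([0.0, side]), Layers())


def column_architecture(mesh, direction=(1.0, 0.0, 0.0)):
    ng = mesh.n_cells * 8
    d = np.tile(np.asarray(direction, dtype=float), (ng, 1))
    from cartimech.constitutive import FibrilArchitecture

    return FibrilArchitecture(
        primary_direction=d, normalized_depth=np.zeros(ng),
        split_line_direction=d,
    )


TERZAGHI = dict(E=0.31, nu=0.42, k=2e-3, H=4.0, q0=0.05, t_ramp=100.0)


@pytest.fixture(scope="session")
def terzaghi_solution():
    """Confined-compression ramp-hold solve on a 20-element column (the
    poroelastic oracle scenario), solved in small-strain mode."""
    E, nu = TERZAGHI["E"], TERZAGHI["nu"]
    G = E / (2 * (1 + nu))
    K = E / (3 * (1 - 2 * nu))
    H, q0, t_ramp = TERZAGHI["H"], TERZAGHI["q0"], TERZAGHI["t_ramp"]
    mesh = column_mesh(n_el=20, height=H)
    params = FRPEParams(
        matrix_shear_modulus_MPa=G, matrix_bulk_modulus_MPa=K,
        fibril_modulus_initial_MPa=0.0, fibril_modulus_strain_dependent_MPa=0.0,
        permeability_mm4_per_Ns=TERZAGHI["k"],
    )
    mat = PoroelasticCartilage(params, column_architecture(mesh))
    c = TERZAGHI["k"] * (K + 4 * G / 3)
    t_char = H**2 / c
    times = np.concatenate([
        np.linspace(0.0, t_ramp, 11),
        t_ramp + (2 * t_char - t_ramp) * np.linspace(0.0, 1.0, 60)[1:] ** 1.5,
    ])
    prot = LoadProtocol(
        times_s=times, stance_pct=np.linspace(0, 100, len(times)),
        axial_force_N=np.zeros(len(times)), flexion_deg=np.zeros(len(times)),
    )
    model = FEModel(
        mesh=mesh, materials={0: mat},
        dirichlet=[
            DirichletBC(np.arange(mesh.n_points), (0, 1), 0.0),
            DirichletBC(mesh.node_sets["bone_interface"], (2,), 0.0),
        ],
        pressure_bcs=[PressureBC(mesh.node_sets["articular_surface"], 0.0)],
        face_loads=[FaceLoad(mesh.face_sets["articular_surface"],
                             lambda t: q0 * min(t / t_ramp, 1.0))],
    )
    cfg = SolverConfig(kinematics="small")
    res = solve_protocol(model, prot, cfg)
    assert res.failure is None, res.failure
    return {"mesh": mesh, "result": res, "times": times, "G": G, "K": K, **TERZAGHI}


# ---------------------------------------------------------------------------
# toy defect scenario (intact + damaged ramp to peak load)
# ---------------------------------------------------------------------------
def ramp_protocol(f_peak, n_steps=6, t_end=0.09, s_end=15.0):
    s = np.linspace(0.0, 1.0, n_steps + 1)
    return LoadProtocol(
        times_s=s * t_end, stance_pct=s * s_end,
        axial_force_N=s * f_peak, flexion_deg=np.zeros(n_steps + 1),
    )


@pytest.fixture(scope="session")
def toy_defect_scenario(small_compartment, default_params):
    """Intact and damaged solves of the small compartment ramped to twice
    the nominal stance-peak contact force (~30 N), so the failure criteria
    that govern the defect rim are actually exercised."""
    from cartimech.pipeline import build_cartilage_model

    comp = small_compartment
    spec = make_defect(center=(0.0, 0.0), patch_extent_mm=comp.plan_bounds())
    geo = carve_defect(comp, spec)
    cfg = SolverConfig()
    prot = ramp_protocol(f_peak=30.0, n_steps=6)
    intact = solve_protocol(build_cartilage_model(comp, default_params), prot, cfg)
    damaged = solve_protocol(build_cartilage_model(comp, default_params, geo), prot, cfg)
    assert intact.failure is None and damaged.failure is None
    return {
        "compartment": comp, "geometry": geo, "protocol": prot,
        "intact": intact, "damaged": damaged,
    }


@pytest.fixture(scope="session")
def gradient_relocation():
    """Default defect carved at the thick end of a linear-gradient plateau
    (1.5 -> 3.5 mm) and relocated to the thin end at fixed normalized
    penetration (0.25 mm surface grid)."""
    from cartimech.defects import relocate_defect

    spec = CompartmentSpec(
        plateau_extent_mm=(16.0, 16.0),
        thickness_profile=ThicknessProfile(base_mm=2.5, gradient_mm_per_mm=(0.125, 0.0)),
        target_element_size_mm=0.25,
    )
    comp = make_compartment(spec)
    d = make_defect(center=(5.0, 0.0), patch_extent_mm=comp.plan_bounds())
    geo_a = carve_defect(comp, d)
    new_spec, geo_b = relocate_defect(comp, geo_a, np.array([-5.0, 0.0]))
    return {"compartment": comp, "spec_a": d, "geo_a": geo_a,
            "spec_b": new_spec, "geo_b": geo_b}
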