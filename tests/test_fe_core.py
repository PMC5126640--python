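import numpy as np
import pytest

from cartimech.benchmarks import terzaghi_history
from cartimech.constitutive import FRPEParams
from cartimech.fe.convergence import convergence_study
from cartimech.fe.materials import IsotropicElastic, PoroelasticCartilage
from cartimech.fe.model import (
    ContactSpec,
    DirichletBC,
    FaceLoad,
    FEModel,
    NonConvergenceError,
    PressureBC,
    SolverConfig,
    SpringSet,
    State,
    System,
    assemble,
    contact_traction,
    solve_protocol,
)
from cartimech.fe.strain import history_fields, log_strain_from_F, strain_measures
from cartimech.fe.submodel import submodel_bcs
from cartimech.synthetic import LoadProtocol

from conftest import column_architecture, column_mesh, ramp_protocol
from tests_support import flat_box_mesh


def elastic_column_model(mesh, E=1.0, nu=0.3):
    return FEModel(mesh=mesh, materials={0: IsotropicElastic(E_MPa=E, nu=nu)})


def short_protocol(n=3, t_end=1.0):
    s = np.linspace(0, 1, n)
    return LoadProtocol(times_s=s * t_end, stance_pct=s * 100,
                        axial_force_N=np.zeros(n), flexion_deg=np.zeros(n))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------
class TestAssemble:
    def test_zero_state_zero_loads_zero_residual(self):
        mesh = flat_box_mesh()
        model = elastic_column_model(mesh)
        K, R = assemble(model)
        assert np.allclose(R, 0.0)
        assert K.shape[0] == 3 * mesh.n_points

    def test_uniform_stretch_patch_state(self):
        # single hex under uniform stretch: internal nodal forces must be
        # the tractions of the analytic uniform stress state
        mesh = flat_box_mesh(nx=1, ny=1, nz=1, lx=1.0, ly=1.0, lz=1.0)
        E, nu = 1.0, 0.25
        model = elastic_column_model(mesh, E=E, nu=nu)
        cfg = SolverConfig(kinematics="small")
        sys_ = System(model, cfg)
        eps = 1e-3
        u = np.zeros((mesh.n_points, 3))
        u[:, 2] = eps * mesh.points[:, 2]  # uniaxial strain
        f = sys_.internal_force_elements(u[mesh.cells], np.zeros((1, 8))).reshape(8, 3)
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        sig_zz = (lam + 2 * mu) * eps
        top = mesh.points[mesh.cells[0], 2] > 0.5
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)
        assert np.allclose(f[top, 2], sig_zz / 4.0, rtol=1e-8)

    def test_spring_group_diagonal_matches_total(self):
        mesh = flat_box_mesh()
        nodes = mesh.node_sets["articular_surface"][:5]
        springs = SpringSet.from_total(nodes, 350.0, label="medial_anterior_horn")
        model = elastic_column_model(mesh)
        model.springs.append(springs)
        K, _ = assemble(model)
        diag = K.diagonal()
        base = assemble(elastic_column_model(mesh))[0].diagonal()
        added = diag - base
        # each displacement component of each spring node carries k_i
        assert np.isclose(added[3 * nodes].sum(), 350.0, atol=1e-10)
        assert springs.total_stiffness_N_per_mm == pytest.approx(350.0)

    def test_singular_system_names_rigid_body_modes(self):
        mesh = flat_box_mesh()
        model = elastic_column_model(mesh)  # no Dirichlet at all
        model.face_loads.append(FaceLoad(mesh.face_sets["articular_surface"], 0.1))
        prot = short_protocol()
        res = solve_protocol(model, prot, SolverConfig(kinematics="small"))
        assert res.failure is not None
        assert "rigid-body" in res.failure["message"]


# ---------------------------------------------------------------------------
# protocol solves
# ---------------------------------------------------------------------------
class TestSolveProtocol:
    def test_zero_force_protocol_stays_at_rest(self):
        mesh = column_mesh(n_el=4, height=2.0)
        params = FRPEParams()
        mat = PoroelasticCartilage(params, column_architecture(mesh))
        model = FEModel(
            mesh=mesh, materials={0: mat},
            dirichlet=[DirichletBC(mesh.node_sets["bone_interface"], (0, 1, 2), 0.0)],
        )
        res = solve_protocol(model, short_protocol(), SolverConfig())
        assert res.failure is None
        for s in res.states:
            assert np.allclose(s.u, 0.0, atol=1e-10)
            assert np.allclose(s.p, 0.0, atol=1e-10)

    def test_consolidation_matches_series_solution(self, terzaghi_solution):
        ts = terzaghi_solution
        mesh, res = ts["mesh"], ts["result"]
        H, q0 = ts["H"], ts["q0"]
        times = ts["times"]
        top = mesh.node_sets["articular_surface"]
        w_num = np.array([-s.u[top, 2].mean() for s in res.states])
        mid = np.nonzero(np.abs(mesh.points[:, 2] - H / 2) < 1e-9)[0]
        p_num = np.array([s.p[mid].mean() for s in res.states])
        p_an, w_an = terzaghi_history(
            [H / 2], times, H_mm=H, q0_MPa=q0, t_ramp_s=ts["t_ramp"],
            k_mm4_per_Ns=ts["k"], G_MPa=ts["G"], K_MPa=ts["K"],
        )
        hold = times > ts["t_ramp"]
        err_w = np.linalg.norm(w_num[hold] - w_an[hold]) / np.linalg.norm(w_an[hold])
        err_p = np.linalg.norm(p_num[hold] - p_an[hold, 0]) / np.linalg.norm(p_an[hold, 0])
        assert err_w <= 0.02
        assert err_p <= 0.02

    def test_long_hold_reaches_drained_settlement(self, terzaghi_solution):
        ts = terzaghi_solution
        Eoed = ts["K"] + 4 * ts["G"] / 3
        w_inf = ts["q0"] * ts["H"] / Eoed
        top = ts["mesh"].node_sets["articular_surface"]
        w_end = -ts["result"].states[-1].u[top, 2].mean()
        assert abs(w_end - w_inf) / w_inf < 0.01

    def test_instantaneous_response_stiffer_than_drained(self, terzaghi_solution):
        ts = terzaghi_solution
        top = ts["mesh"].node_sets["articular_surface"]
        w = np.array([-s.u[top, 2].mean() for s in ts["result"].states])
        k_ramp_end = int(np.searchsorted(ts["times"], ts["t_ramp"]))
        assert w[k_ramp_end] < w[-1]  # undrained settles less than drained

    def test_rate_independence_when_fully_drained(self):
        # drained conditions (p = 0 everywhere): same load level gives the
        # same state regardless of loading rate
        mesh = column_mesh(n_el=4, height=2.0)
        params = FRPEParams()  # fibrils on; still rate-independent
        mat = PoroelasticCartilage(params, column_architecture(mesh))

        def build():
            return FEModel(
                mesh=mesh, materials={0: mat},
                dirichlet=[
                    DirichletBC(np.arange(mesh.n_points), (0, 1), 0.0),
                    DirichletBC(mesh.node_sets["bone_interface"], (2,), 0.0),
                ],
                pressure_bcs=[PressureBC(np.arange(mesh.n_points), 0.0)],
                face_loads=[FaceLoad(mesh.face_sets["articular_surface"],
                                     lambda t: 0.02 * min(t, 1.0))],
            )

        cfg = SolverConfig()
        slow = solve_protocol(build(), short_protocol(n=9, t_end=1.0), cfg)
        fast = solve_protocol(build(), short_protocol(n=3, t_end=1.0), cfg)
        assert slow.failure is None and fast.failure is None
        assert np.allclose(slow.states[-1].u, fast.states[-1].u, atol=1e-8)

    def test_force_balance_and_contact_equilibrium(self, toy_defect_scenario):
        res = toy_defect_scenario["intact"]
        for s in res.states[1:]:
            applied = s.applied_force_N
            total = s.reactions.sum(axis=0) + s.contact_force_N
            # reactions + contact load balance to solver tolerance
            assert np.linalg.norm(total) <= 1e-5 * max(applied, 1.0)
            assert abs(-s.contact_force_N[2] - applied) <= 5e-3 * max(applied, 1.0)

    def test_translation_invariance_of_strains(self):
        # rigid-body shift of the whole scenario leaves strains unchanged
        def run(shift):
            mesh = column_mesh(n_el=3, height=1.5)
            mesh.points += np.array(shift)
            params = FRPEParams()
            mat = PoroelasticCartilage(params, column_architecture(mesh))
            model = FEModel(
                mesh=mesh, materials={0: mat},
                dirichlet=[
                    DirichletBC(np.arange(mesh.n_points), (0, 1), 0.0),
                    DirichletBC(mesh.node_sets["bone_interface"], (2,), 0.0),
                ],
                face_loads=[FaceLoad(mesh.face_sets["articular_surface"], 0.01)],
            )
            res = solve_protocol(model, short_protocol(), SolverConfig())
            assert res.failure is None
            return res.states[-1].strain

        a = run((0.0, 0.0, 0.0))
        b = run((13.0, -4.0, 2.0))
        assert np.allclose(a, b, atol=1e-10)


# ---------------------------------------------------------------------------
# contact
# ---------------------------------------------------------------------------
class TestContact:
    def test_open_gap_carries_no_force(self, small_compartment, default_params):
        from cartimech.pipeline import build_cartilage_model

        model = build_cartilage_model(small_compartment, default_params)
        u = np.zeros((model.mesh.n_points, 3))
        out = contact_traction(model, u, dz=+1.0)  # sphere lifted: gap open
        assert np.allclose(out["forces_N"], 0.0)
        assert not out["active"].any()

    def test_forces_are_normal_to_the_sphere(self, toy_defect_scenario):
        comp = toy_defect_scenario["compartment"]
        from cartimech.pipeline import build_cartilage_model

        s = toy_defect_scenario["intact"].states[-1]
        model = build_cartilage_model(comp, FRPEParams())
        out = contact_traction(model, s.u, s.indenter_dz_mm)
        f = out["forces_N"]
        active = out["active"]
        assert active.any()
        x = model.mesh.points[out["nodes"]] + s.u[out["nodes"]]
        c = comp.indenter.center + np.array([0, 0, s.indenter_dz_mm])
        nrm = (x - c) / np.linalg.norm(x - c, axis=1, keepdims=True)
        fmag = np.linalg.norm(f, axis=1)
        tangential = f - (np.einsum("ij,ij->i", f, nrm))[:, None] * nrm
        assert np.all(np.linalg.norm(tangential[active], axis=1) <= 1e-8 * fmag[active])

    def test_contact_patch_grows_with_load(self, toy_defect_scenario):
        states = toy_defect_scenario["intact"].states
        comp = toy_defect_scenario["compartment"]
        from cartimech.pipeline import build_cartilage_model

        model = build_cartilage_model(comp, FRPEParams())
        counts = []
        for s in states[1:]:
            out = contact_traction(model, s.u, s.indenter_dz_mm)
            counts.append(int(out["active"].sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] > counts[0]


# ---------------------------------------------------------------------------
# submodeling
# ---------------------------------------------------------------------------
class TestSubmodel:
    def test_identity_submodel_reproduces_nodal_values(self, terzaghi_solution):
        mesh = terzaghi_solution["mesh"]
        states = terzaghi_solution["result"].states[:3]
        u_s, p_s = submodel_bcs(mesh, states, mesh.points)
        for k, s in enumerate(states):
            assert np.allclose(u_s[k], s.u, atol=1e-9)
            assert np.allclose(p_s[k], s.p, atol=1e-9)

    def test_uniform_field_interpolates_to_constant(self):
        mesh = flat_box_mesh()
        s = _fake_state(mesh, u_const=(0.1, -0.2, 0.3), p_const=0.7)
        pts = np.array([[0.3, 0.3, 0.2], [1.1, 0.9, 0.8], [1.9, 0.1, 0.9]])
        u_s, p_s = submodel_bcs(mesh, [s], pts)
        assert np.allclose(u_s[0], [0.1, -0.2, 0.3], atol=1e-12)
        assert np.allclose(p_s[0], 0.7, atol=1e-12)

    def test_linear_field_is_reproduced_exactly(self):
        mesh = flat_box_mesh()
        g = np.array([0.02, -0.01, 0.03])
        u = mesh.points @ np.diag(g)
        p = 1.0 + mesh.points @ np.array([0.5, -0.2, 0.1])
        s = _state_from_fields(mesh, u, p)
        rng = np.random.default_rng(0)
        pts = rng.uniform([0.05, 0.05, 0.05], [1.95, 1.45, 0.95], size=(15, 3))
        u_s, p_s = submodel_bcs(mesh, [s], pts)
        assert np.allclose(u_s[0], pts @ np.diag(g), atol=1e-10)
        assert np.allclose(p_s[0], 1.0 + pts @ np.array([0.5, -0.2, 0.1]), atol=1e-10)

    def test_point_outside_global_mesh_rejected(self):
        mesh = flat_box_mesh()
        s = _fake_state(mesh, u_const=(0, 0, 0), p_const=0.0)
        with pytest.raises(ValueError, match="outside the global mesh"):
            submodel_bcs(mesh, [s], np.array([[10.0, 10.0, 10.0]]))


def _fake_state(mesh, u_const, p_const):
    n = mesh.n_points
    return _state_from_fields(mesh, np.tile(u_const, (n, 1)).astype(float),
                              np.full(n, float(p_const)))


def _state_from_fields(mesh, u, p):
    ng = mesh.n_cells * 8
    z3 = np.zeros((ng, 3, 3))
    return State(
        time_s=0.0, stance_pct=0.0, u=u, p=p, strain=z3, stress_eff=z3.copy(),
        stress_total=z3.copy(), fibril_strain=np.zeros(ng),
        gauss_points=np.zeros((ng, 3)), contact_force_N=np.zeros(3),
        indenter_dz_mm=0.0, applied_force_N=0.0,
        reactions=np.zeros((mesh.n_points, 3)), n_iterations=0, rel_residual=0.0,
    )


# ---------------------------------------------------------------------------
# strain measures
# ---------------------------------------------------------------------------
class TestStrainMeasures:
    def test_zero_tensor_gives_zero_measures(self):
        out = strain_measures(np.zeros((3, 3)))
        assert out["max_shear_engineering"] == 0.0
        assert np.allclose(out["principal_log_strains"], 0.0)

    def test_diagonal_case(self):
        out = strain_measures(np.diag([0.1, 0.0, -0.2]))
        assert np.allclose(out["principal_log_strains"], [0.1, 0.0, -0.2])
        assert out["max_shear_engineering"] == pytest.approx(0.3)
        assert out["axial_strain"] == pytest.approx(-0.2)
        assert out["lateral_strain"] == pytest.approx(0.1)

    def test_invariants_match_characteristic_polynomial(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(10, 3, 3))
        eps = 0.1 * (A + np.swapaxes(A, 1, 2))
        out = strain_measures(eps)
        pr = out["principal_log_strains"]
        # eigenvalues satisfy the tensor invariants
        assert np.allclose(pr.sum(axis=1), np.trace(eps, axis1=1, axis2=2), atol=1e-10)
        assert np.allclose(np.prod(pr, axis=1), np.linalg.det(eps), atol=1e-10)
        i2 = 0.5 * (np.trace(eps, axis1=1, axis2=2) ** 2
                    - np.trace(eps @ eps, axis1=1, axis2=2))
        assert np.allclose(pr[:, 0] * pr[:, 1] + pr[:, 1] * pr[:, 2] + pr[:, 0] * pr[:, 2],
                           i2, atol=1e-10)

    def test_asymmetric_tensor_rejected(self):
        bad = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            strain_measures(bad)

    def test_log_strain_of_pure_stretch(self):
        F = np.diag([1.2, 1.0, 0.8])
        eps = log_strain_from_F(F)
        assert np.allclose(np.diag(eps), np.log([1.2, 1.0, 0.8]), atol=1e-12)


# ---------------------------------------------------------------------------
# convergence bookkeeping
# ---------------------------------------------------------------------------
class TestConvergenceStudy:
    PEAKS = {"min_principal_strain": -0.2, "shear_strain": 0.3,
             "max_principal_stress": 1.5, "fibril_strain": 0.05}

    def test_identical_levels_give_zero_difference(self):
        rep = convergence_study(lambda lv: dict(self.PEAKS), [1.0, 0.5])
        assert rep["max_rel_diff_pct"] == 0.0
        assert rep["pass"]

    def test_manufactured_linear_solution_is_level_independent(self):
        # a field linear elements represent exactly: peaks identical at any
        # density, so differences vanish
        def run(level):
            return dict(self.PEAKS)

        rep = convergence_study(run, [0.4, 0.2, 0.1])
        assert all(all(v == 0.0 for v in d.values()) for d in rep["rel_diff_pct"])

    def test_two_percent_rule_flags(self):
        def run(level):
            out = dict(self.PEAKS)
            out["shear_strain"] *= 1.0 + 0.05 * level
            return out

        rep = convergence_study(run, [1.0, 0.0])
        assert not rep["pass"]
        assert rep["max_rel_diff_pct"] > 2.0

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 refinement levels"):
            convergence_study(lambda lv: dict(self.PEAKS), [1.0])

    def test_failing_level_leaves_partial_table(self):
        def run(level):
            if level < 0.5:
                raise RuntimeError("did not converge")
            return dict(self.PEAKS)

        rep = convergence_study(run, [1.0, 0.25])
        assert rep["failures"] and not rep["pass"]
        assert rep["peaks"][0] is not None and rep["peaks"][1] is None


def test_state_history_export_round_trip(tmp_path, terzaghi_solution):
    import h5py
    import pandas as pd

    from cartimech.fe import write_state_history
    from cartimech.vtkio import read_vtu

    mesh = terzaghi_solution["mesh"]
    states = terzaghi_solution["result"].states[:4]
    paths = write_state_history(tmp_path, mesh, states, vtu_every=2)
    assert len(paths["vtu"]) == 2
    back = read_vtu(paths["vtu"][1])
    assert np.allclose(back.point_data["displacement_mm"], states[2].u, atol=1e-12)
    with h5py.File(paths["h5"]) as h5:
        assert h5["states/3/u"].shape == states[3].u.shape
        assert np.allclose(h5["states/3/p"][...], states[3].p)
        assert h5["states/1"].attrs["time_s"] == states[1].time_s
    df = pd.read_csv(paths["csv"])
    assert len(df) == 4
    assert "peak_pore_pressure_MPa" in df.columns
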