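"""Quasi-static mixed displacement-pressure poroelastic solver.

Formulation: equal-order trilinear u-p hexahedra, backward-Euler time
integration of the fluid mass balance, polynomial pressure-projection
stabilization of the equal-order pair, total-Lagrangian kinematics with
logarithmic strain output (a small-strain mode exists for closed-form
benchmarks), penalty-regularized frictionless contact against a rigid
analytic sphere, and linear node-to-ground spring sets (meniscal horns).

Discrete residual per time step (dt = t_n+1 - t_n):

  R_u = f_int(u, p) - f_ext(t) - f_contact - f_spring
  R_p = M(v(u) - v_prev) + dt * H p + S p

with v = det F (or div u in small-strain mode), H the Darcy flow matrix
and S the Bochev-Dohrmann projection stabilization. The Newton matrix
couples the analytic p-blocks with a finite-difference element tangent
for the u-block. Dirichlet rows are eliminated (identity rows, zero
residual); an optional extra unknown carries the indenter position under
force control.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..constitutive import ElementInversionError
from ..meshes import GAUSS_POINTS, GAUSS_WEIGHTS, VolumeMesh, hex_shape, hex_shape_grad

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration and boundary-condition records
# --------------------------------------------------------------------------
@dataclass
class SolverConfig:
    newton_rel_tol: float = 1e-7
    newton_abs_tol: float = 1e-8
    max_iterations: int = 30
    contact_penalty_MPa_per_mm: float = 30.0
    pressure_stabilization: float = 0.05
    kinematics: str = "finite"  # "finite" | "small"
    linear_solver: str = "splu"
    fd_step_mm: float = 1e-6
    line_search: bool = True
    contact_max_step_mm: float = 0.25  # indenter advance per Newton iteration

    def __post_init__(self):
        if self.newton_rel_tol <= 0 or self.newton_abs_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.kinematics not in ("finite", "small"):
            raise ValueError("kinematics must be 'finite' or 'small'")


def _as_time_fn(value):
    return value if callable(value) else (lambda t, v=value: v)


@dataclass
class DirichletBC:
    """Prescribed displacement components on a node set.

    ``value`` is a scalar, an array broadcastable to (n_nodes, n_comp), or
    a callable of time returning either.
    """

    nodes: np.ndarray
    components: tuple = (0, 1, 2)
    value = 0.0

    def __init__(self, nodes, components=(0, 1, 2), value=0.0):
        self.nodes = np.asarray(nodes, dtype=int)
        self.components = tuple(components)
        self.value = value

    def values_at(self, t):
        v = _as_time_fn(self.value)(t)
        return np.broadcast_to(np.asarray(v, dtype=float), (len(self.nodes), len(self.components)))


@dataclass
class PressureBC:
    nodes: np.ndarray
    value = 0.0

    def __init__(self, nodes, value=0.0):
        self.nodes = np.asarray(nodes, dtype=int)
        self.value = value

    def values_at(self, t):
        return np.broadcast_to(np.asarray(_as_time_fn(self.value)(t), dtype=float), (len(self.nodes),))


@dataclass
class FaceLoad:
    """Uniform normal pressure (MPa, positive pushes into the body) on a
    face set, lumped to face nodes in the reference configuration."""

    faces: np.ndarray
    pressure_MPa = 0.0

    def __init__(self, faces, pressure_MPa=0.0):
        self.faces = np.asarray(faces, dtype=int).reshape(-1, 2)
        self.pressure_MPa = pressure_MPa


class SpringSet:
    """Linear node-to-ground springs (meniscal horn attachments).

    Per-spring stiffnesses are positive; the group total is reported by
    :attr:`total_stiffness_N_per_mm`.
    """

    def __init__(self, nodes, stiffness_N_per_mm, label="springs", anchor_displacement=0.0):
        self.nodes = np.asarray(nodes, dtype=int)
        self.stiffness_N_per_mm = np.broadcast_to(
            np.asarray(stiffness_N_per_mm, dtype=float), self.nodes.shape
        ).copy()
        if np.any(self.stiffness_N_per_mm <= 0):
            raise ValueError("spring stiffness must be positive")
        self.label = label
        self.anchor_displacement = anchor_displacement

    @classmethod
    def from_total(cls, nodes, total_N_per_mm, label="springs"):
        nodes = np.asarray(nodes, dtype=int)
        return cls(nodes, total_N_per_mm / len(nodes), label=label)

    @property
    def total_stiffness_N_per_mm(self) -> float:
        return float(self.stiffness_N_per_mm.sum())


@dataclass
class ContactSpec:
    """Rigid analytic sphere contact over a boundary face set.

    ``mode='force'`` adds one unknown (the sphere's axial position) and
    enforces that the total axial contact force equals the protocol's
    axial force; ``mode='displacement'`` prescribes the axial position.
    """

    center0: np.ndarray
    radius_mm: float
    faces: np.ndarray
    mode: str = "force"
    # callable(t) -> axial z displacement (displacement mode)
    axial_position: object = None
    # callable(t) -> axial force (force mode); default: the protocol's force
    force_N: object = None

    def __post_init__(self):
        self.center0 = np.asarray(self.center0, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 2)
        if self.mode not in ("force", "displacement"):
            raise ValueError("contact mode must be 'force' or 'displacement'")


@dataclass
class FEModel:
    mesh: VolumeMesh
    materials: dict  # material id -> material object
    dirichlet: list = field(default_factory=list)
    pressure_bcs: list = field(default_factory=list)
    face_loads: list = field(default_factory=list)
    springs: list = field(default_factory=list)
    contact: ContactSpec | None = None


@dataclass
class State:
    """Converged solution at one protocol time point."""

    time_s: float
    stance_pct: float
    u: np.ndarray  # (n_nodes, 3) mm
    p: np.ndarray  # (n_nodes,) MPa, zero on non-poroelastic nodes
    strain: np.ndarray  # (n_gauss, 3, 3) logarithmic strain
    stress_eff: np.ndarray  # (n_gauss, 3, 3) effective Cauchy stress MPa
    stress_total: np.ndarray  # (n_gauss, 3, 3) total Cauchy stress MPa
    fibril_strain: np.ndarray  # (n_gauss,)
    gauss_points: np.ndarray  # (n_gauss, 3) reference coordinates
    contact_force_N: np.ndarray  # (3,) resultant on the tissue
    indenter_dz_mm: float
    applied_force_N: float
    reactions: np.ndarray  # (n_nodes, 3) nodal reaction forces
    n_iterations: int
    rel_residual: float
    F: np.ndarray | None = None  # (n_gauss, 3, 3) deformation gradient


class NonConvergenceError(RuntimeError):
    def __init__(self, step, message, partial=None):
        self.step = step
        self.partial = partial
        super().__init__(message)


@dataclass
class ProtocolResult:
    states: list
    failure: dict | None = None

    def __iter__(self):
        return iter(self.states)

    def __len__(self):
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]


# --------------------------------------------------------------------------
# the assembled system
# --------------------------------------------------------------------------
class System:
    """Precomputed discrete operators for one FEModel."""

    def __init__(self, model: FEModel, config: SolverConfig):
        self.model = model
        self.config = config
        mesh = model.mesh
        if mesh.cell_type != "hex8":
            raise NotImplementedError("the solver operates on hex8 meshes")
        self.n = mesh.n_points
        self.ne = mesh.n_cells
        self.cells = mesh.cells
        self.small = config.kinematics == "small"

        dN = hex_shape_grad(GAUSS_POINTS)  # (q, a, 3)
        self.N = hex_shape(GAUSS_POINTS)  # (q, a)
        xe = mesh.points[self.cells]
        J0 = np.einsum("qam,ean->eqnm", dN, xe)
        self.detJ0 = np.linalg.det(J0)
        if np.any(self.detJ0 <= 0):
            bad = np.unique(np.nonzero(self.detJ0 <= 0)[0])
            raise ValueError(f"inverted element(s) in reference mesh: {bad[:10].tolist()}")
        J0inv = np.linalg.inv(J0)
        # dN/dX[e,q,a,n] = dN/dxi[q,a,m] * (J0^-1)[e,q,m,n]
        self.dNdX = np.einsum("qam,eqmn->eqan", dN, J0inv)
        self.wdet = GAUSS_WEIGHTS[None, :] * self.detJ0  # (e, q)
        self.gauss_xyz = np.einsum("qa,ean->eqn", self.N, xe).reshape(-1, 3)

        # material element groups (ordered by material id)
        self.groups = []
        for mid, mat in model.materials.items():
            elems = np.nonzero(mesh.material_id == mid)[0]
            if len(elems):
                self.groups.append((mid, mat, elems))

        # pressure dof map: nodes attached to poroelastic elements
        poro_elems = np.concatenate(
            [e for _, m, e in self.groups if m.poroelastic] or [np.array([], dtype=int)]
        )
        poro_nodes = np.unique(self.cells[poro_elems]) if len(poro_elems) else np.array([], dtype=int)
        self.pmap = np.full(self.n, -1, dtype=int)
        self.pmap[poro_nodes] = np.arange(len(poro_nodes))
        self.n_p = len(poro_nodes)
        self.poro_nodes = poro_nodes
        self.has_contact_dof = model.contact is not None and model.contact.mode == "force"
        self.ndof = 3 * self.n + self.n_p + (1 if self.has_contact_dof else 0)
        self.c_dof = self.ndof - 1 if self.has_contact_dof else None

        # element dof indices
        self.edof_u = (3 * self.cells[:, :, None] + np.arange(3)[None, None, :]).reshape(self.ne, 24)
        self.edof_p = np.where(
            self.pmap[self.cells] >= 0, 3 * self.n + self.pmap[self.cells], -1
        )
        self.is_poro_elem = np.zeros(self.ne, dtype=bool)
        for _, mat, elems in self.groups:
            if mat.poroelastic:
                self.is_poro_elem[elems] = True
        self.poro_elems = np.nonzero(self.is_poro_elem)[0]

        # constant flow + stabilization matrices for poroelastic groups
        self.Hp = np.zeros((self.ne, 8, 8))
        self.Sp = np.zeros((self.ne, 8, 8))
        self.Mp = np.zeros((self.ne, 8, 8))  # mass-consistency matrix (N N)
        for _, mat, elems in self.groups:
            if not mat.poroelastic:
                continue
            k = mat.permeability
            d = self.dNdX[elems]
            w = self.wdet[elems]
            self.Hp[elems] = k * np.einsum("eq,eqam,eqbm->eab", w, d, d)
            Me = np.einsum("eq,qa,qb->eab", w, self.N, self.N)
            self.Mp[elems] = Me
            ve = np.einsum("eq,qa->ea", w, self.N)
            Ve = w.sum(axis=1)
            G_ref = mat.params.matrix_shear_modulus_MPa
            alpha = config.pressure_stabilization
            self.Sp[elems] = (alpha / G_ref) * (
                Me - ve[:, :, None] * ve[:, None, :] / Ve[:, None, None]
            )

        # contact surface nodes and reference areas
        self.contact_nodes = None
        if model.contact is not None:
            cs = model.contact
            fnodes = mesh.face_nodes(cs.faces)
            area, _ = mesh.face_areas_normals(cs.faces)
            w = np.zeros(self.n)
            np.add.at(w, fnodes.ravel(), np.repeat(area / 4.0, 4))
            self.contact_nodes = np.unique(fnodes)
            self.contact_area = w[self.contact_nodes]

        self._linear = (
            self.small
            and model.contact is None
            and all(m.linear for _, m, _ in self.groups)
        )
        self._K_cache = None
        self._dz_override = None  # set under displacement-controlled contact

        # static sparsity pattern: data vectors are concatenated in exactly
        # this block order by ``tangent``
        rows = [np.repeat(self.edof_u, 24, axis=1).ravel()]
        cols = [np.tile(self.edof_u, (1, 24)).ravel()]
        if self.n_p:
            pel = self.poro_elems
            eu_p, ep_p = self.edof_u[pel], self.edof_p[pel]
            rows += [np.repeat(eu_p, 8, axis=1).ravel(),
                     np.repeat(ep_p, 24, axis=1).ravel(),
                     np.repeat(ep_p, 8, axis=1).ravel()]
            cols += [np.tile(ep_p, (1, 24)).ravel(),
                     np.tile(eu_p, (1, 8)).ravel(),
                     np.tile(ep_p, (1, 8)).ravel()]
        for s in model.springs:
            for comp in range(3):
                rows.append(3 * s.nodes + comp)
                cols.append(3 * s.nodes + comp)
        if model.contact is not None:
            idx3 = 3 * self.contact_nodes[:, None] + np.arange(3)[None, :]
            rows.append(np.repeat(idx3, 3, axis=1).ravel())
            cols.append(np.tile(idx3, (1, 3)).ravel())
            if self.has_contact_dof:
                nc = len(self.contact_nodes)
                rows += [idx3.ravel(), np.full(3 * nc, self.c_dof), np.array([self.c_dof])]
                cols += [np.full(3 * nc, self.c_dof), idx3.ravel(), np.array([self.c_dof])]
        self._coo_rows = np.concatenate(rows)
        self._coo_cols = np.concatenate(cols)

    # ---- field helpers ------------------------------------------------
    def split(self, x):
        u = x[: 3 * self.n].reshape(self.n, 3)
        p_full = np.zeros(self.n)
        if self.n_p:
            p_full[self.poro_nodes] = x[3 * self.n : 3 * self.n + self.n_p]
        if self.has_contact_dof:
            dz = x[self.c_dof]
        else:
            dz = self._dz_override if self._dz_override is not None else 0.0
        return u, p_full, dz

    def deformation_gradient(self, u):
        ue = u[self.cells]
        G = np.einsum("eai,eqam->eqim", ue, self.dNdX)
        return np.eye(3)[None, None] + G

    def volumetric_measure(self, u):
        if self.small:
            ue = u[self.cells]
            return np.einsum("eai,eqai->eq", ue, self.dNdX)
        return np.linalg.det(self.deformation_gradient(u))

    def stresses(self, F):
        """Effective Cauchy stress and fibril strain at all Gauss points."""
        sig = np.zeros_like(F)
        fib = np.full(F.shape[:2], np.nan)
        for _, mat, elems in self.groups:
            s, f = mat.stress(F[elems].reshape(-1, 3, 3), small=self.small)
            sig[elems] = s.reshape(len(elems), 8, 3, 3)
            fib[elems] = np.asarray(f).reshape(len(elems), 8)
        return sig, fib

    # ---- internal force -----------------------------------------------
    def first_pk_total(self, F, p_g):
        """Total first Piola-Kirchhoff stress (Cauchy in small mode) at all
        Gauss points, for effective stress plus pore-pressure term."""
        sig, _ = self.stresses(F)
        I = np.eye(3)
        if self.small:
            return sig - p_g[..., None, None] * I[None, None]
        Jd = np.linalg.det(F)
        Finv = np.linalg.inv(F)
        sig_tot = sig - p_g[..., None, None] * I[None, None]
        return Jd[..., None, None] * np.einsum("eqij,eqMj->eqiM", sig_tot, Finv)

    def internal_force_elements(self, ue, pe_vals):
        """Element internal force vectors (ne, 24) for given element nodal
        displacements (ne, 8, 3) and pressures (ne, 8)."""
        G = np.einsum("eai,eqam->eqim", ue, self.dNdX)
        F = np.eye(3)[None, None] + G
        p_g = np.einsum("qb,eb->eq", self.N, pe_vals)
        P = self.first_pk_total(F, p_g)
        f = np.einsum("eq,eqim,eqam->eai", self.wdet, P, self.dNdX)
        return f.reshape(self.ne, 24)

    def _pressure_blocks(self, u, elems):
        """Analytic K_up (m,24,8), K_pu (m,8,24) for the given elements."""
        w = self.wdet[elems]
        d = self.dNdX[elems]
        m = len(elems)
        if self.small:
            B = np.einsum("eq,qb,eqai->eaib", w, self.N, d)
            K_up = -B.reshape(m, 24, 8)
            K_pu = np.einsum("eq,qa,eqbi->eabi", w, self.N, d).reshape(m, 8, 24)
            return K_up, K_pu
        ue = u[self.cells[elems]]
        G = np.einsum("eai,eqam->eqim", ue, d)
        F = np.eye(3)[None, None] + G
        Jd = np.linalg.det(F)
        Finv = np.linalg.inv(F)
        JFinvT = Jd[..., None, None] * np.swapaxes(Finv, -1, -2)  # (e,q,i,M)
        K_up = -np.einsum("eq,qb,eqiM,eqaM->eaib", w, self.N, JFinvT, d)
        K_pu = np.einsum("eq,qa,eqiM,eqbM->eabi", w, self.N, JFinvT, d)
        return K_up.reshape(m, 24, 8), K_pu.reshape(m, 8, 24)

    # ---- external loads, springs, contact ------------------------------
    def external_force(self, t):
        f = np.zeros((self.n, 3))
        for load in self.model.face_loads:
            pval = float(_as_time_fn(load.pressure_MPa)(t))
            if pval == 0.0:
                continue
            area, nrm = self.model.mesh.face_areas_normals(load.faces)
            fnodes = self.model.mesh.face_nodes(load.faces)
            contrib = (-pval * area)[:, None] * nrm  # push along inward normal
            for kk in range(4):
                np.add.at(f, fnodes[:, kk], contrib / 4.0)
        return f

    def spring_force(self, u, t):
        f = np.zeros((self.n, 3))
        for s in self.model.springs:
            anchor = np.asarray(_as_time_fn(s.anchor_displacement)(t), dtype=float)
            rel = u[s.nodes] - anchor
            f[s.nodes] += s.stiffness_N_per_mm[:, None] * rel
        return f

    def contact_forces(self, u, dz):
        """Nodal contact forces (on the tissue) and their derivative blocks.

        Returns (forces (m,3), dfdx (m,3,3), dfdz (m,3), active mask).
        """
        cs = self.model.contact
        nodes = self.contact_nodes
        x = self.model.mesh.points[nodes] + u[nodes]
        c = cs.center0 + np.array([0.0, 0.0, dz])
        d = x - c
        dist = np.linalg.norm(d, axis=1)
        gap = cs.radius_mm - dist  # >0 means penetration
        active = gap > 0
        nrm = d / dist[:, None]
        kA = self.config.contact_penalty_MPa_per_mm * self.contact_area
        fmag = np.where(active, kA * gap, 0.0)
        forces = fmag[:, None] * nrm
        I = np.eye(3)
        nn = nrm[:, :, None] * nrm[:, None, :]
        dfdx = np.where(
            active[:, None, None],
            kA[:, None, None] * (-nn + (gap / dist)[:, None, None] * (I[None] - nn)),
            0.0,
        )
        dfdz = -np.einsum("mij,j->mi", dfdx, np.array([0.0, 0.0, 1.0]))
        return forces, dfdx, dfdz, active

    # ---- residual and tangent ------------------------------------------
    def residual(self, x, v_prev, dt, t, applied_force=0.0, identity_dirichlet=True):
        u, p_full, dz = self.split(x)
        pe = p_full[self.cells]
        R = np.zeros(self.ndof)
        f_int = self.internal_force_elements(u[self.cells], pe)
        np.add.at(R, self.edof_u.ravel(), f_int.ravel())

        # fluid mass balance (poroelastic elements only)
        if self.n_p:
            pel = self.poro_elems
            v = self.volumetric_measure(u)
            dv = (v - v_prev)[pel]
            Rp_e = np.einsum("eq,qa,eq->ea", self.wdet[pel], self.N, dv)
            Rp_e += np.einsum("eab,eb->ea", dt * self.Hp[pel] + self.Sp[pel], pe[pel])
            np.add.at(R, self.edof_p[pel].ravel(), Rp_e.ravel())

        R[: 3 * self.n] -= self.external_force(t).ravel()
        R[: 3 * self.n] += self.spring_force(u, t).ravel()

        if self.model.contact is not None:
            forces, _, _, _ = self.contact_forces(u, dz)
            idx = (3 * self.contact_nodes[:, None] + np.arange(3)[None, :]).ravel()
            np.add.at(R, idx, -forces.ravel())
            if self.has_contact_dof:
                R[self.c_dof] = applied_force + forces[:, 2].sum()
        return R

    def dirichlet_dofs(self, t):
        """(dof indices, prescribed values) for all Dirichlet conditions."""
        dofs, vals = [], []
        for bc in self.model.dirichlet:
            v = bc.values_at(t)
            for j, comp in enumerate(bc.components):
                dofs.append(3 * bc.nodes + comp)
                vals.append(v[:, j])
        for bc in self.model.pressure_bcs:
            pidx = self.pmap[bc.nodes]
            if np.any(pidx < 0):
                raise ValueError("pressure BC on a node without a pressure dof")
            dofs.append(3 * self.n + pidx)
            vals.append(bc.values_at(t))
        if self.model.contact is not None and self.model.contact.mode == "displacement":
            pass  # handled by caller via dz argument
        if dofs:
            return np.concatenate(dofs), np.concatenate(vals)
        return np.array([], dtype=int), np.array([])

    def tangent(self, x, dt, t):
        u, p_full, dz = self.split(x)
        ue = u[self.cells]
        pe = p_full[self.cells]
        h = self.config.fd_step_mm

        if self._linear and self._K_cache is not None and self._K_cache[0] == dt:
            return self._K_cache[1].copy()

        # consistent tangent by finite differences on the pointwise stress
        # function: A[i,M,j,N] = dP_iM/dF_jN, then K_uu = B^T A B
        G = np.einsum("eai,eqam->eqim", ue, self.dNdX)
        F = np.eye(3)[None, None] + G
        p_g = np.einsum("qb,eb->eq", self.N, pe)
        P0 = self.first_pk_total(F, p_g)
        A = np.empty(F.shape[:2] + (3, 3, 3, 3))
        for j in range(3):
            for Nc in range(3):
                Fp = F.copy()
                Fp[..., j, Nc] += h
                A[..., :, :, j, Nc] = (self.first_pk_total(Fp, p_g) - P0) / h
        A *= self.wdet[..., None, None, None, None]
        tmp = np.einsum("eqiMjN,eqbN->eqiMjb", A, self.dNdX)
        K_uu = np.einsum("eqaM,eqiMjb->eaibj", self.dNdX, tmp).reshape(self.ne, 24, 24)

        vals = [K_uu.ravel()]

        if self.n_p:
            pel = self.poro_elems
            K_up, K_pu = self._pressure_blocks(u, pel)
            K_pp = dt * self.Hp[pel] + self.Sp[pel]
            vals += [K_up.ravel(), K_pu.ravel(), K_pp.ravel()]

        for s in self.model.springs:
            for _ in range(3):
                vals.append(s.stiffness_N_per_mm)

        if self.model.contact is not None:
            _, dfdx, dfdz, active = self.contact_forces(u, dz)
            nds = self.contact_nodes
            # R_u rows get -f: d(-f)/du = -dfdx
            vals.append((-dfdx).ravel())
            if self.has_contact_dof:
                vals.append((-dfdz).ravel())
                vals.append(dfdx[:, 2, :].ravel())
                # regularize the indenter row when no contact is active yet
                diag = dfdz[:, 2].sum()
                k_floor = self.config.contact_penalty_MPa_per_mm * float(self.contact_area.mean())
                if abs(diag) < k_floor:
                    diag = k_floor
                vals.append(np.array([diag]))

        K = sp.coo_matrix(
            (np.concatenate(vals), (self._coo_rows, self._coo_cols)),
            shape=(self.ndof, self.ndof),
        ).tocsr()
        if self._linear:
            self._K_cache = (dt, K.copy())
        return K

    # ---- solve one step -------------------------------------------------
    def newton_step(self, x, v_prev, dt, t, applied_force, ref_force):
        cfg = self.config
        dofs, dvals = self.dirichlet_dofs(t)
        x = x.copy()
        x[dofs] = dvals
        free_scale = max(ref_force, 1.0)
        r0 = None
        for it in range(cfg.max_iterations):
            R = self.residual(x, v_prev, dt, t, applied_force)
            R[dofs] = 0.0
            nr = np.linalg.norm(R)
            if r0 is None:
                r0 = max(nr, cfg.newton_abs_tol)
            rel = nr / max(r0, free_scale * 1e-12)
            if nr <= cfg.newton_abs_tol * free_scale or rel <= cfg.newton_rel_tol:
                return x, it, rel
            K = self.tangent(x, dt, t)
            K = _apply_identity_rows(K, dofs)
            try:
                dx = _sparse_solve(K, -R, cfg.linear_solver)
            except RuntimeError as exc:
                raise NonConvergenceError(
                    None,
                    "singular system: check for unconstrained rigid-body modes "
                    f"(no displacement BC fixes all six modes?): {exc}",
                ) from exc
            if self.has_contact_dof:
                cap = cfg.contact_max_step_mm
                u_now, _, dz_now = self.split(x)
                _, _, _, act_now = self.contact_forces(u_now, dz_now)
                if not act_now.any() and applied_force > 0:
                    # approach phase: advance the sphere by the minimum
                    # clearance so contact engages in one step
                    xs = self.model.mesh.points[self.contact_nodes] + u_now[self.contact_nodes]
                    c = self.model.contact.center0 + np.array([0.0, 0.0, dz_now])
                    clearance = np.linalg.norm(xs - c, axis=1) - self.model.contact.radius_mm
                    dx[self.c_dof] = -(clearance.min() * 1.05 + 1e-6)
                dx[self.c_dof] = np.clip(dx[self.c_dof], -cap, cap)
            approach_phase = False
            if self.model.contact is not None:
                u_now, _, dz_now = self.split(x)
                _, _, _, act = self.contact_forces(u_now, dz_now)
                approach_phase = not act.any()
            backtrack = cfg.line_search and not approach_phase
            scale = 1.0
            xn = None
            for _ in range(8):
                trial = x + scale * dx
                try:
                    Rn = self.residual(trial, v_prev, dt, t, applied_force)
                except ElementInversionError:
                    scale *= 0.5
                    continue
                Rn[dofs] = 0.0
                xn = trial
                if not backtrack:
                    break
                if np.linalg.norm(Rn) < (1.0 - 0.1 * scale) * nr or scale < 0.2:
                    break
                scale *= 0.5
            if xn is None:
                raise NonConvergenceError(
                    None, "Newton step inverts elements even after backtracking"
                )
            x = xn
        R = self.residual(x, v_prev, dt, t, applied_force)
        R[dofs] = 0.0
        nr = np.linalg.norm(R)
        rel = nr / max(r0, 1e-300)
        if nr <= 10 * cfg.newton_abs_tol * free_scale or rel <= 10 * cfg.newton_rel_tol:
            log.warning("Newton reached max iterations with near-converged residual %.3e", rel)
            return x, cfg.max_iterations, rel
        msg = f"Newton failed: relative residual {rel:.3e}"
        if not self.model.dirichlet and not self.model.springs:
            msg += (" — singular system: no displacement boundary conditions or "
                    "springs constrain the six rigid-body modes")
        raise NonConvergenceError(None, msg)


def _apply_identity_rows(K: sp.csr_matrix, dofs: np.ndarray) -> sp.csr_matrix:
    if len(dofs) == 0:
        return K
    n = K.shape[0]
    scale = np.ones(n)
    scale[dofs] = 0.0
    K = sp.diags(scale) @ K
    K = K + sp.coo_matrix((np.ones(len(dofs)), (dofs, dofs)), shape=(n, n))
    return K.tocsr()


def _sparse_solve(K, b, method="splu"):
    K = K.tocsc()
    try:
        lu = spla.splu(K)
    except RuntimeError as exc:
        raise RuntimeError(str(exc))
    x = lu.solve(b)
    if not np.all(np.isfinite(x)):
        raise RuntimeError("linear solve produced non-finite values")
    # guard against silently garbage factorizations of singular systems
    bn = np.linalg.norm(b)
    if bn > 0 and np.linalg.norm(K @ x - b) > 1e-6 * (bn + np.linalg.norm(x)):
        raise RuntimeError("linear system numerically singular")
    return x


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------
def assemble(model: FEModel, x=None, v_prev=None, dt: float = 1.0, t: float = 0.0,
             config: SolverConfig | None = None):
    """Assemble the Newton system (sparse matrix, residual) at a state.

    With the zero state, no loads and no BCs the residual is identically
    zero. Dirichlet rows are replaced by identity rows.
    """
    config = config or SolverConfig()
    sys_ = System(model, config)
    if x is None:
        x = np.zeros(sys_.ndof)
    if v_prev is None:
        v_prev = sys_.volumetric_measure(sys_.split(x)[0])
    R = sys_.residual(x, v_prev, dt, t)
    K = sys_.tangent(x, dt, t)
    dofs, _ = sys_.dirichlet_dofs(t)
    K = _apply_identity_rows(K, dofs)
    R[dofs] = 0.0
    return K, R


def contact_traction(model: FEModel, u: np.ndarray, dz: float = 0.0,
                     config: SolverConfig | None = None):
    """Nodal contact forces and contact pressure on the contact surface.

    Forces are normal to the rigid sphere (frictionless penalty contact,
    a regularization of the hard pressure-overclosure law: pressure =
    penalty x penetration); zero wherever the gap is open. Returns a dict
    with nodes, forces, pressures and the total resultant.
    """
    config = config or SolverConfig()
    sys_ = System(model, config)
    if sys_.contact_nodes is None:
        raise ValueError("model has no contact definition")
    forces, _, _, active = sys_.contact_forces(u, dz)
    pressure = np.linalg.norm(forces, axis=1) / sys_.contact_area
    return {
        "nodes": sys_.contact_nodes,
        "forces_N": forces,
        "pressure_MPa": pressure,
        "active": active,
        "total_force_N": forces.sum(axis=0),
    }


def _extract_state(sys_: System, x, t, stance, applied, ref_dofs_vals):
    from .strain import log_strain_from_F

    u, p_full, dz = sys_.split(x)
    F = sys_.deformation_gradient(u)
    sig_eff, fib = sys_.stresses(F)
    pg = np.einsum("qb,eb->eq", sys_.N, p_full[sys_.cells])
    sig_tot = sig_eff - pg[..., None, None] * np.eye(3)[None, None]
    if sys_.small:
        G = F - np.eye(3)[None, None]
        strain = 0.5 * (G + np.swapaxes(G, -1, -2))
    else:
        strain = log_strain_from_F(F.reshape(-1, 3, 3)).reshape(F.shape)
    if sys_.model.contact is not None:
        forces, _, _, _ = sys_.contact_forces(u, dz)
        cf = forces.sum(axis=0)
    else:
        cf = np.zeros(3)
    # nodal reactions: residual without Dirichlet elimination
    dofs, vals = ref_dofs_vals
    Rfull = sys_.residual(x, sys_._v_prev_for_state, sys_._dt_for_state, t, applied)
    reactions = np.zeros((sys_.n, 3))
    urows = dofs[dofs < 3 * sys_.n]
    # constraint force on the body at a fixed dof equals the residual there
    reactions.ravel()[urows] = Rfull[urows]
    return State(
        time_s=t, stance_pct=stance, u=u, p=p_full,
        strain=strain.reshape(-1, 3, 3), F=F.reshape(-1, 3, 3),
        stress_eff=sig_eff.reshape(-1, 3, 3),
        stress_total=sig_tot.reshape(-1, 3, 3), fibril_strain=fib.ravel(),
        gauss_points=sys_.gauss_xyz, contact_force_N=cf, indenter_dz_mm=float(dz),
        applied_force_N=float(applied), reactions=reactions,
        n_iterations=sys_._iters_for_state, rel_residual=sys_._rel_for_state,
    )


def solve_protocol(model: FEModel, protocol, config: SolverConfig | None = None,
                   force_scale: float = 1.0) -> ProtocolResult:
    """March the model through a load protocol.

    The protocol's axial force drives the contact in force mode (scaled
    by ``force_scale``); face loads and Dirichlet values are evaluated at
    each protocol time. Returns the state sequence; on non-convergence
    the partial history plus a failure record.
    """
    config = config or SolverConfig()
    sys_ = System(model, config)
    times = np.asarray(protocol.times_s, dtype=float)
    stance = np.asarray(protocol.stance_pct, dtype=float)
    forces = np.asarray(protocol.axial_force_N, dtype=float) * force_scale

    x = np.zeros(sys_.ndof)
    states = []
    sys_._v_prev_for_state = sys_.volumetric_measure(sys_.split(x)[0])
    sys_._dt_for_state = max(times[1] - times[0], 1e-12) if len(times) > 1 else 1.0
    sys_._iters_for_state = 0
    sys_._rel_for_state = 0.0
    # initial state (zero load assumed at the first protocol point)
    states.append(_extract_state(sys_, x, times[0], stance[0], forces[0],
                                 sys_.dirichlet_dofs(times[0])))
    v_prev = sys_.volumetric_measure(sys_.split(x)[0])
    for k in range(1, len(times)):
        dt = max(times[k] - times[k - 1], 1e-12)
        t = times[k]
        if model.contact is not None and model.contact.mode == "displacement":
            dzval = float(_as_time_fn(model.contact.axial_position)(t))
            # prescribed indenter position: stored via closure on contact_forces
            x_dz = dzval
        else:
            x_dz = None
        try:
            if x_dz is None:
                x, iters, rel = sys_.newton_step(
                    x, v_prev, dt, t, applied_force=forces[k],
                    ref_force=max(abs(forces).max(), 1.0),
                )
            else:
                x, iters, rel = _newton_step_displacement(sys_, x, v_prev, dt, t, x_dz)
        except NonConvergenceError as exc:
            failure = {"step": k, "time_s": float(t), "stance_pct": float(stance[k]),
                       "message": str(exc)}
            log.error("protocol failed at step %d (%.1f%% stance): %s", k, stance[k], exc)
            return ProtocolResult(states=states, failure=failure)
        sys_._v_prev_for_state = v_prev
        sys_._dt_for_state = dt
        sys_._iters_for_state = iters
        sys_._rel_for_state = rel
        if x_dz is not None:
            sys_._dz_override = x_dz
        st = _extract_state(sys_, x, t, stance[k], forces[k], sys_.dirichlet_dofs(t))
        sys_._dz_override = None
        states.append(st)
        # force-balance audit (0.5 % contract on the axial contact reaction)
        if model.contact is not None and model.contact.mode == "force" and forces[k] > 1e-9:
            err = abs(-st.contact_force_N[2] - forces[k]) / forces[k]
            if err > 5e-3:
                log.warning("axial contact force off by %.2e at step %d", err, k)
        v_prev = sys_.volumetric_measure(sys_.split(x)[0])
    return ProtocolResult(states=states)


def _newton_step_displacement(sys_, x, v_prev, dt, t, dz):
    """Newton step with the sphere position prescribed (submodels)."""
    sys_._dz_override = dz
    try:
        return sys_.newton_step(x, v_prev, dt, t, applied_force=0.0, ref_force=1.0)
    finally:
        sys_._dz_override = None
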