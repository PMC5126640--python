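"""Material laws.

Cartilage is a fibril-reinforced porous material: a compressible
Neo-Hookean ground matrix (proteoglycan gel + fluid, with Darcy flow
handled by the solver) reinforced by tension-only collagen fibrils whose
stiffness grows linearly with strain, sigma_f = (E0 + Ee * eps) * eps.
Fibrils follow a Benninghoff arcade: parallel to the surface split lines
in the superficial zone, perpendicular to the bone interface in the deep
zone, with a spherical-linear blend in between. Fibril viscoelasticity is
deliberately omitted: the analysis outputs are strain snapshots over a
single stance cycle, for which the elastic fibril backbone governs the
response; a rate-dependent fibril law can be slotted in behind
:func:`fibril_stress_1d` without touching the solver.

Menisci are transversely isotropic linear elastic with the stiff axis
along the circumferential fibre direction; bone is isotropic elastic with
CT-calibrated modulus (see :mod:`cartimech.calibration`).

Units: MPa, mm, N, s.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# --------------------------------------------------------------------------
# parameter cards
# --------------------------------------------------------------------------
def _EnuToGK(E: float, nu: float):
    return E / (2 * (1 + nu)), E / (3 * (1 - 2 * nu))


@dataclass
class FRPEParams:
    """Fibril-reinforced poroelastic cartilage constants.

    Defaults are the commonly used fibril-reinforced cartilage card:
    non-fibrillar matrix E = 0.31 MPa, nu = 0.42, fibril moduli
    E0 = 0.47 MPa and Ee = 150 MPa, permeability 2e-3 mm^4/(N s),
    superficial/deep arcade zone fractions 0.15 / 0.70, one primary fibril
    family plus 13 isotropically distributed secondary families.
    """

    matrix_shear_modulus_MPa: float = 0.31 / (2 * 1.42)
    matrix_bulk_modulus_MPa: float = 0.31 / (3 * (1 - 2 * 0.42))
    permeability_mm4_per_Ns: float = 2.0e-3
    fibril_modulus_initial_MPa: float = 0.47
    fibril_modulus_strain_dependent_MPa: float = 150.0
    primary_fibril_density_fraction: float = 0.8
    n_secondary_directions: int = 13
    solid_volume_fraction: float = 0.2
    superficial_fraction: float = 0.15
    deep_fraction: float = 0.70

    def __post_init__(self):
        if min(self.matrix_shear_modulus_MPa, self.matrix_bulk_modulus_MPa,
               self.fibril_modulus_initial_MPa, self.fibril_modulus_strain_dependent_MPa) < 0:
            raise ValueError("moduli must be non-negative")
        if self.permeability_mm4_per_Ns <= 0:
            raise ValueError("permeability must be positive")
        for f in (self.primary_fibril_density_fraction, self.solid_volume_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("density fractions must lie in [0, 1]")

    @classmethod
    def from_matrix_EnU(cls, E: float, nu: float, **kw) -> "FRPEParams":
        G, K = _EnuToGK(E, nu)
        return cls(matrix_shear_modulus_MPa=G, matrix_bulk_modulus_MPa=K, **kw)


@dataclass
class MeniscusParams:
    """Transversely isotropic meniscus; stiff axis = circumferential."""

    E_circumferential_MPa: float = 120.0
    E_transverse_MPa: float = 20.0
    G_MPa: float = 8.33
    nu_in_plane: float = 0.2
    nu_out_of_plane: float = 0.3

    def __post_init__(self):
        C = meniscus_elasticity_tensor(self, np.array([1.0, 0.0, 0.0]))[0]
        w = np.linalg.eigvalsh(C)
        if w.min() <= 0:
            raise ValueError(
                "non-physical Poisson/modulus combination: elasticity tensor "
                f"not positive definite (min eigenvalue {w.min():.3g})"
            )


@dataclass
class FibrilArchitecture:
    """Per-integration-point arcade data for one mesh.

    All arrays are (n_points, ...): ``primary_direction`` unit vectors,
    ``normalized_depth`` in [0, 1] (0 = articular surface, 1 = bone),
    ``split_line_direction`` unit surface tangents.
    """

    primary_direction: np.ndarray
    normalized_depth: np.ndarray
    split_line_direction: np.ndarray
    superficial_fraction: float = 0.15
    deep_fraction: float = 0.70

    def __post_init__(self):
        n = np.linalg.norm(self.primary_direction, axis=-1)
        if np.any(np.abs(n - 1) > 1e-8):
            raise ValueError("primary directions must be unit vectors")
        d = self.normalized_depth
        if np.any((d < -1e-12) | (d > 1 + 1e-12)):
            raise ValueError("normalized depth outside [0, 1]")


# --------------------------------------------------------------------------
# Benninghoff arcade
# --------------------------------------------------------------------------
def arcade_direction(
    normalized_depth,
    surface_normal,
    split_line,
    superficial_fraction: float = 0.15,
    deep_fraction: float = 0.70,
):
    """Primary collagen fibril direction at a given normalized depth.

    Superficial zone (depth <= superficial_fraction): along the split
    line.  Deep zone (depth >= deep_fraction): along -surface_normal,
    i.e. pointing into the bone.  Middle zone: spherical linear
    interpolation between the two; the result is always unit norm.
    Vectorized over leading axes.
    """
    d = np.asarray(normalized_depth, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("normalized depth must lie in [0, 1]")
    n = np.asarray(surface_normal, dtype=float)
    t = np.asarray(split_line, dtype=float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    n = np.atleast_2d(n) * np.ones((d.size, 3))
    t = np.atleast_2d(t) * np.ones((d.size, 3))
    if np.any(np.abs(np.einsum("ij,ij->i", n, t)) > 1e-8):
        raise ValueError("split line must be tangent to the surface")
    a = t  # superficial end
    b = -n  # deep end
    s = np.clip((d - superficial_fraction) / (deep_fraction - superficial_fraction), 0.0, 1.0)
    # slerp between orthogonal unit vectors: angle is pi/2
    ang = 0.5 * np.pi * s
    out = np.cos(ang)[:, None] * a + np.sin(ang)[:, None] * b
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out[0] if scalar else out


def build_architecture(mesh, surface_normal_fn, split_line_fn, thickness_fn,
                       z_top_fn, params: FRPEParams) -> FibrilArchitecture:
    """Arcade field at the Gauss points of a layered cartilage mesh.

    The callables map (x, y) arrays to the surface normal / split line /
    thickness / surface height at those plan coordinates; depth is taken
    along z (the mesh is a shallow graph over the plan).
    """
    from .meshes import GAUSS_POINTS, hex_shape

    N = hex_shape(GAUSS_POINTS)  # (8, 8)
    gp = np.einsum("qa,ean->eqn", N, mesh.points[mesh.cells]).reshape(-1, 3)
    x, y, z = gp[:, 0], gp[:, 1], gp[:, 2]
    zt = z_top_fn(x, y)
    th = thickness_fn(x, y)
    depth = np.clip((zt - z) / th, 0.0, 1.0)
    nrm = surface_normal_fn(x, y)
    sl = split_line_fn(x, y)
    prim = arcade_direction(depth, nrm, sl, params.superficial_fraction, params.deep_fraction)
    return FibrilArchitecture(
        primary_direction=prim, normalized_depth=depth, split_line_direction=sl,
        superficial_fraction=params.superficial_fraction, deep_fraction=params.deep_fraction,
    )


# --------------------------------------------------------------------------
# stress laws (vectorized over leading axes)
# --------------------------------------------------------------------------
def fibril_stress_1d(fibril_strain, params: FRPEParams):
    """Tension-only strain-stiffening fibril stress (MPa).

    sigma = (E0 + Ee * eps) * eps for eps > 0, zero in compression.
    """
    eps = np.asarray(fibril_strain, dtype=float)
    if np.any(eps <= -1):
        raise ValueError("fibril strain must exceed -1")
    E0 = params.fibril_modulus_initial_MPa
    Ee = params.fibril_modulus_strain_dependent_MPa
    return np.where(eps > 0, (E0 + Ee * eps) * eps, 0.0)


def matrix_stress(F, params: FRPEParams):
    """Effective Cauchy stress of the compressible Neo-Hookean matrix.

    sigma = G/J (b - I) + K ln(J)/J I  with b = F F^T; zero at F = I.
    Vectorized: F may be (..., 3, 3).
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        bad = np.nonzero(np.atleast_1d(J) <= 0)[0]
        raise ElementInversionError(bad)
    G = params.matrix_shear_modulus_MPa
    K = params.matrix_bulk_modulus_MPa
    b = F @ np.swapaxes(F, -1, -2)
    I = np.broadcast_to(np.eye(3), F.shape)
    Jm = J[..., None, None]
    # split off the volumetric part of the NH term so stress vanishes at F=I
    sig = G / Jm * (b - np.cbrt(Jm) ** 2 * I) + K * np.log(Jm) / Jm * I
    return 0.5 * (sig + np.swapaxes(sig, -1, -2))


class ElementInversionError(ValueError):
    def __init__(self, element_ids):
        self.element_ids = np.atleast_1d(element_ids)
        super().__init__(f"negative Jacobian in element(s) {self.element_ids[:10].tolist()}")


def secondary_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit directions (deterministic Fibonacci sphere)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1 - 2 * (k + 0.5) / n
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def effective_stress(F, primary_direction, params: FRPEParams):
    """Total effective (solid-skeleton) Cauchy stress and primary fibril strain.

    The fibril network is a primary family along the arcade direction
    plus ``n_secondary_directions`` fixed secondary families sharing the
    remaining density. Each family contributes a tension-only 1-D stress
    push-forwarded onto its deformed direction dyad. Returns
    (sigma (...,3,3), fibril_strain (...)). Fibril strain is the
    engineering stretch minus one along the primary family.
    """
    F = np.asarray(F, dtype=float)
    a0 = np.asarray(primary_direction, dtype=float)
    sig = matrix_stress(F, params)

    def family_stress(dir0, dens):
        a = np.einsum("...ij,...j->...i", F, np.broadcast_to(dir0, F.shape[:-2] + (3,)))
        lam = np.linalg.norm(a, axis=-1)
        eps = lam - 1.0
        s1d = fibril_stress_1d(eps, params) * dens
        ahat = a / lam[..., None]
        dyad = ahat[..., :, None] * ahat[..., None, :]
        # the 1-D law is taken as the Cauchy stress carried along the
        # deformed fibril direction
        return s1d[..., None, None] * dyad, eps

    s_p, eps_p = family_stress(a0, params.primary_fibril_density_fraction)
    sig = sig + s_p
    ns = params.n_secondary_directions
    if ns > 0 and params.primary_fibril_density_fraction < 1.0:
        dens = (1.0 - params.primary_fibril_density_fraction) / ns
        D = secondary_directions(ns)  # (nf, 3)
        a = np.einsum("...ij,fj->...fi", F, D)
        lam = np.linalg.norm(a, axis=-1)
        s1d = fibril_stress_1d(lam - 1.0, params) * dens
        ahat = a / lam[..., None]
        sig = sig + np.einsum("...f,...fi,...fj->...ij", s1d, ahat, ahat)
    return sig, eps_p


def meniscus_elasticity_tensor(params: MeniscusParams, circumferential_direction):
    """6x6 stiffness (Voigt, engineering shear) in the local frame plus the
    local->global rotation matrix whose first axis is the circumferential
    direction."""
    Ec, Et = params.E_circumferential_MPa, params.E_transverse_MPa
    G = params.G_MPa
    nu_t = params.nu_in_plane        # within the transverse (2-3) plane
    nu_ct = params.nu_out_of_plane   # axial(1)-transverse coupling
    # compliance in Voigt order (11, 22, 33, 23, 13, 12); axis 1 = fibre
    S = np.zeros((6, 6))
    S[0, 0] = 1 / Ec
    S[1, 1] = S[2, 2] = 1 / Et
    S[0, 1] = S[0, 2] = S[1, 0] = S[2, 0] = -nu_ct / Ec
    S[1, 2] = S[2, 1] = -nu_t / Et
    Gt = Et / (2 * (1 + nu_t))
    S[3, 3] = 1 / Gt
    S[4, 4] = S[5, 5] = 1 / G
    C = np.linalg.inv(S)
    w = np.linalg.eigvalsh(0.5 * (C + C.T))
    if w.min() <= 0:
        raise ValueError("meniscus elasticity tensor not positive definite")
    e1 = np.asarray(circumferential_direction, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    trial = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(trial, e1)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    R = np.column_stack([e1, e2, e3])
    return 0.5 * (C + C.T), R


_VOIGT = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


def voigt_to_tensor(C: np.ndarray) -> np.ndarray:
    """6x6 engineering-shear Voigt stiffness -> full 3x3x3x3 tensor.

    With engineering shear strains the entries map without factors:
    C4[i,j,k,l] = C4[i,j,l,k] = C[I,J].
    """
    C4 = np.zeros((3, 3, 3, 3))
    for I, (i, j) in enumerate(_VOIGT):
        for Jv, (k, l) in enumerate(_VOIGT):
            for a, b in {(i, j), (j, i)}:
                for c, d in {(k, l), (l, k)}:
                    C4[a, b, c, d] = C[I, Jv]
    return C4


def tensor_to_voigt(C4: np.ndarray) -> np.ndarray:
    out = np.zeros((6, 6))
    for I, (i, j) in enumerate(_VOIGT):
        for Jv, (k, l) in enumerate(_VOIGT):
            out[I, Jv] = C4[i, j, k, l]
    return out


def rotate_voigt_stiffness(C: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Rotate a 6x6 Voigt (engineering-shear) stiffness to the global frame."""
    C4r = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, voigt_to_tensor(C))
    return tensor_to_voigt(C4r)
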