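"""Material wrappers evaluated at Gauss points by the solver.

Each wrapper exposes ``stress(F, small) -> (cauchy_effective, fibril_strain)``
vectorized over an array of deformation gradients belonging to its
elements (in element-gauss order). ``fibril_strain`` is NaN for
non-fibrillar materials.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..constitutive import (
    FRPEParams,
    FibrilArchitecture,
    MeniscusParams,
    effective_stress,
    fibril_stress_1d,
    matrix_stress,
    meniscus_elasticity_tensor,
    rotate_voigt_stiffness,
    secondary_directions,
)


def _sym_small_strain(F):
    g = F - np.eye(3)
    return 0.5 * (g + np.swapaxes(g, -1, -2))


@dataclass
class PoroelasticCartilage:
    """Fibril-reinforced poroelastic cartilage with an arcade direction per
    Gauss point of its element block."""

    params: FRPEParams
    architecture: FibrilArchitecture

    poroelastic = True
    linear = False

    @property
    def permeability(self) -> float:
        return self.params.permeability_mm4_per_Ns

    def stress(self, F: np.ndarray, small: bool = False):
        a0 = self.architecture.primary_direction
        if small:
            eps = _sym_small_strain(F)
            G = self.params.matrix_shear_modulus_MPa
            K = self.params.matrix_bulk_modulus_MPa
            tr = np.trace(eps, axis1=-2, axis2=-1)[..., None, None]
            I = np.broadcast_to(np.eye(3), F.shape)
            sig = 2 * G * (eps - tr / 3 * I) + K * tr * I
            epsf = np.einsum("...i,...ij,...j->...", a0, eps, a0)
            sf = fibril_stress_1d(epsf, self.params) * self.params.primary_fibril_density_fraction
            dyad = a0[..., :, None] * a0[..., None, :]
            sig = sig + sf[..., None, None] * dyad
            ns = self.params.n_secondary_directions
            if ns > 0 and self.params.primary_fibril_density_fraction < 1.0:
                dens = (1.0 - self.params.primary_fibril_density_fraction) / ns
                D = secondary_directions(ns)
                e_d = np.einsum("fi,...ij,fj->...f", D, eps, D)
                s_d = fibril_stress_1d(e_d, self.params) * dens
                sig = sig + np.einsum("...f,fi,fj->...ij", s_d, D, D)
            return sig, epsf
        return effective_stress(F, a0, self.params)


@dataclass
class IsotropicElastic:
    """Isotropic elasticity; ``E_MPa`` may be a scalar or per-Gauss-point
    array (CT-calibrated bone)."""

    E_MPa: float | np.ndarray = 5000.0
    nu: float = 0.3

    poroelastic = False
    linear = True
    permeability = None

    def stress(self, F: np.ndarray, small: bool = False):
        E = np.asarray(self.E_MPa, dtype=float)
        G = E / (2 * (1 + self.nu))
        K = E / (3 * (1 - 2 * self.nu))
        if small:
            eps = _sym_small_strain(F)
            tr = np.trace(eps, axis1=-2, axis2=-1)
            I = np.broadcast_to(np.eye(3), F.shape)
            sig = 2 * G[..., None, None] * (eps - tr[..., None, None] / 3 * I) \
                + K[..., None, None] * tr[..., None, None] * I
        else:
            J = np.linalg.det(F)[..., None, None]
            b = F @ np.swapaxes(F, -1, -2)
            I = np.broadcast_to(np.eye(3), F.shape)
            sig = G[..., None, None] / J * (b - np.cbrt(J) ** 2 * I) \
                + K[..., None, None] * np.log(J) / J * I
        fib = np.full(F.shape[:-2], np.nan)
        return sig, fib


@dataclass
class TransverselyIsotropicElastic:
    """Meniscus: transversely isotropic linear elasticity with a
    circumferential fibre direction per Gauss point (or one shared)."""

    params: MeniscusParams
    circumferential_direction: np.ndarray = None

    poroelastic = False
    linear = True
    permeability = None

    def __post_init__(self):
        d = self.circumferential_direction
        if d is None:
            d = np.array([1.0, 0.0, 0.0])
        self.circumferential_direction = np.asarray(d, dtype=float)

    def _voigt_tensors(self, n: int):
        d = self.circumferential_direction
        if d.ndim == 1:
            C, R = meniscus_elasticity_tensor(self.params, d)
            return np.broadcast_to(rotate_voigt_stiffness(C, R), (n, 6, 6))
        out = np.empty((n, 6, 6))
        for i in range(n):
            C, R = meniscus_elasticity_tensor(self.params, d[i])
            out[i] = rotate_voigt_stiffness(C, R)
        return out

    def stress(self, F: np.ndarray, small: bool = False):
        eps = _sym_small_strain(F)  # geometric linearity assumed for meniscus
        shp = F.shape[:-2]
        epsf = eps.reshape(-1, 3, 3)
        ev = np.column_stack([
            epsf[:, 0, 0], epsf[:, 1, 1], epsf[:, 2, 2],
            2 * epsf[:, 1, 2], 2 * epsf[:, 0, 2], 2 * epsf[:, 0, 1],
        ])
        Cv = self._voigt_tensors(len(epsf))
        sv = np.einsum("nij,nj->ni", Cv, ev)
        sig = np.zeros_like(epsf)
        sig[:, 0, 0], sig[:, 1, 1], sig[:, 2, 2] = sv[:, 0], sv[:, 1], sv[:, 2]
        sig[:, 1, 2] = sig[:, 2, 1] = sv[:, 3]
        sig[:, 0, 2] = sig[:, 2, 0] = sv[:, 4]
        sig[:, 0, 1] = sig[:, 1, 0] = sv[:, 5]
        return sig.reshape(shp + (3, 3)), np.full(shp, np.nan)
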