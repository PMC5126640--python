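"""Closed-form poroelastic benchmark solutions.

One-dimensional confined-compression consolidation of a fluid-saturated
poroelastic column (drained at the loaded top, sealed and rigid at the
bottom, laterally confined) under ramp-and-hold loading. The series
solution for a step load

    p(zeta, t) = q0 * sum_m (2 / M_m) sin(M_m zeta) exp(-M_m^2 T)
    w(t)      = (q0 H / E_oed) * (1 - sum_m (2 / M_m^2) exp(-M_m^2 T))

with M_m = pi (2m + 1) / 2, zeta the normalized distance from the
drained face, T = c t / H^2 and c = k E_oed the consolidation
coefficient (E_oed = K + 4G/3), extends to ramp loading by Duhamel
superposition, which is carried out analytically below.
"""
from __future__ import annotations

import numpy as np


def consolidation_coefficient(k_mm4_per_Ns: float, G_MPa: float, K_MPa: float) -> float:
    return k_mm4_per_Ns * (K_MPa + 4.0 * G_MPa / 3.0)


def _ramp_kernel(a: np.ndarray, t: float, t0: float):
    """integral_0^min(t,t0) exp(-a (t - tau)) dtau / t0  (vectorized in a)."""
    s = min(t, t0)
    with np.errstate(over="ignore"):
        out = (np.exp(-a * (t - s)) - np.exp(-a * t)) / (a * t0)
    return out


def terzaghi_ramp_hold(z_from_drained, t, H_mm, q0_MPa, t_ramp_s,
                       k_mm4_per_Ns, G_MPa, K_MPa, n_terms: int = 200):
    """Pore pressure and settlement under ramp-to-q0-then-hold loading.

    ``z_from_drained`` are distances from the drained (loaded) face in mm;
    returns (p (n_z,), settlement (scalar, positive shortening in mm)) at
    time ``t``.
    """
    Eoed = K_MPa + 4.0 * G_MPa / 3.0
    c = k_mm4_per_Ns * Eoed
    zeta = np.asarray(z_from_drained, dtype=float) / H_mm
    m = np.arange(n_terms)
    M = 0.5 * np.pi * (2 * m + 1)
    a = (M**2) * c / H_mm**2
    ker = _ramp_kernel(a, float(t), t_ramp_s)  # (n_terms,)
    p = q0_MPa * np.einsum("m,zm->z", 2.0 / M * ker, np.sin(np.outer(zeta, M)))
    q_now = q0_MPa * min(t / t_ramp_s, 1.0)
    w = (H_mm / Eoed) * (q_now - q0_MPa * np.sum(2.0 / M**2 * ker))
    return p, w


def terzaghi_history(z_from_drained, times, **kw):
    """Vectorized history: returns (p (n_t, n_z), w (n_t,))."""
    ps, ws = [], []
    for t in np.asarray(times, dtype=float):
        p, w = terzaghi_ramp_hold(z_from_drained, t, **kw)
        ps.append(p)
        ws.append(w)
    return np.array(ps), np.array(ws)
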