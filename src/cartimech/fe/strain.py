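"""Strain measures extracted from solved states.

The analysis works on principal logarithmic (Hencky) strains — the
minimum principal strain is the largest compressive strain — plus the
maximum engineering shear strain, defined as the spread between the
largest and smallest principal strains, axial/lateral strain components,
and the primary-fibril engineering strain carried by the State.
"""
from __future__ import annotations

import numpy as np


def log_strain_from_F(F: np.ndarray) -> np.ndarray:
    """Spatial logarithmic strain 0.5 ln(F F^T), vectorized over (..., 3, 3)."""
    b = F @ np.swapaxes(F, -1, -2)
    w, V = np.linalg.eigh(b)
    lw = 0.5 * np.log(np.maximum(w, 1e-300))
    return np.einsum("...ik,...k,...jk->...ij", V, lw, V)


def strain_measures(strain_tensor: np.ndarray, fibril_strain=None,
                    loading_axis: int = 2, lateral_axis: int = 0) -> dict:
    """Scalar strain measures from (a field of) symmetric strain tensors.

    Returns principal log strains sorted descending, the maximum
    engineering shear strain e1 - e3, and the axial/lateral normal
    components (loading axis z, stated in-plane axis x by default).
    """
    eps = np.asarray(strain_tensor, dtype=float)
    single = eps.ndim == 2
    eps = eps.reshape(-1, 3, 3)
    if np.max(np.abs(eps - np.swapaxes(eps, -1, -2))) > 1e-10 * max(1.0, np.max(np.abs(eps))):
        raise ValueError("strain tensor must be symmetric")
    w = np.linalg.eigvalsh(eps)  # ascending
    principal = w[:, ::-1]
    out = {
        "principal_log_strains": principal,
        "max_principal_strain": principal[:, 0],
        "min_principal_strain": principal[:, 2],
        "max_shear_engineering": principal[:, 0] - principal[:, 2],
        "axial_strain": eps[:, loading_axis, loading_axis],
        "lateral_strain": eps[:, lateral_axis, lateral_axis],
    }
    if fibril_strain is not None:
        out["fibril_strain"] = np.atleast_1d(np.asarray(fibril_strain, dtype=float))
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


def state_fields(state) -> dict:
    """Failure-analysis parameter fields of one State (per Gauss point)."""
    m = strain_measures(state.strain, state.fibril_strain)
    sp = np.linalg.eigvalsh(state.stress_eff)[:, -1]
    return {
        "max_principal_stress": sp,
        "fibril_strain": np.nan_to_num(m["fibril_strain"], nan=0.0),
        "max_principal_strain": m["max_principal_strain"],
        "min_principal_strain": m["min_principal_strain"],
        "shear_strain": m["max_shear_engineering"],
    }


def history_fields(states) -> dict:
    """Stack per-state parameter fields into (n_t, n_pts) arrays."""
    per_state = [state_fields(s) for s in states]
    return {k: np.stack([f[k] for f in per_state]) for k in per_state[0]}
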