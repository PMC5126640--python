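"""Failure analysis of cartilage state histories.

Five criteria flag potentially damaging tissue states, each against a
literature failure limit: maximum principal (tensile) effective stress
above 7 MPa (collagen matrix degeneration), primary collagen fibril
strain above 8 % (collagen-network damage), maximum principal logarithmic
strain above 30 % (matrix failure in tension), minimum principal
logarithmic strain below -30 % (chondrocyte apoptosis) and maximum
engineering shear strain above 32 % (collagen cross-link failure).
Inequalities are strict, so exactly-at-threshold states are not flagged
and load-scaling bisection over the flag boundary is well defined.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CRITERIA = (
    "max_principal_stress",
    "fibril_strain",
    "max_principal_strain",
    "min_principal_strain",
    "shear_strain",
)


@dataclass
class FailureThresholds:
    """Failure limits; defaults are the literature values used in the
    stance-phase risk analysis."""

    max_principal_stress_MPa: float = 7.0
    fibril_strain: float = 0.08
    max_principal_strain: float = 0.30
    min_principal_strain: float = -0.30
    shear_strain: float = 0.32

    def __post_init__(self):
        if self.max_principal_stress_MPa <= 0:
            raise ValueError("stress threshold must be positive")
        if self.min_principal_strain >= 0:
            raise ValueError("compressive strain threshold must be negative")
        if min(self.fibril_strain, self.max_principal_strain, self.shear_strain) <= 0:
            raise ValueError("strain thresholds must be positive")

    def limit(self, criterion: str) -> float:
        return {
            "max_principal_stress": self.max_principal_stress_MPa,
            "fibril_strain": self.fibril_strain,
            "max_principal_strain": self.max_principal_strain,
            "min_principal_strain": self.min_principal_strain,
            "shear_strain": self.shear_strain,
        }[criterion]


@dataclass
class FailureReport:
    """Per-criterion exceedance masks and ROI summaries for one scenario."""

    label: str
    stance_pct: np.ndarray
    masks: dict = field(default_factory=dict)  # criterion -> (n_t, n_pts) bool
    roi_series: dict = field(default_factory=dict)  # parameter -> (n_t,) float
    exceedance_intervals: dict = field(default_factory=dict)  # criterion -> [[s0, s1], ...]
    fold_change: dict = field(default_factory=dict)  # parameter -> (n_t,) float
    provenance: dict = field(default_factory=dict)

    def peak(self, parameter: str) -> float:
        s = np.asarray(self.roi_series[parameter])
        return float(s[np.argmax(np.abs(s))])

    def exceedance_pct(self, criterion: str) -> float:
        return float(sum(b - a for a, b in self.exceedance_intervals.get(criterion, [])))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "stance_pct": np.asarray(self.stance_pct).tolist(),
            "roi_series": {k: np.asarray(v).tolist() for k, v in self.roi_series.items()},
            "exceedance_intervals": {k: [list(map(float, ab)) for ab in v]
                                     for k, v in self.exceedance_intervals.items()},
            "fold_change": {k: np.asarray(v).tolist() for k, v in self.fold_change.items()},
            "provenance": self.provenance,
        }


def _required(fields: dict, name: str) -> np.ndarray:
    if name not in fields:
        raise ValueError(f"missing field '{name}' in state")
    return np.asarray(fields[name])


def classify_failure(state_fields: dict, thresholds: FailureThresholds) -> dict:
    """Boolean per-point masks for the five criteria.

    ``state_fields`` maps parameter names (as in :data:`CRITERIA`) to
    per-point values. Strict inequalities; the compressive criterion flags
    values below its (negative) limit.
    """
    out = {}
    out["max_principal_stress"] = _required(state_fields, "max_principal_stress") > thresholds.max_principal_stress_MPa
    out["fibril_strain"] = _required(state_fields, "fibril_strain") > thresholds.fibril_strain
    out["max_principal_strain"] = _required(state_fields, "max_principal_strain") > thresholds.max_principal_strain
    out["min_principal_strain"] = _required(state_fields, "min_principal_strain") < thresholds.min_principal_strain
    out["shear_strain"] = _required(state_fields, "shear_strain") > thresholds.shear_strain
    return out


def roi_membership(point_coords: np.ndarray, rim_coords: np.ndarray, radius_mm: float = 1.0) -> np.ndarray:
    """Points within ``radius_mm`` of the nearest rim node (reference
    configuration, computed once)."""
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    d2 = np.min(
        np.sum((point_coords[:, None, :] - rim_coords[None, :, :]) ** 2, axis=-1), axis=1
    )
    return d2 <= radius_mm**2


def roi_max_series(history_fields: dict, point_coords: np.ndarray,
                   rim_coords: np.ndarray, radius_mm: float = 1.0) -> dict:
    """Per-parameter extremum time series over the defect-rim ROI.

    ``history_fields`` maps parameter names to (n_t, n_pts) arrays. For
    ``min_principal_strain`` the minimum (most compressive) value is
    tracked; for every other parameter the maximum.
    """
    mask = roi_membership(point_coords, rim_coords, radius_mm)
    if not mask.any():
        raise ValueError("empty ROI: no integration point within radius of the rim")
    out = {}
    for name, arr in history_fields.items():
        arr = np.asarray(arr)[:, mask]
        out[name] = arr.min(axis=1) if name == "min_principal_strain" else arr.max(axis=1)
    return out


def exceedance_intervals(series, threshold: float, stance_pct, compressive: bool = False):
    """Maximal contiguous stance intervals where the series violates the
    threshold (series < threshold when ``compressive``, > otherwise);
    crossing points are linearly interpolated between samples."""
    s = np.asarray(series, dtype=float)
    q = np.asarray(stance_pct, dtype=float)
    if len(s) != len(q):
        raise ValueError("series and stance_pct must have equal length")
    if np.any(np.diff(q) <= 0):
        raise ValueError("stance_pct must be strictly increasing")
    over = (s < threshold) if compressive else (s > threshold)
    intervals = []
    i = 0
    n = len(s)
    while i < n:
        if not over[i]:
            i += 1
            continue
        # interval start
        if i == 0:
            a = q[0]
        else:
            f = (threshold - s[i - 1]) / (s[i] - s[i - 1])
            a = q[i - 1] + f * (q[i] - q[i - 1])
        j = i
        while j + 1 < n and over[j + 1]:
            j += 1
        if j == n - 1:
            b = q[-1]
        else:
            f = (threshold - s[j]) / (s[j + 1] - s[j])
            b = q[j] + f * (q[j + 1] - q[j])
        intervals.append([float(a), float(b)])
        i = j + 1
    return intervals


def compare_scenarios(intact_fields: dict, damaged_fields: dict,
                      strain_floor: float = 1e-4) -> tuple[dict, dict]:
    """Damaged-minus-intact difference fields and fold-change series.

    Both field dicts map parameter names to (n_t, n_pts) arrays on a
    shared evaluation grid. Fold change at each time is the ratio of the
    damaged extremum magnitude to the co-located intact magnitude;
    locations where the intact magnitude is below ``strain_floor`` are
    masked out of the fold-change (NaN if nothing remains).
    """
    diffs, folds = {}, {}
    for name, dmg in damaged_fields.items():
        if name not in intact_fields:
            continue
        dmg = np.asarray(dmg, dtype=float)
        ref = np.asarray(intact_fields[name], dtype=float)
        if dmg.shape != ref.shape:
            raise ValueError(f"incompatible time grids for '{name}': {dmg.shape} vs {ref.shape}")
        diffs[name] = dmg - ref
        n_t = dmg.shape[0]
        fc = np.full(n_t, np.nan)
        for it in range(n_t):
            valid = np.abs(ref[it]) >= strain_floor
            if not valid.any():
                continue
            k = np.argmax(np.abs(dmg[it]) * valid)
            if valid[k]:
                fc[it] = abs(dmg[it][k]) / abs(ref[it][k])
        folds[name] = fc
    return diffs, folds


def max_difference_location(diff_field: np.ndarray, point_coords: np.ndarray, stance_pct):
    """Location and stance percentage of the largest absolute difference."""
    diff_field = np.asarray(diff_field)
    it, ip = np.unravel_index(np.argmax(np.abs(diff_field)), diff_field.shape)
    return {
        "stance_pct": float(np.asarray(stance_pct)[it]),
        "location_mm": point_coords[ip].tolist(),
        "value": float(diff_field[it, ip]),
    }
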