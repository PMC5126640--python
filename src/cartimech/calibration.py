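"""CT-side computations.

Hounsfield-unit volumes are calibrated to volumetric bone mineral density
(vBMD, mg hydroxyapatite per cm^3) through the mean intensities of
density-phantom regions of interest, converted to Young's moduli through a
literature density-elasticity power law E = a * rho^b (rho in g/cm^3), and
mapped onto finite elements by Gaussian quadrature of the continuum
modulus field over each element volume. Otsu's method separates material
classes on intensity histograms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class HUVolume:
    """3-D CT-like scalar volume with phantom annotations.

    ``phantom_labels`` is an integer label image (0 = background, i >= 1 =
    phantom i) aligned with ``data``; ``phantom_densities[i-1]`` is the true
    vBMD of phantom i in mg/cm^3.
    """

    data: np.ndarray
    voxel_size_mm: float = 0.2
    phantom_labels: np.ndarray | None = None
    phantom_densities: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        self.data = np.asarray(self.data, dtype=float)

    def roi_means(self) -> np.ndarray:
        if self.phantom_labels is None:
            raise ValueError("volume has no phantom ROI masks")
        n = int(self.phantom_labels.max())
        return np.array([self.data[self.phantom_labels == i].mean() for i in range(1, n + 1)])

    def to_nifti(self, path) -> None:
        import nibabel as nib

        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), aff), str(path))
        if self.phantom_labels is not None:
            p = str(path)
            stem = p[: -len(".nii.gz")] if p.endswith(".nii.gz") else p.rsplit(".", 1)[0]
            nib.save(nib.Nifti1Image(self.phantom_labels.astype(np.int16), aff), stem + "_labels.nii.gz")


# density-elasticity literature presets: E(MPa) = a * rho^b, rho in g/cm^3
DENSITY_ELASTICITY_PRESETS = {
    "trabecular_power": {"a_MPa": 6850.0, "b": 1.49},
    "cortical_power": {"a_MPa": 10200.0, "b": 2.01},
}


@dataclass
class CalibrationCurve:
    """HU -> vBMD affine calibration plus density -> modulus power law."""

    slope_mg_cm3_per_hu: float
    intercept_mg_cm3: float
    r_squared: float = 1.0
    residuals_mg_cm3: np.ndarray | None = None
    a_MPa: float = DENSITY_ELASTICITY_PRESETS["trabecular_power"]["a_MPa"]
    b: float = DENSITY_ELASTICITY_PRESETS["trabecular_power"]["b"]
    density_units: str = "mg/cm^3"

    def __post_init__(self):
        if self.slope_mg_cm3_per_hu <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")
        if self.a_MPa <= 0:
            raise ValueError("power-law coefficient a must be positive")

    def hu_to_density(self, hu):
        return self.slope_mg_cm3_per_hu * np.asarray(hu, dtype=float) + self.intercept_mg_cm3


def otsu_threshold(histogram) -> float:
    """Otsu's threshold for an intensity histogram.

    ``histogram`` is either a (counts, bin_centers) pair or a 1-D array of
    raw intensities (histogrammed over its unique values). Returns the bin
    center maximizing the between-class variance; ties break toward the
    lower threshold. The search is exhaustive over all candidate splits.
    """
    if isinstance(histogram, tuple):
        counts, centers = (np.asarray(a, dtype=float) for a in histogram)
    else:
        vals = np.asarray(histogram, dtype=float).ravel()
        if vals.size == 0:
            raise ValueError("empty histogram")
        centers, cts = np.unique(vals, return_counts=True)
        counts = cts.astype(float)
    if len(centers) < 2 or np.count_nonzero(counts) < 2:
        raise ValueError("need at least 2 distinct intensity values")
    order = np.argsort(centers)
    centers, counts = centers[order], counts[order]
    w = counts / counts.sum()
    mu = np.cumsum(w * centers)
    omega = np.cumsum(w)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-np.inf)
    k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    # report the class boundary: midpoint of the optimal split
    return float(0.5 * (centers[k] + centers[k + 1]))


def fit_hu_vbmd(volume: HUVolume, weight_by_voxels: bool = False, **power_law) -> CalibrationCurve:
    """Ordinary least squares of true phantom density on ROI mean HU."""
    if volume.phantom_densities is None or volume.phantom_labels is None:
        raise ValueError("volume carries no phantom annotations")
    hu = volume.roi_means()
    rho = np.asarray(volume.phantom_densities, dtype=float)
    if np.ptp(hu) < 1e-12:
        raise ValueError("rank-deficient calibration: phantom ROI means are identical")
    X = np.column_stack([hu, np.ones_like(hu)])
    if weight_by_voxels:
        n = np.array([(volume.phantom_labels == i).sum() for i in range(1, len(rho) + 1)], dtype=float)
        sw = np.sqrt(n)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], rho * sw, rcond=None)
    else:
        beta, *_ = np.linalg.lstsq(X, rho, rcond=None)
    resid = rho - X @ beta
    ss_tot = np.sum((rho - rho.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
    return CalibrationCurve(
        slope_mg_cm3_per_hu=float(beta[0]), intercept_mg_cm3=float(beta[1]),
        r_squared=float(np.clip(r2, 0.0, 1.0)), residuals_mg_cm3=resid, **power_law,
    )


def density_to_modulus(vbmd_mg_cm3, curve: CalibrationCurve):
    """Young's modulus E = a * rho^b (MPa), rho = vBMD in g/cm^3.

    Negative calibrated densities are clamped to zero (count logged).
    """
    rho = np.asarray(vbmd_mg_cm3, dtype=float) / 1000.0  # mg/cm^3 -> g/cm^3
    n_neg = int(np.sum(rho < 0))
    if n_neg:
        log.info("density_to_modulus: clamped %d negative densities to 0", n_neg)
    rho = np.maximum(rho, 0.0)
    out = curve.a_MPa * rho**curve.b
    return float(out) if np.isscalar(vbmd_mg_cm3) else out


def gauss_legendre_3d(order: int):
    """Tensor-product Gauss-Legendre points/weights on [-1, 1]^3."""
    x, w = np.polynomial.legendre.leggauss(order)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    W = np.einsum("i,j,k->ijk", w, w, w)
    return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()]), W.ravel()


def map_modulus_to_elements(field_fn, mesh, quadrature_order: int = 2) -> np.ndarray:
    """Volume-average a continuum modulus field over every element.

    ``field_fn(points (n,3)) -> (n,)`` must be evaluable anywhere inside
    the mesh. The per-element value is the Gauss-quadrature approximation
    of (1/V_e) * integral(E dV); integral conservation sum(E_e V_e) vs the
    quadrature of the field is exact by construction, so total stiffness
    content is preserved.
    """
    from .meshes import hex_shape, hex_shape_grad

    xi, w = gauss_legendre_3d(quadrature_order)
    N = hex_shape(xi)  # (q, 8)
    dN = hex_shape_grad(xi)  # (q, 8, 3)
    xe = mesh.points[mesh.cells]  # (e, 8, 3)
    gp = np.einsum("qa,ean->eqn", N, xe)
    J = np.einsum("qam,ean->eqnm", dN, xe)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = np.unique(np.nonzero(detJ <= 0)[0])
        raise ValueError(f"non-positive Jacobian in element(s) {bad[:10].tolist()}")
    vals = np.asarray(field_fn(gp.reshape(-1, 3)), dtype=float)
    if np.any(~np.isfinite(vals)):
        bad = np.unique(np.nonzero(~np.isfinite(vals.reshape(detJ.shape)))[0])
        raise ValueError(f"modulus field not evaluable inside element(s) {bad[:10].tolist()}")
    vals = vals.reshape(detJ.shape)
    V = np.einsum("eq,q->e", detJ, w)
    return np.einsum("eq,eq,q->e", vals, detJ, w) / V
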