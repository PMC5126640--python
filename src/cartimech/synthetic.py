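"""Synthetic study fixtures.

Everything the analysis pipeline consumes can be generated here without
any external data: an idealized tibial-compartment cartilage layer with a
spatially varying thickness profile and split-line field, a rigid
spherical femoral-condyle surrogate, an optional meniscus wedge with horn
attachment node sets, a two-peak stance-phase axial load waveform scaled
by body weight, a CT-like volume with density-calibration phantoms, and
parametric defect footprints.

All generators are pure functions of (spec, seed); units are mm, N, MPa, s.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import HUVolume
from .defects import DefectSpec, polygon_area
from .meshes import SurfaceMesh, VolumeMesh, structured_hex_grid

GRAVITY_M_PER_S2 = 9.81


# --------------------------------------------------------------------------
# compartment
# --------------------------------------------------------------------------
@dataclass
class ThicknessProfile:
    """Analytic cartilage thickness t(x, y) = base + g.(x, y) + bump."""

    base_mm: float = 2.2
    gradient_mm_per_mm: tuple = (0.0, 0.0)
    bump_amplitude_mm: float = 0.0
    bump_sigma_mm: float = 5.0

    def __call__(self, x, y):
        gx, gy = self.gradient_mm_per_mm
        t = self.base_mm + gx * np.asarray(x) + gy * np.asarray(y)
        if self.bump_amplitude_mm:
            t = t + self.bump_amplitude_mm * np.exp(
                -(np.asarray(x) ** 2 + np.asarray(y) ** 2) / (2 * self.bump_sigma_mm**2)
            )
        return t


@dataclass
class CompartmentSpec:
    """Idealized medial-tibial-compartment geometry.

    The articular surface is a shallow concave dish of radius
    ``surface_curvature_radius_mm``; the femoral side is represented by a
    rigid analytic sphere (``indenter_radius_mm``). Default element size
    follows the tibial-cartilage global-model density (~1.0 mm); at least
    four element layers span the thickness.
    """

    plateau_extent_mm: tuple = (16.0, 16.0)  # anterior-posterior, medial-lateral
    thickness_profile: ThicknessProfile = field(default_factory=ThicknessProfile)
    surface_curvature_radius_mm: float = 100.0
    meniscus_enabled: bool = False
    indenter_radius_mm: float = 35.0
    target_element_size_mm: float = 1.0
    min_layers: int = 4
    split_line_swirl_deg: float = 0.0
    seed: int = 0

    def validate(self):
        if min(self.plateau_extent_mm) <= 0:
            raise ValueError("plateau extents must be positive")
        if self.target_element_size_mm <= 0:
            raise ValueError("element size must be positive")
        Lx, Ly = self.plateau_extent_mm
        xs = np.linspace(-Lx / 2, Lx / 2, 41)
        ys = np.linspace(-Ly / 2, Ly / 2, 41)
        T = self.thickness_profile(*np.meshgrid(xs, ys, indexing="ij"))
        if T.min() <= 0.5 or T.max() >= 6.0:
            raise ValueError(
                f"thickness must stay within (0.5, 6.0) mm; got "
                f"[{T.min():.2f}, {T.max():.2f}]"
            )
        if self.target_element_size_mm > T.min():
            raise ValueError(
                f"element size {self.target_element_size_mm} mm exceeds minimum "
                f"thickness {T.min():.2f} mm; refine the mesh"
            )


@dataclass
class Indenter:
    """Rigid spherical femoral-condyle surrogate (analytic contact surface)."""

    center: np.ndarray
    radius_mm: float
    surface: SurfaceMesh | None = None


@dataclass
class Compartment:
    """A generated compartment: meshes plus the analytic fields that
    produced them (used by carving, relocation and the arcade builder)."""

    spec: CompartmentSpec
    cartilage: VolumeMesh
    intact_surface: SurfaceMesh
    thickness: np.ndarray
    split_lines: np.ndarray
    indenter: Indenter
    meniscus: VolumeMesh | None = None
    horn_attachments: dict | None = None
    bounds_override: tuple | None = None  # sub-region plan bounds (submodels)

    def z_top_at(self, x, y):
        R = self.spec.surface_curvature_radius_mm
        return (np.asarray(x) ** 2 + np.asarray(y) ** 2) / (2.0 * R)

    def thickness_at(self, x, y):
        return self.spec.thickness_profile(x, y)

    def normal_at(self, x, y):
        R = self.spec.surface_curvature_radius_mm
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        n = np.column_stack([-x / R, -y / R, np.ones_like(x)])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def split_line_at(self, x, y):
        """Unit surface tangent field; anterior-posterior by default with a
        configurable swirl about the surface normal."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        n = self.normal_at(x, y)
        ex = np.zeros((len(x), 3))
        ex[:, 0] = 1.0
        t = ex - np.einsum("ij,ij->i", ex, n)[:, None] * n
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        sw = np.deg2rad(self.spec.split_line_swirl_deg)
        if sw:
            Lx, Ly = self.spec.plateau_extent_mm
            r = np.sqrt(x**2 + y**2) / (0.5 * min(Lx, Ly))
            ang = sw * r
            b = np.cross(n, t)
            t = np.cos(ang)[:, None] * t + np.sin(ang)[:, None] * b
            t /= np.linalg.norm(t, axis=1, keepdims=True)
        return t

    def plan_bounds(self):
        if self.bounds_override is not None:
            return self.bounds_override
        Lx, Ly = self.spec.plateau_extent_mm
        return ((-Lx / 2, Lx / 2), (-Ly / 2, Ly / 2))


def layer_fractions(thickness_mm: float, element_size_mm: float,
                    min_layers: int = 4, superficial_fraction: float = 0.15):
    """Normalized layer-interface fractions (0 = bone, 1 = surface).

    The superficial zone — where the arcade turns tangential and the
    steepest through-thickness stress gradients live — is meshed at one
    third of the nominal element size; the middle/deep zones at the
    nominal size.
    """
    h = element_size_mm
    n_sup = max(1, round(superficial_fraction * thickness_mm / (h / 3.0)))
    n_rest = max(min_layers - 1, round((1 - superficial_fraction) * thickness_mm / h))
    lower = np.linspace(0.0, 1.0 - superficial_fraction, n_rest + 1)
    upper = np.linspace(1.0 - superficial_fraction, 1.0, n_sup + 1)
    return np.concatenate([lower[:-1], upper])


class _LayerField:
    """Maps a layer-interface index to nodal z over the plan grid."""

    def __init__(self, comp_like, fractions):
        self.c = comp_like
        self.fractions = np.asarray(fractions, dtype=float)
        self.n_layers = len(self.fractions) - 1

    def __call__(self, X, Y, k):
        zt = self.c.z_top_at(X, Y)
        t = self.c.thickness_at(X, Y)
        return zt - t * (1.0 - self.fractions[k])


def _sphere_surface(center, radius, n=24) -> SurfaceMesh:
    th = np.linspace(0, np.pi, n)
    ph = np.linspace(0, 2 * np.pi, 2 * n, endpoint=False)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    pts = center + radius * np.column_stack(
        [(np.sin(TH) * np.cos(PH)).ravel(), (np.sin(TH) * np.sin(PH)).ravel(), np.cos(TH).ravel()]
    )
    faces = []
    for i in range(n - 1):
        for j in range(2 * n):
            a = i * 2 * n + j
            b = i * 2 * n + (j + 1) % (2 * n)
            faces.append([a, b, b + 2 * n, a + 2 * n])
    return SurfaceMesh(points=pts, faces=np.array(faces, dtype=int))


def _make_meniscus(spec: CompartmentSpec, comp: Compartment):
    """Partial annulus wedge resting on the plateau periphery; its only
    mechanical coupling to the tibia is through the horn springs."""
    Lx, Ly = spec.plateau_extent_mm
    r_in, r_out = 0.30 * min(Lx, Ly), 0.48 * min(Lx, Ly)
    h = spec.target_element_size_mm * 0.8  # meniscus element density ~0.8x
    n_r = max(2, round((r_out - r_in) / h))
    n_th = max(8, round(np.pi * (r_in + r_out) / 2 / h))
    n_z = 2
    th = np.linspace(0.25 * np.pi, 1.75 * np.pi, n_th + 1)  # C-shape, gap anterior
    rr = np.linspace(r_in, r_out, n_r + 1)
    height_out, height_in = 3.0, 1.0  # wedge cross-section, mm

    pts = []
    for k in range(n_z + 1):
        for i, r in enumerate(rr):
            hgt = height_in + (height_out - height_in) * (r - r_in) / (r_out - r_in)
            x = r * np.cos(th)
            y = r * np.sin(th)
            z0 = comp.z_top_at(x, y)
            pts.append(np.column_stack([x, y, z0 + hgt * k / n_z]))
    pts = np.vstack(pts)
    npl = (n_r + 1) * (n_th + 1)

    def nid(i, j, k):
        return k * npl + i * (n_th + 1) + j

    cells = []
    for k in range(n_z):
        for i in range(n_r):
            for j in range(n_th):
                cells.append(
                    [nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                     nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1)]
                )
    mesh = VolumeMesh(points=pts, cells=np.array(cells, dtype=int))
    ii, kk = np.meshgrid(np.arange(n_r + 1), np.arange(n_z + 1), indexing="ij")
    horn_a = nid(ii, 0, kk).ravel()
    horn_b = nid(ii, n_th, kk).ravel()
    mesh.node_sets["anterior_horn"] = horn_a
    mesh.node_sets["posterior_horn"] = horn_b
    return mesh, {"anterior_horn": horn_a, "posterior_horn": horn_b}


def make_compartment(spec: CompartmentSpec) -> Compartment:
    """Generate the idealized compartment: layered hex cartilage mesh,
    intact articular surface, thickness and split-line vertex fields, the
    rigid spherical indenter and (optionally) the meniscus wedge."""
    spec.validate()
    Lx, Ly = spec.plateau_extent_mm
    h = spec.target_element_size_mm
    nx = max(2, round(Lx / h))
    ny = max(2, round(Ly / h))
    x = np.linspace(-Lx / 2, Lx / 2, nx + 1)
    y = np.linspace(-Ly / 2, Ly / 2, ny + 1)

    comp = Compartment(
        spec=spec, cartilage=None, intact_surface=None, thickness=None,
        split_lines=None, indenter=None,
    )
    t_mean = float(np.mean(spec.thickness_profile(*np.meshgrid(x, y, indexing="ij"))))
    fractions = layer_fractions(t_mean, h, min_layers=spec.min_layers)
    mesh = structured_hex_grid(x, y, _LayerField(comp, fractions))
    mesh.meta["layer_fractions"] = fractions
    comp.cartilage = mesh

    surf = mesh.extract_surface(mesh.face_sets["articular_surface"])
    X, Y = np.meshgrid(x, y, indexing="ij")
    # the extracted surface points coincide with the top structured layer;
    # rebuild as an explicit heightfield for downstream reconstruction
    sp_pts = np.column_stack([X.ravel(), Y.ravel(), comp.z_top_at(X.ravel(), Y.ravel())])
    faces = []
    for i in range(nx):
        for j in range(ny):
            a = i * (ny + 1) + j
            faces.append([a, a + (ny + 1), a + (ny + 1) + 1, a + 1])
    surf = SurfaceMesh(points=sp_pts, faces=np.array(faces, dtype=int), grid_shape=(nx + 1, ny + 1))

    thickness = spec.thickness_profile(sp_pts[:, 0], sp_pts[:, 1])
    split = comp.split_line_at(sp_pts[:, 0], sp_pts[:, 1])
    surf.point_data["thickness"] = thickness
    surf.point_data["split_line"] = split
    comp.intact_surface = surf
    comp.thickness = thickness
    comp.split_lines = split

    zc = comp.z_top_at(0.0, 0.0) + spec.indenter_radius_mm
    center = np.array([0.0, 0.0, float(np.atleast_1d(zc)[0])])
    comp.indenter = Indenter(
        center=center, radius_mm=spec.indenter_radius_mm,
        surface=_sphere_surface(center, spec.indenter_radius_mm),
    )
    if spec.meniscus_enabled:
        comp.meniscus, comp.horn_attachments = _make_meniscus(spec, comp)

    if mesh.min_scaled_jacobian() <= 0:
        raise RuntimeError("generated mesh contains inverted elements")
    return comp


# --------------------------------------------------------------------------
# gait protocol
# --------------------------------------------------------------------------
@dataclass
class GaitSpec:
    """Two-peak stance-phase axial loading scaled by body weight.

    Defaults: 71 kg subject, load peaks of 2.2x and 2.6x body weight at
    15 % and 85 % of stance (typical instrumented-knee axial force), a
    0.6 s stance sampled at 101 points.
    """

    body_mass_kg: float = 71.0
    peak_multiples_of_bw: tuple = (2.2, 2.6)
    peak_times_pct_stance: tuple = (15.0, 85.0)
    n_time_points: int = 101
    stance_duration_s: float = 0.6
    # Gaussian bump width; narrow enough that the waveform decays below
    # 5 % of the first peak at 0 and 100 % stance for peak ratios <= 2
    peak_width_pct: float = 5.5

    def validate(self):
        t1, t2 = self.peak_times_pct_stance
        if not (0 < t1 < t2 < 100):
            raise ValueError("peak times must be strictly increasing within (0, 100)")
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")
        if self.n_time_points < 3:
            raise ValueError("need at least 3 time points")


@dataclass
class LoadProtocol:
    times_s: np.ndarray
    stance_pct: np.ndarray
    axial_force_N: np.ndarray
    flexion_deg: np.ndarray

    def __post_init__(self):
        n = len(self.times_s)
        if not (len(self.stance_pct) == len(self.axial_force_N) == len(self.flexion_deg) == n):
            raise ValueError("protocol vectors must have equal length")
        if np.any(self.axial_force_N < 0):
            raise ValueError("axial force must be non-negative")

    def scaled(self, factor: float) -> "LoadProtocol":
        return LoadProtocol(self.times_s.copy(), self.stance_pct.copy(),
                            self.axial_force_N * factor, self.flexion_deg.copy())


def make_gait_protocol(spec: GaitSpec) -> LoadProtocol:
    """Smooth two-peak stance waveform: a sum of two Gaussian bumps whose
    amplitudes are solved so the force at each configured peak time equals
    peak_multiple x m x g exactly."""
    spec.validate()
    s = np.linspace(0.0, 100.0, spec.n_time_points)
    t1, t2 = spec.peak_times_pct_stance
    sig = spec.peak_width_pct
    g1 = lambda q: np.exp(-((q - t1) ** 2) / (2 * sig**2))
    g2 = lambda q: np.exp(-((q - t2) ** 2) / (2 * sig**2))
    bw = spec.body_mass_kg * GRAVITY_M_PER_S2
    targets = np.array(spec.peak_multiples_of_bw) * bw
    M = np.array([[g1(t1), g2(t1)], [g1(t2), g2(t2)]])
    A = np.linalg.solve(M, targets)
    force = A[0] * g1(s) + A[1] * g2(s)
    force = np.maximum(force, 0.0)
    # stance-phase knee flexion stand-in: early-stance flexion wave plus
    # pre-swing flexion onset (metadata; not printed gait data)
    flexion = 20.0 * np.exp(-((s - 15.0) / 12.0) ** 2) + 40.0 * np.exp(-((s - 105.0) / 20.0) ** 2)
    times = s / 100.0 * spec.stance_duration_s
    return LoadProtocol(times_s=times, stance_pct=s, axial_force_N=force, flexion_deg=flexion)


# --------------------------------------------------------------------------
# CT phantom volume
# --------------------------------------------------------------------------
def make_ct_volume(
    phantom_densities,
    noise_sd: float,
    seed: int,
    slope_hu_per_density: float = 1.0,
    intercept_hu: float = 0.0,
    voxel_size_mm: float = 0.2,
    shape: tuple = (80, 40, 24),
    phantom_radius_vox: int = 6,
) -> HUVolume:
    """CT-like volume containing one cylindrical density phantom per entry.

    Mean ROI intensity is affine in the true volumetric bone mineral
    density (mg/cm^3) with additive Gaussian voxel noise. ROI label masks
    and the true densities travel with the volume.
    """
    dens = np.asarray(phantom_densities, dtype=float)
    if len(np.unique(dens)) < 2:
        raise ValueError("need at least 2 distinct phantom densities")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    vol = np.full(shape, intercept_hu, dtype=float)
    labels = np.zeros(shape, dtype=int)
    nx, ny, nz = shape
    centers = np.linspace(phantom_radius_vox + 2, nx - phantom_radius_vox - 2, len(dens))
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for i, (d, cx) in enumerate(zip(dens, centers), start=1):
        m = (xx - cx) ** 2 + (yy - ny / 2) ** 2 <= phantom_radius_vox**2
        vol[m, :] = slope_hu_per_density * d + intercept_hu
        labels[m, :] = i
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=shape)
    return HUVolume(
        data=vol, voxel_size_mm=voxel_size_mm, phantom_labels=labels,
        phantom_densities=dens,
        meta={"slope_hu_per_density": slope_hu_per_density, "intercept_hu": intercept_hu,
              "units": {"density": "mg/cm^3", "voxel": "mm"}},
    )


# --------------------------------------------------------------------------
# defects
# --------------------------------------------------------------------------
def make_defect(
    footprint_area_mm2: float = 5.2,
    depth_fraction: float = 0.63,
    center=(0.0, 0.0),
    shape: str = "circular",
    seed: int = 0,
    n_vertices: int = 64,
    patch_extent_mm: tuple | None = None,
) -> DefectSpec:
    """Parametric defect footprint scaled to the requested area.

    Defaults reproduce the clinically observed lesion: 5.2 mm^2 footprint
    at 63 % normalized depth (ICRS grade 3). Shapes: ``circular``,
    ``elliptical`` (2:1 aspect) or ``irregular`` (random low-order radial
    harmonics, deterministic in ``seed``).
    """
    if footprint_area_mm2 <= 0:
        raise ValueError("footprint area must be positive")
    if not 0 < depth_fraction <= 1:
        raise ValueError("depth_fraction must lie in (0, 1]")
    th = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    if shape == "circular":
        r = np.ones_like(th)
    elif shape == "elliptical":
        a, b = np.sqrt(2.0), np.sqrt(0.5)
        r = a * b / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)
    elif shape == "irregular":
        rng = np.random.default_rng(seed)
        r = np.ones_like(th)
        for k in (2, 3, 5):
            r = r + rng.uniform(-0.15, 0.15) * np.cos(k * th + rng.uniform(0, 2 * np.pi))
        r = np.maximum(r, 0.3)
    else:
        raise ValueError(f"unknown footprint shape '{shape}'")
    poly = np.column_stack([r * np.cos(th), r * np.sin(th)])
    poly *= np.sqrt(footprint_area_mm2 / polygon_area(poly))
    spec = DefectSpec(
        footprint=poly, depth_fraction=depth_fraction,
        center=np.asarray(center, dtype=float),
        label=f"{shape}_defect_{footprint_area_mm2:g}mm2",
    )
    if patch_extent_mm is not None:
        (x0, x1), (y0, y1) = patch_extent_mm
        w = spec.footprint_world()
        if w[:, 0].min() < x0 or w[:, 0].max() > x1 or w[:, 1].min() < y0 or w[:, 1].max() > y1:
            raise ValueError("footprint extends off the surface patch")
    return spec
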