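import numpy as np
import pytest

from cartimech.defects import (
    DefectGeometry,
    DefectSpec,
    carve_defect,
    defect_drainage_bcs,
    fill_defect_surface,
    normalized_penetration,
    points_in_polygon,
    polygon_area,
    relocate_defect,
    signed_distance_to_polygon,
)
from cartimech.meshes import SurfaceMesh
from cartimech.synthetic import (
    CompartmentSpec,
    ThicknessProfile,
    make_compartment,
    make_defect,
)


@pytest.fixture(scope="module")
def flat_compartment():
    """Constant 2.2 mm slab at 0.5 mm elements (fast carving substrate)."""
    return make_compartment(CompartmentSpec(
        plateau_extent_mm=(14.0, 14.0), target_element_size_mm=0.5,
        surface_curvature_radius_mm=1e6,
    ))


# ---------------------------------------------------------------------------
# polygon kernels against shapely
# ---------------------------------------------------------------------------
def test_polygon_kernels_match_shapely():
    shapely = pytest.importorskip("shapely.geometry")
    rng = np.random.default_rng(2)
    th = np.linspace(0, 2 * np.pi, 17, endpoint=False)
    poly = np.column_stack([(1 + 0.3 * np.cos(3 * th)) * np.cos(th),
                            (1 + 0.3 * np.cos(3 * th)) * np.sin(th)])
    sp = shapely.Polygon(poly)
    assert np.isclose(polygon_area(poly), sp.area, rtol=1e-12)
    pts = rng.uniform(-1.5, 1.5, size=(200, 2))
    ours = points_in_polygon(pts, poly)
    ref = np.array([sp.contains(shapely.Point(*p)) for p in pts])
    assert np.array_equal(ours, ref)
    d_ours = signed_distance_to_polygon(pts, poly)
    d_ref = np.array([sp.exterior.distance(shapely.Point(*p)) for p in pts])
    assert np.allclose(np.abs(d_ours), d_ref, atol=1e-9)
    assert np.array_equal(d_ours > 0, ref)


def test_self_intersecting_footprint_rejected():
    bowtie = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
    with pytest.raises(ValueError, match="self-intersecting"):
        DefectSpec(footprint=bowtie, depth_fraction=0.5, center=np.zeros(2))


# ---------------------------------------------------------------------------
# normalized penetration
# ---------------------------------------------------------------------------
def test_penetration_zero_on_surface_one_at_bone(flat_compartment):
    comp = flat_compartment
    zt = float(comp.z_top_at(1.0, 1.0))
    t = float(comp.thickness_at(1.0, 1.0))
    assert normalized_penetration([1.0, 1.0, zt], comp) == pytest.approx(0.0)
    assert normalized_penetration([1.0, 1.0, zt - t], comp) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="outside"):
        normalized_penetration([1.0, 1.0, zt + 1.0], comp)


def test_default_defects_deepest_node_penetrates_63_percent(flat_compartment):
    comp = flat_compartment
    geo = carve_defect(comp, make_defect(center=(0.0, 0.0)))
    pen = normalized_penetration(geo.mesh.points[geo.defect_surface_nodes], comp)
    assert np.max(pen) == pytest.approx(0.63, abs=1e-9)


# ---------------------------------------------------------------------------
# carving
# ---------------------------------------------------------------------------
def test_removed_volume_matches_prism_estimate(flat_compartment):
    # footprint wide relative to the smoothed wall band, so the prism
    # estimate area x depth x thickness applies
    comp = flat_compartment
    spec = make_defect(footprint_area_mm2=40.0, depth_fraction=0.2, center=(0.0, 0.0))
    geo = carve_defect(comp, spec)
    prism = 40.0 * 0.2 * 2.2
    assert abs(geo.removed_volume_mm3 - prism) / prism < 0.05


def test_removed_volume_vanishes_with_depth(flat_compartment):
    geo = carve_defect(flat_compartment, make_defect(depth_fraction=0.01))
    # prism estimate at 1 % depth is ~0.11 mm^3; continuity toward zero
    assert 0 < geo.removed_volume_mm3 < 0.15


def test_removed_volume_increases_with_depth(flat_compartment):
    vols = [carve_defect(flat_compartment, make_defect(depth_fraction=d)).removed_volume_mm3
            for d in (0.2, 0.4, 0.6, 0.8)]
    assert np.all(np.diff(vols) > 0)


def test_carved_mesh_quality_and_rim_on_intact_surface(flat_compartment):
    comp = flat_compartment
    geo = carve_defect(comp, make_defect())
    assert geo.mesh.min_scaled_jacobian() > 0.1
    rim = geo.mesh.points[geo.rim_nodes]
    assert np.max(np.abs(rim[:, 2] - comp.z_top_at(rim[:, 0], rim[:, 1]))) < 1e-6


def test_footprint_off_patch_rejected_at_carve(flat_compartment):
    spec = make_defect(center=(6.9, 0.0))
    with pytest.raises(ValueError, match="off the surface patch"):
        carve_defect(flat_compartment, spec)


# ---------------------------------------------------------------------------
# intact-surface reconstruction
# ---------------------------------------------------------------------------
def grid_surface(f, n=25, half=5.0):
    x = np.linspace(-half, half, n)
    X, Y = np.meshgrid(x, x, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), f(X.ravel(), Y.ravel())])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            faces.append([a, a + n, a + n + 1, a + 1])
    return SurfaceMesh(points=pts, faces=np.array(faces), grid_shape=(n, n))


def damage_and_rim(surf, radius=1.6):
    r = np.linalg.norm(surf.points[:, :2], axis=1)
    hole = r < radius
    damaged = SurfaceMesh(surf.points.copy(), surf.faces.copy(), grid_shape=surf.grid_shape)
    damaged.points[hole, 2] -= 1.0  # carve a pit
    # rim: nearest intact ring around the hole
    ring = (~hole) & (r < radius + 0.7)
    return damaged, np.nonzero(ring)[0], hole


def test_planar_rim_fills_planar(flat_compartment):
    surf = grid_surface(lambda x, y: 0.2 * x - 0.1 * y + 1.0)
    damaged, rim, hole = damage_and_rim(surf)
    filled = fill_defect_surface(damaged, rim)
    expect = 0.2 * filled.points[hole, 0] - 0.1 * filled.points[hole, 1] + 1.0
    assert np.max(np.abs(filled.points[hole, 2] - expect)) < 1e-8


def test_spherical_cap_fill_deviation_below_2pct_of_sagitta():
    R = 60.0
    surf = grid_surface(lambda x, y: R - np.sqrt(R**2 - x**2 - y**2))
    damaged, rim, hole = damage_and_rim(surf, radius=1.6)
    filled = fill_defect_surface(damaged, rim)
    r2 = np.sum(filled.points[hole, :2] ** 2, axis=1)
    truth = R - np.sqrt(R**2 - r2)
    sagitta = 1.6**2 / (2 * R)
    assert np.max(np.abs(filled.points[hole, 2] - truth)) < 0.02 * sagitta


def test_fill_of_unbroken_surface_is_identity():
    surf = grid_surface(lambda x, y: np.sin(0.3 * x) * np.cos(0.2 * y))
    filled = fill_defect_surface(surf, np.array([], dtype=int))
    assert np.array_equal(filled.points, surf.points)


def test_open_rim_loop_rejected():
    surf = grid_surface(lambda x, y: np.zeros_like(x))
    with pytest.raises(ValueError, match="closed loop"):
        fill_defect_surface(surf, np.array([0, 1]))


def test_carve_then_fill_recovers_intact_surface(flat_compartment):
    comp = flat_compartment
    geo = carve_defect(comp, make_defect(center=(0.0, 0.0)))
    nx, ny, nz = geo.mesh.meta["structured_dims"]
    top = geo.mesh.node_sets["articular_surface"]
    pts = geo.mesh.points[top]
    damaged = SurfaceMesh(points=pts.copy(), faces=np.zeros((0, 4), dtype=int),
                          grid_shape=(nx + 1, ny + 1))
    # rim indices within the surface grid numbering
    remap = {g: i for i, g in enumerate(top)}
    rim_local = np.array([remap[g] for g in geo.rim_nodes])
    filled = fill_defect_surface(damaged, rim_local)
    intact_z = comp.z_top_at(pts[:, 0], pts[:, 1])
    rms = np.sqrt(np.mean((filled.points[:, 2] - intact_z) ** 2))
    assert rms < 0.01 * comp.thickness_at(0.0, 0.0)


# ---------------------------------------------------------------------------
# relocation
# ---------------------------------------------------------------------------
@pytest.fixture(scope="module")
def gradient_compartment():
    return make_compartment(CompartmentSpec(
        plateau_extent_mm=(16.0, 16.0), target_element_size_mm=0.5,
        thickness_profile=ThicknessProfile(base_mm=2.5, gradient_mm_per_mm=(0.125, 0.0)),
    ))


def test_relocate_to_same_center_is_identity(flat_compartment):
    geo = carve_defect(flat_compartment, make_defect(center=(1.0, -1.0)))
    _, geo2 = relocate_defect(flat_compartment, geo, np.array([1.0, -1.0]))
    assert np.max(np.abs(geo2.mesh.points - geo.mesh.points)) < 1e-10


def test_relocation_on_uniform_slab_is_rigid_translation(flat_compartment):
    geo_a = carve_defect(flat_compartment, make_defect(center=(-2.0, 0.0)))
    _, geo_b = relocate_defect(flat_compartment, geo_a, np.array([2.0, 0.0]))
    # defect-surface node depths identical after shifting by (4, 0)
    za = np.sort(geo_a.mesh.points[geo_a.defect_surface_nodes, 2])
    zb = np.sort(geo_b.mesh.points[geo_b.defect_surface_nodes, 2])
    assert np.allclose(za, zb, atol=1e-9)


def test_halved_thickness_halves_absolute_depth_not_normalized(gradient_compartment):
    comp = gradient_compartment
    # thickness 3.0 at x=+4, 1.5 at x=-8; pick B where thickness is half of A
    geo_a = carve_defect(comp, make_defect(center=(4.0, 0.0)))
    _, geo_b = relocate_defect(comp, geo_a, np.array([-8.0 + 4.0, 0.0]))  # x=-4: t=2.0
    t_a = float(comp.thickness_at(4.0, 0.0))
    t_b = float(comp.thickness_at(-4.0, 0.0))
    pen_a = normalized_penetration(geo_a.mesh.points[geo_a.defect_surface_nodes], comp)
    pen_b = normalized_penetration(geo_b.mesh.points[geo_b.defect_surface_nodes], comp)
    assert np.max(pen_a) == pytest.approx(np.max(pen_b), abs=1e-9)
    # absolute depth scales with local thickness
    depth_a = np.max(pen_a) * t_a
    depth_b = np.max(pen_b) * t_b
    assert depth_b / depth_a == pytest.approx(t_b / t_a, rel=1e-9)


def test_relocation_round_trip_is_idempotent(gradient_compartment):
    comp = gradient_compartment
    geo_a = carve_defect(comp, make_defect(center=(3.0, 1.0)))
    _, geo_b = relocate_defect(comp, geo_a, np.array([-3.0, -1.0]))
    _, geo_a2 = relocate_defect(comp, geo_b, np.array([3.0, 1.0]))
    rms = np.sqrt(np.mean((geo_a2.mesh.points - geo_a.mesh.points) ** 2))
    assert rms < 1e-6


def test_projected_area_is_conserved(gradient_compartment):
    comp = gradient_compartment
    geo_a = carve_defect(comp, make_defect(center=(4.0, 0.0)))
    for target in [(-4.0, 0.0), (0.0, 3.0), (-2.0, -3.0)]:
        spec_b, geo_b = relocate_defect(comp, geo_a, np.array(target))
        assert np.isclose(geo_b.projected_area_mm2, geo_a.projected_area_mm2, rtol=1e-12)
        assert np.isclose(spec_b.area_mm2, 5.2, rtol=1e-6)


def test_relocation_off_patch_rejected(flat_compartment):
    geo = carve_defect(flat_compartment, make_defect())
    with pytest.raises(ValueError, match="off the surface patch"):
        relocate_defect(flat_compartment, geo, np.array([6.9, 0.0]))


# ---------------------------------------------------------------------------
# drainage boundary conditions
# ---------------------------------------------------------------------------
def test_carved_model_drains_only_through_inner_walls(flat_compartment):
    geo = carve_defect(flat_compartment, make_defect())
    drained, sealed = defect_drainage_bcs(geo)
    all_faces = {tuple(p) for p in geo.mesh.boundary_faces().tolist()}
    dset = {tuple(p) for p in drained.tolist()}
    sset = {tuple(p) for p in sealed.tolist()}
    assert dset == {tuple(p) for p in geo.inner_wall_faces.tolist()}
    assert dset.isdisjoint(sset)
    assert dset | sset == all_faces


def test_intact_model_is_fully_sealed(flat_compartment):
    comp = flat_compartment
    spec = make_defect()
    geo = carve_defect(comp, spec)
    intact_geo = DefectGeometry(
        mesh=comp.cartilage.copy(), spec=spec,
        inner_wall_faces=np.zeros((0, 2), dtype=int),
        rim_nodes=np.array([], dtype=int),
        node_penetration=np.array([]), defect_surface_nodes=np.array([], dtype=int),
        projected_area_mm2=0.0,
    )
    drained, sealed = defect_drainage_bcs(intact_geo)
    assert len(drained) == 0
    assert len(sealed) == len(intact_geo.mesh.boundary_faces())


def test_sealed_variant_changes_only_the_drained_set(flat_compartment):
    # toggling drainage is a boundary-condition switch: mesh, sets and
    # geometry stay bitwise identical
    geo = carve_defect(flat_compartment, make_defect())
    drained, sealed = defect_drainage_bcs(geo)
    sealed_variant_drained = np.zeros((0, 2), dtype=int)
    assert len(drained) > 0 and len(sealed_variant_drained) == 0
    assert np.array_equal(geo.mesh.points, carve_defect(
        flat_compartment, make_defect()).mesh.points)
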