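"""Scenario orchestration: fixtures -> intact solve -> carve/relocate ->
damaged solves -> failure reports, under one validated configuration.

A scenario is an idealized compartment loaded through the stance-phase
protocol by the rigid femoral-condyle surrogate, solved once intact and
once per defect location with the same mesh topology (carving deforms
node columns, so intact and damaged states share an evaluation grid),
followed by the five-criterion failure analysis in a 1 mm ROI around the
defect rim.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .constitutive import FRPEParams, build_architecture
from .defects import DefectGeometry, carve_defect, defect_drainage_bcs, relocate_defect
from .failure import (
    CRITERIA,
    FailureReport,
    FailureThresholds,
    classify_failure,
    compare_scenarios,
    exceedance_intervals,
    roi_max_series,
    roi_membership,
)
from .fe import (
    ContactSpec,
    DirichletBC,
    FEModel,
    PoroelasticCartilage,
    SolverConfig,
    solve_protocol,
)
from .fe.model import PressureBC
from .fe.strain import history_fields
from .synthetic import (
    CompartmentSpec,
    GaitSpec,
    ThicknessProfile,
    make_compartment,
    make_defect,
    make_gait_protocol,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
@dataclass
class DefectConfig:
    footprint_area_mm2: float = 5.2
    depth_fraction: float = 0.63
    shape: str = "circular"
    center_mm: tuple | None = (0.0, 0.0)  # None: intact-only scenario
    alternative_locations_mm: tuple = ()
    drainage: str = "free"  # "free" | "sealed" inner defect surfaces


@dataclass
class ScenarioConfig:
    """Validated end-to-end scenario description."""

    compartment: CompartmentSpec = field(default_factory=CompartmentSpec)
    material: FRPEParams = field(default_factory=FRPEParams)
    gait: GaitSpec = field(default_factory=GaitSpec)
    defect: DefectConfig = field(default_factory=DefectConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    thresholds: FailureThresholds = field(default_factory=FailureThresholds)
    # scales the body-weight stance force onto the single desk-scale
    # compartment so the intact peak compressive strain sits in the healthy
    # 10-18 % stance-deformation range (peak ~15 N at the defaults)
    force_scale: float = 0.008
    roi_radius_mm: float = 1.0
    n_protocol_points: int | None = 21
    seed: int = 0
    label: str = "scenario"

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        kw = {}
        sub = {
            "compartment": CompartmentSpec, "material": FRPEParams, "gait": GaitSpec,
            "defect": DefectConfig, "solver": SolverConfig, "thresholds": FailureThresholds,
        }
        for key, klass in sub.items():
            if key in d:
                sd = dict(d.pop(key))
                if key == "compartment" and "thickness_profile" in sd:
                    sd["thickness_profile"] = ThicknessProfile(**sd["thickness_profile"])
                known = klass.__dataclass_fields__.keys()
                unknown = set(sd) - set(known)
                if unknown:
                    raise ValueError(f"unknown keys in '{key}': {sorted(unknown)}")
                kw[key] = klass(**sd)
        unknown = set(d) - set(cls.__dataclass_fields__.keys())
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self), default=default)), fh)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)  # name -> {status, wall_s, outputs}
    warnings: list = field(default_factory=list)

    def record(self, stage: str, status: str, wall_s: float, outputs=None, message=None):
        self.stages[stage] = {
            "status": status, "wall_time_s": round(wall_s, 3),
            "outputs": outputs or [], "message": message,
        }

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages.values())

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# model building
# --------------------------------------------------------------------------
def build_cartilage_model(compartment, params: FRPEParams,
                          geometry: DefectGeometry | None = None,
                          drainage: str = "free") -> FEModel:
    """FE model of the cartilage layer: bone interface tied (fixed), free
    side walls, penalty contact with the rigid sphere under force control,
    sealed boundaries except free-draining inner defect walls (switchable
    to a fully sealed variant with ``drainage='sealed'``)."""
    mesh = compartment.cartilage if geometry is None else geometry.mesh
    arch = build_architecture(
        mesh, compartment.normal_at, compartment.split_line_at,
        compartment.thickness_at, compartment.z_top_at, params,
    )
    mat = PoroelasticCartilage(params=params, architecture=arch)
    pressure_bcs = []
    if geometry is not None and drainage == "free" and len(geometry.inner_wall_faces):
        drained, _ = defect_drainage_bcs(geometry)
        wall_nodes = np.unique(mesh.face_nodes(drained))
        pressure_bcs.append(PressureBC(wall_nodes, 0.0))
    return FEModel(
        mesh=mesh,
        materials={0: mat},
        dirichlet=[DirichletBC(mesh.node_sets["bone_interface"], (0, 1, 2), 0.0)],
        pressure_bcs=pressure_bcs,
        contact=ContactSpec(
            center0=compartment.indenter.center,
            radius_mm=compartment.indenter.radius_mm,
            faces=mesh.face_sets["articular_surface"],
            mode="force",
        ),
    )


def _protocol_for(config: ScenarioConfig):
    gait = config.gait
    if config.n_protocol_points is not None:
        gait = replace(gait, n_time_points=config.n_protocol_points)
    return make_gait_protocol(gait)


def _location_report(config, protocol, intact_states, damaged_states, geometry,
                     label) -> FailureReport:
    hf_d = history_fields(damaged_states)
    hf_i = history_fields(intact_states)
    stance = np.array([s.stance_pct for s in damaged_states])
    gp = damaged_states[0].gauss_points
    rim_xyz = geometry.mesh.points[geometry.rim_nodes]
    roi = roi_max_series(hf_d, gp, rim_xyz, config.roi_radius_mm)
    thr = config.thresholds
    intervals = {}
    for crit in CRITERIA:
        intervals[crit] = exceedance_intervals(
            roi[crit], thr.limit(crit), stance, compressive=(crit == "min_principal_strain")
        )
    masks = {crit: np.stack([classify_failure(
        {k: hf_d[k][i] for k in hf_d}, thr)[crit] for i in range(len(stance))])
        for crit in CRITERIA}
    # fold change restricted to the ROI (co-located intact values)
    mask_roi = roi_membership(gp, rim_xyz, config.roi_radius_mm)
    _, folds = compare_scenarios(
        {k: v[:, mask_roi] for k, v in hf_i.items()},
        {k: v[:, mask_roi] for k, v in hf_d.items()},
    )
    return FailureReport(
        label=label, stance_pct=stance, masks=masks, roi_series=roi,
        exceedance_intervals=intervals, fold_change=folds,
        provenance={"config_hash": config.config_hash(),
                    "mesh_hash": hashlib.sha256(
                        np.ascontiguousarray(geometry.mesh.points).tobytes()).hexdigest()[:16]},
    )


def run_scenario(config: ScenarioConfig, out_dir=None):
    """Execute the full pipeline; returns (manifest, reports).

    ``reports`` maps location labels to FailureReports (empty when the
    config lists no defect locations). A failed stage aborts downstream
    stages for that location only; everything is recorded in the
    manifest.
    """
    from . import __version__

    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)
    reports: dict = {}

    t0 = time.time()
    comp = make_compartment(config.compartment)
    protocol = _protocol_for(config)
    manifest.record("fixtures", "ok", time.time() - t0)

    t0 = time.time()
    intact_model = build_cartilage_model(comp, config.material)
    intact = solve_protocol(intact_model, protocol, config.solver,
                            force_scale=config.force_scale)
    if intact.failure:
        manifest.record("intact_solve", "failed", time.time() - t0,
                        message=intact.failure["message"])
        return manifest, reports
    manifest.record("intact_solve", "ok", time.time() - t0)

    if config.defect.center_mm is None:
        centers = []
    else:
        centers = [tuple(config.defect.center_mm)] + [
            tuple(c) for c in config.defect.alternative_locations_mm
        ]
    base_spec = None
    for i, center in enumerate(centers):
        label = "original" if i == 0 else f"alt_{i}"
        stage = f"damaged_solve[{label}]"
        t0 = time.time()
        try:
            if base_spec is None:
                base_spec = make_defect(
                    footprint_area_mm2=config.defect.footprint_area_mm2,
                    depth_fraction=config.defect.depth_fraction,
                    center=center, shape=config.defect.shape, seed=config.seed,
                    patch_extent_mm=comp.plan_bounds(),
                )
                geometry = carve_defect(comp, base_spec)
            else:
                _, geometry = relocate_defect(
                    comp, carve_defect(comp, base_spec), np.asarray(center)
                )
            dmg_model = build_cartilage_model(comp, config.material, geometry,
                                              drainage=config.defect.drainage)
            damaged = solve_protocol(dmg_model, protocol, config.solver,
                                     force_scale=config.force_scale)
            if damaged.failure:
                raise RuntimeError(damaged.failure["message"])
            reports[label] = _location_report(
                config, protocol, intact.states, damaged.states, geometry, label
            )
            manifest.record(stage, "ok", time.time() - t0)
        except Exception as exc:
            log.error("%s failed: %s", stage, exc)
            manifest.record(stage, "failed", time.time() - t0, message=str(exc))

    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, rep in reports.items():
            with open(out / f"failure_report_{label}.json", "w") as fh:
                json.dump(rep.to_dict(), fh, indent=1, sort_keys=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
        if reports:
            import pandas as pd

            summarize_locations(list(reports.values())).to_csv(
                out / "location_summary.csv", index=False
            )
    return manifest, reports


def summarize_locations(reports):
    """Ranked location table: sorted by descending peak compressive strain
    magnitude, ties broken by peak shear strain."""
    import pandas as pd

    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for rep in reports:
        flags = {f"flag_{c}": bool(rep.exceedance_intervals.get(c)) for c in CRITERIA}
        rows.append({
            "location": rep.label,
            "peak_min_principal_strain": float(np.min(rep.roi_series["min_principal_strain"])),
            "peak_shear_strain": float(np.max(rep.roi_series["shear_strain"])),
            "exceedance_pct_compressive": rep.exceedance_pct("min_principal_strain"),
            "exceedance_pct_shear": rep.exceedance_pct("shear_strain"),
            **flags,
        })
    df = pd.DataFrame(rows)
    df["_k"] = df["peak_min_principal_strain"].abs()
    df = df.sort_values(["_k", "peak_shear_strain"], ascending=False, kind="stable")
    return df.drop(columns="_k").reset_index(drop=True)


# --------------------------------------------------------------------------
# convergence scenario (submodel density study)
# --------------------------------------------------------------------------
def indentation_convergence_levels(config: ScenarioConfig | None = None,
                                   element_sizes_mm=(0.3, 0.2),
                                   region_half_mm: float = 2.0,
                                   n_steps: int = 3):
    """Callable factory for the toy spherical-indentation submodel
    convergence study.

    Solves one coarse global model, then re-solves the central region as a
    submodel at each element size with interpolated boundary conditions;
    returns (run_level callable, levels) for
    :func:`cartimech.fe.convergence_study`. Peaks are evaluated over
    Gauss points at least one element inside the cut boundary.
    """
    from .fe.convergence import peak_parameters
    from .fe.submodel import build_submodel, solve_submodel

    from .synthetic import LoadProtocol

    config = config or ScenarioConfig()
    comp = make_compartment(config.compartment)
    # ramp to the stance peak force in n_steps (first-peak snapshot)
    gait_peak = float(np.max(make_gait_protocol(config.gait).axial_force_N))
    f_peak = gait_peak * config.force_scale
    t_peak = 0.15 * config.gait.stance_duration_s
    s = np.linspace(0.0, 1.0, n_steps + 1)
    protocol = LoadProtocol(
        times_s=s * t_peak, stance_pct=s * 15.0,
        axial_force_N=s * f_peak, flexion_deg=np.zeros(n_steps + 1),
    )
    model = build_cartilage_model(comp, config.material)
    # the ramp already carries the scenario force scale
    glob = solve_protocol(model, protocol, config.solver, force_scale=1.0)
    if glob.failure:
        raise RuntimeError(f"global solve failed: {glob.failure['message']}")

    bounds = ((-region_half_mm, region_half_mm), (-region_half_mm, region_half_mm))
    # fixed probe lattice, identical for every refinement level: in-plane
    # 0.25 mm spacing with a 0.5 mm margin off the cut boundary, nine
    # normalized-depth stations from 0.1 to 0.9
    margin = 0.5
    px = np.arange(bounds[0][0] + margin, bounds[0][1] - margin + 1e-9, 0.25)
    py = np.arange(bounds[1][0] + margin, bounds[1][1] - margin + 1e-9, 0.25)
    depths = np.linspace(0.1, 0.9, 9)
    X, Y, D = np.meshgrid(px, py, depths, indexing="ij")
    x, y, d = X.ravel(), Y.ravel(), D.ravel()
    z = comp.z_top_at(x, y) - d * comp.thickness_at(x, y)
    probes = np.column_stack([x, y, z])
    from .constitutive import arcade_direction

    probe_dirs = arcade_direction(
        d, comp.normal_at(x, y), comp.split_line_at(x, y),
        config.material.superficial_fraction, config.material.deep_fraction,
    )

    def run_level(element_size_mm):
        from .fe.convergence import probe_peak_parameters

        sub, _ = build_submodel(comp, bounds, element_size_mm)
        res = solve_submodel(
            sub, config.material, comp.cartilage, glob.states, protocol, config.solver
        )
        if res.failure:
            raise RuntimeError(f"submodel solve failed: {res.failure['message']}")
        return probe_peak_parameters(res.states, sub.cartilage, probes,
                                     fibril_direction=probe_dirs,
                                     material_params=config.material)

    return run_level, list(element_sizes_mm)
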