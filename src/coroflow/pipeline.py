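"""End-to-end study orchestration.

A study is the four-arm comparison the analysis is built around: the
bifurcation with and without plaques, each solved under the Newtonian and
the generalized-power-law rheology, post-processed at peak systole (0.4 s)
and mid-diastole (0.7 s) and reduced to one :class:`SummaryReport`.

Configuration lives in a YAML file (see ``coroflow/configs/default.yaml``
for the annotated default); :func:`validate_config` parses and
invariant-checks it, :func:`run_study` executes the requested arms and
writes the artifact tree.  Everything is deterministic given the config:
meshing uses a fixed seed and the solver has no random components.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .geometry import (LumenOutline, PlaqueSpec, SectionPlane,
                       VesselSpec, apply_plaque, build_bifurcation,
                       default_plaques, define_sections, measure_stenosis)
from .inflow import Waveform, default_waveform, load_waveform_csv
from .meshing import generate_mesh
from .post import (ARM_NAMES, ArmResult, SummaryReport,
                   pressure_gradient_magnitude, sample_section, summarize,
                   wall_shear_stress)
from .rheology import GeneralizedPowerLawModel, NewtonianModel
from .solver import NavierStokesSolver, SolverConfig

__all__ = ["StudyConfig", "StudyResult", "ConfigError", "validate_config",
           "default_config", "run_study"]

REPORT_TIMES = (0.4, 0.7)
#: station of the prestenotic reference section, upstream of the plaque
#: center in units of the plaque length
REFERENCE_OFFSET = 0.75


class ConfigError(ValueError):
    """Aggregated configuration violations, one message per key path."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid study configuration:\n  "
                         + "\n  ".join(self.errors))


@dataclass
class StudyConfig:
    """Fully resolved study configuration."""

    vessel: VesselSpec = field(default_factory=VesselSpec)
    plaques: list = field(default_factory=default_plaques)
    solver: SolverConfig = field(default_factory=SolverConfig)
    waveform: Waveform = field(default_factory=default_waveform)
    mesh_h: float = 0.25  # mm
    mesh_seed: int = 0
    arms: tuple = ARM_NAMES
    newtonian_viscosity: float = 0.0035  # Pa*s
    lcx_group_center: float = 3.5  # mm, center of sections K-O
    section_samples: int = 51

    def rheology(self, name: str):
        rho = self.solver.rho
        if name == "newtonian":
            return NewtonianModel(mu=self.newtonian_viscosity, rho=rho)
        if name in ("gpl", "generalized_power_law"):
            return GeneralizedPowerLawModel(rho=rho)
        raise ConfigError([f"unknown rheology {name!r}"])


def default_config(**overrides) -> StudyConfig:
    return replace(StudyConfig(), **overrides)


def _get(mapping, path, default=None):
    cur = mapping
    for key in path.split("."):
        if not isinstance(cur, dict) or key not in cur:
            return default
        cur = cur[key]
    return cur


def validate_config(path) -> StudyConfig:
    """Parse and invariant-check a YAML study configuration file.

    Every violated invariant is reported with its key path; all defaults
    are resolved in the returned :class:`StudyConfig`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors = []

    def build(section, cls, kwargs):
        try:
            return cls(**kwargs)
        except (ValueError, TypeError) as exc:
            errors.append(f"{section}: {exc}")
            return None

    vessel = build("vessel", VesselSpec, _get(raw, "vessel", {}) or {})
    plaques = []
    raw_plaques = raw.get("plaques")
    if raw_plaques is None:
        plaques = default_plaques()
    else:
        for i, p in enumerate(raw_plaques):
            pq = build(f"plaques[{i}]", PlaqueSpec, p)
            if pq is not None:
                plaques.append(pq)
    solver = build("solver", SolverConfig, _get(raw, "solver", {}) or {})

    harmonics = int(_get(raw, "waveform.harmonics", 8))
    scale = float(_get(raw, "waveform.amplitude_scale", 1.0))
    source = _get(raw, "waveform.source", "default")
    waveform = None
    try:
        if source == "default":
            waveform = default_waveform(harmonics=harmonics).scaled(scale)
        else:
            csv_path = Path(source)
            if not csv_path.is_absolute():
                csv_path = Path(path).parent / csv_path
            if not csv_path.exists():
                errors.append(f"waveform.source: file {csv_path} not found")
            else:
                waveform = load_waveform_csv(csv_path,
                                             harmonics=harmonics).scaled(scale)
    except ValueError as exc:
        errors.append(f"waveform: {exc}")

    if solver is not None and waveform is not None and \
            abs(solver.period - waveform.period) > 1e-9:
        errors.append(
            "solver: dt*steps_per_cycle "
            f"({solver.period}) must equal the waveform period "
            f"({waveform.period})")

    mesh_h = float(_get(raw, "mesh.h", 0.25))
    if mesh_h <= 0:
        errors.append("mesh.h: must be positive")
    mesh_seed = int(_get(raw, "mesh.seed", 0))
    arms = tuple(_get(raw, "arms", list(ARM_NAMES)))
    if not arms:
        errors.append("arms: at least one study arm is required")
    for a in arms:
        if a not in ARM_NAMES:
            errors.append(f"arms: unknown arm {a!r} (choose from "
                          f"{list(ARM_NAMES)})")
    mu_newt = float(_get(raw, "rheology.newtonian_viscosity", 0.0035))
    if mu_newt <= 0:
        errors.append("rheology.newtonian_viscosity: must be positive")

    if errors:
        raise ConfigError(errors)
    return StudyConfig(vessel=vessel, plaques=plaques, solver=solver,
                       waveform=waveform, mesh_h=mesh_h, mesh_seed=mesh_seed,
                       arms=arms, newtonian_viscosity=mu_newt,
                       lcx_group_center=float(
                           _get(raw, "sections.lcx_group_center", 3.5)),
                       section_samples=int(_get(raw, "sections.samples", 51)))


@dataclass
class StudyResult:
    """Outputs of :func:`run_study`."""

    config: StudyConfig
    report: SummaryReport
    arms: dict  # name -> ArmResult
    outlines: dict  # 'plaque'/'noplaque' -> LumenOutline
    meshes: dict
    sections: dict  # geometry -> list[SectionPlane]
    stenosis: dict  # branch -> percent (plaque geometry)
    elapsed_s: float


def _reference_planes(outline: LumenOutline, plaques) -> dict:
    planes = {}
    for p in plaques:
        s_ref = p.center_s - REFERENCE_OFFSET * p.length
        if s_ref <= 0:
            continue
        a, b = outline.section_segment(p.branch, s_ref)
        br = outline.branches[p.branch]
        planes[p.branch] = SectionPlane(label=f"ref_{p.branch}",
                                        branch=p.branch, s=s_ref, start=a,
                                        end=b, streamwise=br.direction.copy())
    return planes


def run_study(config: StudyConfig, out_dir=None,
              progress=None) -> StudyResult:
    """Build, mesh, solve and post-process the requested study arms."""
    t0 = time.perf_counter()
    log = progress or (lambda msg: None)

    log("building geometry")
    plain = build_bifurcation(config.vessel)
    plaqued = plain
    for p in config.plaques:
        plaqued = apply_plaque(plaqued, p)
    outlines = {"noplaque": plain, "plaque": plaqued}
    stenosis = {p.branch: measure_stenosis(plaqued, p.branch)
                for p in config.plaques}

    log("meshing")
    meshes = {}
    for geo, outline in outlines.items():
        meshes[geo] = generate_mesh(outline, config.mesh_h,
                                    seed=config.mesh_seed)

    sections = {geo: define_sections(outline, plaques=config.plaques,
                                     lcx_group_center=config.lcx_group_center)
                for geo, outline in outlines.items()}
    refs = {geo: _reference_planes(outline, config.plaques)
            for geo, outline in outlines.items()}

    arms = {}
    for arm_name in config.arms:
        rhe_name, geo_tag = arm_name.rsplit("_", 1)
        geo = "plaque" if geo_tag == "plaque" else "noplaque"
        rheology = config.rheology(
            "newtonian" if rhe_name == "newtonian" else "gpl")
        log(f"solving arm {arm_name}")
        solver = NavierStokesSolver(meshes[geo], config.solver,
                                    rheology=rheology,
                                    waveform=config.waveform)
        result = solver.run_cycles()
        arms[arm_name] = ArmResult(
            name=arm_name, rheology_name=rheology.name,
            plaque=(geo == "plaque"), rheology=rheology, solver=solver,
            result=result, outline=outlines[geo], sections=sections[geo],
            reference_sections=refs[geo])

    log("summarizing")
    report = summarize(arms, config.plaques, times=REPORT_TIMES,
                       require_all=set(config.arms) >= set(ARM_NAMES))
    report.meta["stenosis_percent"] = {k: float(v)
                                       for k, v in stenosis.items()}
    report.meta["mesh"] = {geo: {"nodes": int(m.n_nodes),
                                 "triangles": int(m.n_triangles),
                                 "h_mm": m.h}
                           for geo, m in meshes.items()}

    elapsed = time.perf_counter() - t0
    result = StudyResult(config=config, report=report, arms=arms,
                         outlines=outlines, meshes=meshes, sections=sections,
                         stenosis=stenosis, elapsed_s=elapsed)
    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: StudyResult, out_dir) -> None:
    """Write the stable artifact tree for a study run.

    Layout: ``report.json``; per-arm directories with residual logs,
    section profiles (CSV, one per section and reporting time) and VTK
    fields at the reporting phases; STL + VTK of each geometry.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(result.report.to_json())

    for geo, mesh in result.meshes.items():
        cio.export_stl(mesh, out / f"lumen_{geo}.stl")
        cio.write_vtk(out / f"mesh_{geo}.vtk", mesh)

    for name, arm in result.arms.items():
        arm_dir = out / name
        arm_dir.mkdir(exist_ok=True)
        log = np.column_stack([
            np.arange(1, len(arm.result.residual_log) + 1),
            arm.result.residual_log, arm.result.iteration_log])
        np.savetxt(arm_dir / "residuals.csv", log, delimiter=",",
                   header="step,residual,inner_iterations", comments="")
        for t in REPORT_TIMES:
            state = arm.result.state_at(t)
            psg = pressure_gradient_magnitude(state, arm.solver.mesh)
            wall = wall_shear_stress(state, arm.solver.mesh, arm.rheology,
                                     outline=arm.outline,
                                     interpolator=arm.interpolator)
            wss_nodal = np.zeros(arm.solver.mesh.n_nodes)
            wss_nodal[wall.node_indices] = np.nan_to_num(wall.wss)
            cio.write_vtk(
                arm_dir / f"fields_t{t:.1f}.vtk", arm.solver.mesh,
                {"velocity_m_s": np.column_stack([state.ux, state.uy]),
                 "pressure_pa": state.p,
                 "viscosity_pa_s": state.viscosity,
                 "psg_kg_m2_s2": psg,
                 "wss_pa": wss_nodal})
            for plane in arm.sections:
                prof = sample_section(state, arm.solver.mesh, plane,
                                      n=51, interpolator=arm.interpolator)
                np.savetxt(
                    arm_dir / f"section_{plane.label}_t{t:.1f}.csv",
                    np.column_stack([prof.positions, prof.streamwise,
                                     prof.transverse]),
                    delimiter=",",
                    header="position_mm,streamwise_mm_s,transverse_mm_s",
                    comments="")
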