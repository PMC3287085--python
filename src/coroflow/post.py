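"""Hemodynamic post-processing.

Reduces solved flow fields to the quantities the study reports:

* PSG — the magnitude of the local spatial pressure gradient |grad p| in
  kg/(m^2 s^2) (= Pa/m), recovered at nodes by area-weighted averaging of
  the element-wise P1 gradients;
* WSS — wall shear stress in Pa, computed at every wall node from the
  wall-normal gradient of the tangential velocity (two-point quadratic
  extrapolation along the inward normal, exact for a parabolic profile)
  with the apparent viscosity of the active rheology evaluated at the wall
  shear rate;
* velocity profiles across the labelled cross-sections A–O, and the
  fraction of reversed (negative streamwise) samples as a recirculation
  measure;
* per-region min/max summaries at the two reporting phases (peak systole
  0.4 s, mid-diastole 0.7 s) for each study arm, with paired
  plaque/no-plaque and non-Newtonian/Newtonian comparisons.

Velocities are reported in mm/s (the display unit of the study); fields are
stored in SI internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import LumenOutline, SectionPlane
from .meshing import Mesh
from .solver import CycleResult, FlowState, NavierStokesSolver

__all__ = [
    "FieldInterpolator",
    "WallField",
    "SectionProfile",
    "ArmResult",
    "SummaryReport",
    "pressure_gradient_magnitude",
    "wall_shear_stress",
    "sample_section",
    "recirculation_fraction",
    "summarize",
]

MM = 1e-3
REPORT_TIMES = (0.4, 0.7)


class FieldInterpolator:
    """Piecewise-linear interpolation of nodal fields at arbitrary points.

    Queries are in mesh (mm) coordinates; candidate elements come from a
    centroid k-d tree, membership from barycentric coordinates.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        p = mesh.points[mesh.triangles]
        self._origin = p[:, 0]
        T = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=-1)
        self._Tinv = np.linalg.inv(T)
        self._tree = cKDTree(p.mean(axis=1))

    def locate(self, pts, k: int = 12):
        """Element index and barycentric coords for each point.

        Points outside the mesh get element -1.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        n = len(pts)
        elem = np.full(n, -1, dtype=int)
        bary = np.zeros((n, 3))
        pending = np.arange(n)
        for kk in (k, 8 * k):
            if not len(pending):
                break
            _, cand = self._tree.query(pts[pending], k=kk)
            cand = np.atleast_2d(cand)
            diff = pts[pending][:, None, :] - self._origin[cand]
            lam = np.einsum("pcij,pcj->pci", self._Tinv[cand], diff)
            lam0 = 1.0 - lam.sum(axis=2)
            lam_full = np.concatenate([lam0[..., None], lam], axis=2)
            ok = lam_full.min(axis=2) >= -1e-9
            first = np.argmax(ok, axis=1)
            found = ok[np.arange(len(pending)), first]
            idx = pending[found]
            elem[idx] = cand[found, first[found]]
            bary[idx] = lam_full[found, first[found]]
            pending = pending[~found]
        if len(pending):
            # points a hair outside the faceted boundary (e.g. on the exact
            # curved wall): snap to the closest element if within ~h/4
            for pi in pending:
                _, cand = self._tree.query(pts[pi], k=6)
                best_d, best = np.inf, None
                for c in np.atleast_1d(cand):
                    lam = self._Tinv[c] @ (pts[pi] - self._origin[c])
                    lam_full = np.array([1.0 - lam.sum(), lam[0], lam[1]])
                    lam_c = np.clip(lam_full, 0.0, None)
                    lam_c /= lam_c.sum()
                    nodes = self.mesh.triangles[c]
                    proj = lam_c @ self.mesh.points[nodes]
                    d = np.linalg.norm(proj - pts[pi])
                    if d < best_d:
                        best_d, best = d, (c, lam_c)
                if best is not None and best_d < 0.25 * self.mesh.h:
                    elem[pi], bary[pi] = best[0], best[1]
        return elem, bary

    def interpolate(self, values, pts):
        """Interpolate one or more nodal fields; NaN outside the mesh."""
        values = np.asarray(values)
        single = values.ndim == 1
        vals = np.atleast_2d(values)
        elem, bary = self.locate(pts)
        out = np.full((len(vals), len(elem)), np.nan)
        ok = elem >= 0
        nodes = self.mesh.triangles[elem[ok]]
        for i, v in enumerate(vals):
            out[i, ok] = np.einsum("pj,pj->p", v[nodes], bary[ok])
        return out[0] if single else out


def elements_to_nodes(mesh: Mesh, elem_values: np.ndarray) -> np.ndarray:
    """Area-weighted recovery of element-constant values at nodes."""
    areas = mesh.triangle_areas()
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    w = elem_values * areas
    for k in range(3):
        np.add.at(num, mesh.triangles[:, k], w)
        np.add.at(den, mesh.triangles[:, k], areas)
    return num / den


def _element_gradients(mesh: Mesh, nodal: np.ndarray) -> np.ndarray:
    """Element-constant spatial gradient (per metre) of a nodal field."""
    p = mesh.points[mesh.triangles] * MM
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    b = np.empty((len(p), 3, 2))
    b[:, 0, 0] = p[:, 1, 1] - p[:, 2, 1]
    b[:, 0, 1] = p[:, 2, 0] - p[:, 1, 0]
    b[:, 1, 0] = p[:, 2, 1] - p[:, 0, 1]
    b[:, 1, 1] = p[:, 0, 0] - p[:, 2, 0]
    b[:, 2, 0] = p[:, 0, 1] - p[:, 1, 1]
    b[:, 2, 1] = p[:, 1, 0] - p[:, 0, 0]
    b /= det[:, None, None]
    return np.einsum("eia,ei->ea", b, nodal[mesh.triangles])


def pressure_gradient_magnitude(state: FlowState, mesh: Mesh) -> np.ndarray:
    """Nodal |grad p| in kg/(m^2 s^2) (= Pa/m)."""
    ge = _element_gradients(mesh, state.p)
    gx = elements_to_nodes(mesh, ge[:, 0])
    gy = elements_to_nodes(mesh, ge[:, 1])
    return np.hypot(gx, gy)


@dataclass
class WallField:
    """WSS sampled at every wall node."""

    node_indices: np.ndarray
    points: np.ndarray  # (n, 2) mm
    branch: np.ndarray  # (n,) branch labels ('' if unclassified)
    s: np.ndarray  # (n,) arc-length station along the branch, mm
    wss: np.ndarray  # (n,) Pa
    shear_rate: np.ndarray  # (n,) 1/s


def classify_points(outline: LumenOutline, pts_mm: np.ndarray):
    """Assign each point to the nearest branch; returns (labels, s)."""
    pts = np.atleast_2d(pts_mm)
    best = np.full(len(pts), np.inf)
    labels = np.empty(len(pts), dtype=object)
    svals = np.zeros(len(pts))
    for name, br in outline.branches.items():
        rel = pts - br.origin
        s = np.clip(rel @ br.direction, 0.0, br.length)
        foot = br.origin + s[:, None] * br.direction
        d = np.linalg.norm(pts - foot, axis=1) / (0.5 * br.diameter)
        better = d < best
        best[better] = d[better]
        labels[better] = name
        svals[better] = s[better]
    return labels.astype(str), svals


def wall_shear_stress(state: FlowState, mesh: Mesh, rheology,
                      outline: LumenOutline | None = None,
                      interpolator: FieldInterpolator | None = None,
                      ) -> WallField:
    """WSS at each wall node via normal-line quadratic extrapolation.

    The tangential velocity is sampled at distances d and 2d along the
    inward wall normal (d ~ the local boundary spacing); with the no-slip
    zero at the wall, the one-sided estimate (4 u(d) - u(2d)) / (2d) is
    second-order accurate and exact for a parabolic profile.
    """
    interp = interpolator or FieldInterpolator(mesh)
    wall_sel = mesh.boundary_tags == "wall"
    edges = mesh.boundary_edges[wall_sel]
    normals = mesh.edge_normals()[wall_sel]
    lengths = mesh.edge_lengths()[wall_sel]

    nodes = np.unique(edges)
    n_in = np.zeros((len(nodes), 2))
    dloc = np.zeros(len(nodes))
    cnt = np.zeros(len(nodes))
    index = {n: i for i, n in enumerate(nodes)}
    for (a, b), nrm, L in zip(edges, normals, lengths):
        for nd in (a, b):
            i = index[nd]
            n_in[i] -= nrm  # inward
            dloc[i] += L
            cnt[i] += 1
    n_in /= np.linalg.norm(n_in, axis=1, keepdims=True)
    # sampling one element row away from the wall skips the largest P1
    # interpolation error; 1.2x the local boundary spacing works best
    dloc = 1.2 * dloc / cnt  # mm

    xw = mesh.points[nodes]
    p1 = xw + dloc[:, None] * n_in
    p2 = xw + 2.0 * dloc[:, None] * n_in
    u1 = interp.interpolate(np.vstack([state.ux, state.uy]), p1)
    u2 = interp.interpolate(np.vstack([state.ux, state.uy]), p2)
    tang = np.column_stack([-n_in[:, 1], n_in[:, 0]])
    ut1 = u1[0] * tang[:, 0] + u1[1] * tang[:, 1]
    ut2 = u2[0] * tang[:, 0] + u2[1] * tang[:, 1]
    dn = dloc * MM
    dudn = (4.0 * ut1 - ut2) / (2.0 * dn)
    gamma = np.abs(dudn)
    mu_w = np.asarray(rheology.apparent_viscosity(
        np.where(np.isfinite(gamma), gamma, 0.0)))
    wss = np.where(np.isfinite(gamma), mu_w * gamma, np.nan)

    if outline is not None:
        labels, svals = classify_points(outline, xw)
    else:
        labels = np.full(len(nodes), "", dtype=object).astype(str)
        svals = np.zeros(len(nodes))
    return WallField(node_indices=nodes, points=xw, branch=labels, s=svals,
                     wss=wss, shear_rate=gamma)


@dataclass
class SectionProfile:
    """Velocity sampled along one cross-section segment."""

    label: str
    branch: str
    positions: np.ndarray  # (n,) distance across the lumen, mm
    streamwise: np.ndarray  # (n,) mm/s, signed by the branch direction
    transverse: np.ndarray  # (n,) mm/s
    width: float  # segment length, mm

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.streamwise, self.transverse)

    def mean_streamwise(self) -> float:
        """Width-averaged streamwise velocity, mm/s (trapezoid rule)."""
        return float(np.trapezoid(self.streamwise, self.positions)
                     / (self.positions[-1] - self.positions[0]))

    def flux(self) -> float:
        """Volume flux through the section, m^2/s per unit depth."""
        return float(np.trapezoid(self.streamwise * MM,
                                  self.positions * MM))


def sample_section(state: FlowState, mesh: Mesh, plane: SectionPlane,
                   n: int = 51,
                   interpolator: FieldInterpolator | None = None,
                   ) -> SectionProfile:
    """Interpolate the velocity at ``n`` equispaced points across a plane."""
    if n < 2:
        raise ValueError("need at least two sample points")
    interp = interpolator or FieldInterpolator(mesh)
    pts = plane.points(n)
    u = interp.interpolate(np.vstack([state.ux, state.uy]), pts)
    if np.isnan(u).any():
        raise ValueError(
            f"section {plane.label} has sample points outside the mesh")
    d = plane.streamwise
    t = np.array([-d[1], d[0]])
    stream = (u[0] * d[0] + u[1] * d[1]) / MM  # mm/s
    trans = (u[0] * t[0] + u[1] * t[1]) / MM
    pos = np.linalg.norm(pts - pts[0], axis=1)
    return SectionProfile(label=plane.label, branch=plane.branch,
                          positions=pos, streamwise=stream, transverse=trans,
                          width=plane.width)


def recirculation_fraction(profile: SectionProfile) -> float:
    """Fraction of section samples with reversed (negative) streamwise flow."""
    return float(np.mean(profile.streamwise < 0.0))


# ---------------------------------------------------------------------------
# study-arm summaries


@dataclass
class ArmResult:
    """Everything post-processing needs about one solved study arm."""

    name: str  # e.g. 'newtonian_plaque'
    rheology_name: str  # 'newtonian' | 'generalized_power_law'
    plaque: bool
    rheology: object
    solver: NavierStokesSolver
    result: CycleResult
    outline: LumenOutline
    sections: list  # the 15 labelled SectionPlanes
    reference_sections: dict = field(default_factory=dict)  # branch -> plane
    _interp: FieldInterpolator | None = None

    @property
    def interpolator(self) -> FieldInterpolator:
        if self._interp is None:
            self._interp = FieldInterpolator(self.solver.mesh)
        return self._interp


ARM_NAMES = ("newtonian_plaque", "newtonian_noplaque",
             "gpl_plaque", "gpl_noplaque")


def _plaque_region_mask(wall: WallField, plaque) -> np.ndarray:
    lo = plaque.center_s - 1.5 * plaque.length
    hi = plaque.center_s + 1.5 * plaque.length
    return (wall.branch == plaque.branch) & (wall.s >= lo) & (wall.s <= hi)


def _minmax(values) -> dict:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if not len(v):
        return {"min": 0.0, "max": 0.0}
    return {"min": float(v.min()), "max": float(v.max())}


def _arm_summary(arm: ArmResult, plaques, times) -> dict:
    mesh = arm.solver.mesh
    interp = arm.interpolator
    labels, svals = classify_points(arm.outline, mesh.points)
    out = {}
    for t in times:
        state = arm.result.state_at(t)
        psg = pressure_gradient_magnitude(state, mesh)
        wall = wall_shear_stress(state, mesh, arm.rheology,
                                 outline=arm.outline, interpolator=interp)
        profiles = {pl.label: sample_section(state, mesh, pl,
                                             interpolator=interp)
                    for pl in arm.sections}
        entry = {
            "velocity_mm_s": {},
            "psg_kg_m2_s2": {},
            "wss_pa": {},
            "recirculation_fraction": {},
            "section_mean_streamwise_mm_s": {},
            "flow_split_lad_over_lcx": None,
            "throat_amplification": {},
        }
        groups = {"LMS": "ABCDE", "LAD": "FGHIJ", "LCX": "KLMNO"}
        for branch, grp in groups.items():
            speeds = np.concatenate([profiles[c].speed for c in grp])
            entry["velocity_mm_s"][branch] = _minmax(speeds)
            entry["psg_kg_m2_s2"][branch] = _minmax(psg[labels == branch])
        for pl in arm.sections:
            prof = profiles[pl.label]
            entry["recirculation_fraction"][pl.label] = \
                recirculation_fraction(prof)
            entry["section_mean_streamwise_mm_s"][pl.label] = \
                prof.mean_streamwise()
        for pq in plaques:
            mask = _plaque_region_mask(wall, pq)
            entry["wss_pa"][pq.branch] = _minmax(wall.wss[mask])
            throat_label = {"LMS": "C", "LAD": "H", "LCX": "M"}[pq.branch]
            ref_plane = arm.reference_sections.get(pq.branch)
            if ref_plane is not None:
                ref = sample_section(state, mesh, ref_plane,
                                     interpolator=interp)
                denom = ref.mean_streamwise()
                entry["throat_amplification"][pq.branch] = (
                    float(profiles[throat_label].mean_streamwise() / denom)
                    if abs(denom) > 1e-12 else None)
        q_lad = arm.solver.boundary_flux(state, "outlet_lad")
        q_lcx = arm.solver.boundary_flux(state, "outlet_lcx")
        entry["flow_split_lad_over_lcx"] = (
            float(q_lad / q_lcx) if abs(q_lcx) > 1e-30 else None)
        out[f"{t:.1f}"] = entry
    out["max_residual"] = float(arm.result.residual_log.max())
    out["max_mass_error"] = float(arm.result.mass_error_log.max())
    out["mean_inner_iterations"] = float(arm.result.iteration_log.mean())
    return out


def summarize(arms: dict, plaques, times=REPORT_TIMES,
              require_all: bool = True) -> "SummaryReport":
    """Reduce the solved study arms to a SummaryReport.

    ``arms`` maps arm names (``newtonian_plaque`` etc.) to
    :class:`ArmResult`.  With ``require_all`` (the default) all four study
    arms must be present; otherwise the paired comparisons that need a
    missing arm are marked ``"unavailable"``.
    """
    missing = [n for n in ARM_NAMES if n not in arms]
    if missing and require_all:
        raise ValueError(f"missing study arms: {missing}")

    arm_summaries = {name: _arm_summary(arm, plaques, times)
                     for name, arm in arms.items()}
    tkeys = [f"{t:.1f}" for t in times]

    comparisons = {}
    for rhe in ("newtonian", "gpl"):
        key = f"psg_max_ratio_plaque_over_noplaque_{rhe}"
        pa, na = f"{rhe}_plaque", f"{rhe}_noplaque"
        if pa in arm_summaries and na in arm_summaries:
            comparisons[key] = {
                br: {tk: arm_summaries[pa][tk]["psg_kg_m2_s2"][br]["max"]
                     / max(arm_summaries[na][tk]["psg_kg_m2_s2"][br]["max"],
                           1e-30)
                     for tk in tkeys}
                for br in {p.branch for p in plaques}}
        else:
            comparisons[key] = "unavailable"
        key = f"recirculation_excess_{rhe}"
        if pa in arm_summaries and na in arm_summaries:
            comparisons[key] = {
                lab: {tk: arm_summaries[pa][tk]["recirculation_fraction"][lab]
                      - arm_summaries[na][tk]["recirculation_fraction"][lab]
                      for tk in tkeys}
                for lab in "IJKL"}
        else:
            comparisons[key] = "unavailable"
    for geo in ("plaque", "noplaque"):
        key = f"wss_max_ratio_gpl_over_newtonian_{geo}"
        ga, na = f"gpl_{geo}", f"newtonian_{geo}"
        if ga in arm_summaries and na in arm_summaries:
            comparisons[key] = {
                br: {tk: arm_summaries[ga][tk]["wss_pa"][br]["max"]
                     / max(arm_summaries[na][tk]["wss_pa"][br]["max"], 1e-30)
                     for tk in tkeys}
                for br in {p.branch for p in plaques}}
        else:
            comparisons[key] = "unavailable"

    meta = {
        "times_s": list(times),
        "plaques": [{"branch": p.branch, "center_s_mm": p.center_s,
                     "length_mm": p.length,
                     "stenosis_fraction": p.stenosis_fraction,
                     "eccentric": p.eccentric} for p in plaques],
        "psg_definition": ("magnitude of the spatial pressure gradient "
                           "|grad p|, kg/(m^2 s^2)"),
    }
    return SummaryReport(meta=meta, arms=arm_summaries,
                         comparisons=comparisons)


@dataclass
class SummaryReport:
    """Serializable per-region, per-phase study summary."""

    meta: dict
    arms: dict
    comparisons: dict
    schema_version: int = 1

    def to_dict(self) -> dict:
        return {"schema_version": self.schema_version, "meta": self.meta,
                "arms": self.arms, "comparisons": self.comparisons}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SummaryReport":
        d = json.loads(text)
        return cls(meta=d["meta"], arms=d["arms"],
                   comparisons=d["comparisons"],
                   schema_version=d["schema_version"])
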