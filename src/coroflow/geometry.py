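"""Synthetic left-coronary bifurcation lumen geometry.

The left main stem (LMS) runs along +x and bifurcates into the left
anterior descending (LAD) and left circumflex (LCx) branches, which leave
the junction symmetrically at ``bifurcation_angle`` degrees to each other.
Each branch is a straight centerline with a signed half-width profile; the
assembled lumen is the union of the three strips with the reentrant junction
corners smoothed by a circular fillet (a morphological closing), standing in
for the smoothing a patient-specific surface would receive.

Plaques are raised-cosine intrusions of the wall: over the plaque extent
``|s - s0| <= L/2`` the local half-width is multiplied by

    f(s) = 1 - (delta/2) * (1 + cos(2*pi*(s - s0)/L))

so the minimum lumen diameter is ``(1 - delta) * D`` at the plaque center —
``delta = 0.6`` gives a 60% diameter stenosis.  All geometry coordinates are
in millimetres.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union

__all__ = [
    "VesselSpec",
    "PlaqueSpec",
    "SectionPlane",
    "LumenOutline",
    "GeometryError",
    "build_bifurcation",
    "apply_plaque",
    "measure_stenosis",
    "define_sections",
    "default_plaques",
]

BRANCHES = ("LMS", "LAD", "LCX")

#: arc-length sampling step for wall profiles, mm
WALL_DS = 0.025

#: labels of the 15 cross-section planes, grouped by branch
SECTION_GROUPS = {"LMS": "ABCDE", "LAD": "FGHIJ", "LCX": "KLMNO"}
SECTION_SPACING = 0.5  # mm between consecutive planes in a group


class GeometryError(ValueError):
    """Raised when a vessel/plaque configuration produces invalid geometry."""


@dataclass(frozen=True)
class VesselSpec:
    """Parametric description of the bifurcation (all lengths in mm).

    Defaults are typical adult left-coronary dimensions.
    """

    lms_diameter: float = 4.5
    lad_diameter: float = 3.5
    lcx_diameter: float = 3.0
    lms_length: float = 10.0
    lad_length: float = 25.0
    lcx_length: float = 25.0
    bifurcation_angle: float = 80.0  # degrees between LAD and LCx
    fillet_radius: float = 1.0  # junction smoothing radius

    def __post_init__(self) -> None:
        errors = []
        for name in ("lms_diameter", "lad_diameter", "lcx_diameter",
                     "lms_length", "lad_length", "lcx_length"):
            if getattr(self, name) <= 0:
                errors.append(f"{name} must be positive")
        if self.lad_diameter > self.lms_diameter:
            errors.append("lad_diameter must not exceed lms_diameter")
        if self.lcx_diameter > self.lms_diameter:
            errors.append("lcx_diameter must not exceed lms_diameter")
        if not (0.0 < self.bifurcation_angle < 180.0):
            errors.append("bifurcation_angle must lie in (0, 180) degrees")
        if self.fillet_radius < 0:
            errors.append("fillet_radius must be non-negative")
        if errors:
            raise GeometryError("; ".join(errors))

    def diameter(self, branch: str) -> float:
        return {"LMS": self.lms_diameter, "LAD": self.lad_diameter,
                "LCX": self.lcx_diameter}[branch]

    def length(self, branch: str) -> float:
        return {"LMS": self.lms_length, "LAD": self.lad_length,
                "LCX": self.lcx_length}[branch]


@dataclass(frozen=True)
class PlaqueSpec:
    """One plaque: a raised-cosine wall intrusion on a single branch.

    ``center_s`` is the arc-length position of the throat along the branch
    centerline (mm, measured from the branch origin; the junction is the
    origin of the daughter branches and the end of the LMS), ``length`` the
    full streamwise extent, and ``stenosis_fraction`` the fractional
    diameter reduction delta.  A symmetric plaque narrows both walls
    equally; an eccentric one narrows a single wall (and therefore requires
    delta < 0.5 so the wall does not cross the centerline).
    """

    branch: str
    center_s: float
    length: float
    stenosis_fraction: float
    eccentric: bool = False

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise GeometryError(f"unknown branch {self.branch!r}")
        if not (0.0 <= self.stenosis_fraction < 1.0):
            raise GeometryError("stenosis_fraction must lie in [0, 1)")
        if self.length <= 0:
            raise GeometryError("plaque length must be positive")
        if self.eccentric and self.stenosis_fraction >= 0.5:
            raise GeometryError(
                "eccentric plaques require stenosis_fraction < 0.5 "
                "(single wall cannot cross the centerline)")

    @property
    def extent(self) -> tuple[float, float]:
        return (self.center_s - 0.5 * self.length,
                self.center_s + 0.5 * self.length)


def default_plaques() -> list[PlaqueSpec]:
    """The study's default plaque pair: mid-LMS and proximal LAD, 60%."""
    return [
        PlaqueSpec(branch="LMS", center_s=5.0, length=4.0,
                   stenosis_fraction=0.6),
        PlaqueSpec(branch="LAD", center_s=6.0, length=4.0,
                   stenosis_fraction=0.6),
    ]


@dataclass
class _Branch:
    """One branch strip: straight centerline plus signed wall offsets."""

    name: str
    origin: np.ndarray  # (2,)
    direction: np.ndarray  # unit (2,)
    length: float
    diameter: float
    s: np.ndarray  # arc-length samples, 0 .. length
    half_left: np.ndarray  # wall offset on the +normal side
    half_right: np.ndarray  # wall offset on the -normal side

    @property
    def normal(self) -> np.ndarray:
        d = self.direction
        return np.array([-d[1], d[0]])

    def point(self, s):
        s = np.asarray(s, dtype=float)
        return self.origin + np.multiply.outer(s, self.direction)

    def width(self) -> np.ndarray:
        return self.half_left + self.half_right


@dataclass
class LumenOutline:
    """Assembled lumen: three branch strips, junction fillet, plaques."""

    spec: VesselSpec
    branches: dict
    plaques: list = field(default_factory=list)
    _polygon_cache: Polygon | None = field(default=None, repr=False)

    # -- frames ---------------------------------------------------------
    @property
    def junction(self) -> np.ndarray:
        lms = self.branches["LMS"]
        return lms.origin + lms.length * lms.direction

    def cap_segment(self, tag: str) -> tuple[np.ndarray, np.ndarray]:
        """End-cap segment (two points) for 'inlet'/'outlet_lad'/'outlet_lcx'."""
        if tag == "inlet":
            br, s = self.branches["LMS"], 0.0
        elif tag == "outlet_lad":
            br, s = self.branches["LAD"], self.branches["LAD"].length
        elif tag == "outlet_lcx":
            br, s = self.branches["LCX"], self.branches["LCX"].length
        else:
            raise KeyError(tag)
        c = br.point(s)
        i = 0 if s == 0.0 else -1
        return (c + br.half_left[i] * br.normal,
                c - br.half_right[i] * br.normal)

    # -- polygon assembly ----------------------------------------------
    def _strip_polygon(self, br: _Branch, back: float) -> Polygon:
        """Nominal constant-width strip, extended ``back`` mm behind s=0."""
        w = 0.5 * br.diameter
        n = br.normal
        p0 = br.point(-back)
        p1 = br.point(br.length)
        pts = [p0 + w * n, p1 + w * n, p1 - w * n, p0 - w * n]
        return Polygon(pts)

    def _carve_polygons(self, br: _Branch) -> list[Polygon]:
        """Regions between a narrowed wall and the nominal wall."""
        w_nom = 0.5 * br.diameter
        out = []
        for half, sign in ((br.half_left, 1.0), (br.half_right, -1.0)):
            narrowed = half < w_nom - 1e-12
            if not narrowed.any():
                continue
            idx = np.flatnonzero(narrowed)
            lo = max(idx[0] - 1, 0)
            hi = min(idx[-1] + 1, len(br.s) - 1)
            ss = br.s[lo:hi + 1]
            hw = half[lo:hi + 1]
            n = br.normal
            inner = br.point(ss) + sign * hw[:, None] * n
            outer_off = w_nom + 0.05  # just beyond the nominal wall
            outer = br.point(ss[::-1]) + sign * outer_off * n
            out.append(Polygon(np.vstack([inner, outer])))
        return out

    def polygon(self) -> Polygon:
        """Closed lumen polygon (nominal union + fillet, plaques carved)."""
        if self._polygon_cache is not None:
            return self._polygon_cache
        poly = self._filleted_base()
        for br in self.branches.values():
            for carve in self._carve_polygons(br):
                poly = poly.difference(carve)
        if poly.geom_type != "Polygon" or not poly.is_valid:
            raise GeometryError("plaque carving produced an invalid lumen")
        poly = Polygon(poly.exterior)  # drop any numerical-dust holes
        self._polygon_cache = poly
        return poly

    def _filleted_base(self) -> Polygon:
        back = 0.6 * self.spec.lms_diameter
        strips = [self._strip_polygon(self.branches["LMS"], 0.0),
                  self._strip_polygon(self.branches["LAD"], back),
                  self._strip_polygon(self.branches["LCX"], back)]
        base = unary_union(strips)
        if base.geom_type != "Polygon":
            raise GeometryError(
                "branch strips do not form a single connected lumen")
        r = self.spec.fillet_radius
        if r > 0:
            closed = base.buffer(r, quad_segs=24).buffer(-r, quad_segs=24)
        else:
            closed = base
        if closed.geom_type != "Polygon" or not closed.is_valid:
            raise GeometryError(
                "junction fillet produced a self-intersecting or "
                "disconnected outline (angle/fillet incompatible)")
        return Polygon(closed.exterior)

    # -- diagnostics ----------------------------------------------------
    def local_width(self, branch: str, s: float) -> float:
        """Lumen width measured on the assembled polygon at station s."""
        seg = self.section_segment(branch, s)
        return float(np.linalg.norm(seg[1] - seg[0]))

    def section_segment(self, branch: str, s: float):
        """Cross-lumen segment through station ``s``, spanning the true wall."""
        br = self.branches[branch]
        if not (0.0 <= s <= br.length):
            raise GeometryError(
                f"station s={s} outside branch {branch} (0..{br.length})")
        c = br.point(s)
        n = br.normal
        reach = 2.0 * self.spec.lms_diameter
        line = LineString([c - reach * n, c + reach * n])
        cut = line.intersection(self.polygon())
        pieces = ([cut] if cut.geom_type == "LineString"
                  else list(getattr(cut, "geoms", [])))
        centre = Point(c)
        best = None
        for g in pieces:
            if g.geom_type == "LineString" and g.distance(centre) < 1e-9:
                best = g
                break
        if best is None:
            raise GeometryError(
                f"section at {branch} s={s} does not intersect the lumen")
        p = np.asarray(best.coords)
        a, b = p[0], p[-1]
        # pull endpoints a hair inside so the segment is strictly interior
        eps = 1e-6
        u = (b - a) / np.linalg.norm(b - a)
        return a + eps * u, b - eps * u

    def nominal_wall_is_exposed(self, branch: str, s_lo: float,
                                s_hi: float) -> bool:
        """True if the nominal wall between s_lo..s_hi lies on the polygon
        boundary (i.e. the junction fillet does not reach into it)."""
        br = self.branches[branch]
        w = 0.5 * br.diameter
        boundary = self.polygon().exterior
        for s in np.linspace(max(s_lo, 0.0), min(s_hi, br.length), 17):
            c = br.point(s)
            for sign in (1.0, -1.0):
                pt = Point(c + sign * w * br.normal)
                if boundary.distance(pt) > 1e-6:
                    return False
        return True


def _make_branches(spec: VesselSpec) -> dict:
    lms_dir = np.array([1.0, 0.0])
    junction = np.array([spec.lms_length, 0.0])
    half = 0.5 * np.deg2rad(spec.bifurcation_angle)
    # LAD below the LMS axis, LCx above (the sign convention is arbitrary)
    lad_dir = np.array([np.cos(-half), np.sin(-half)])
    lcx_dir = np.array([np.cos(half), np.sin(half)])
    out = {}
    for name, origin, direction in (
            ("LMS", np.zeros(2), lms_dir),
            ("LAD", junction, lad_dir),
            ("LCX", junction, lcx_dir)):
        L = spec.length(name)
        D = spec.diameter(name)
        n = max(int(np.ceil(L / WALL_DS)), 8)
        s = np.linspace(0.0, L, n + 1)
        hw = np.full_like(s, 0.5 * D)
        out[name] = _Branch(name=name, origin=origin, direction=direction,
                            length=L, diameter=D, s=s,
                            half_left=hw.copy(), half_right=hw.copy())
    return out


def build_bifurcation(spec: VesselSpec) -> LumenOutline:
    """Assemble the plaque-free bifurcation outline and validate it.

    Raises :class:`GeometryError` with a diagnostic if the requested angle
    and fillet produce a self-intersecting or degenerate outline.
    """
    if spec.fillet_radius >= 0.5 * min(spec.lad_diameter, spec.lcx_diameter):
        raise GeometryError(
            f"fillet_radius {spec.fillet_radius} mm must be smaller than the "
            "smallest daughter radius "
            f"({0.5 * min(spec.lad_diameter, spec.lcx_diameter)} mm); a "
            "larger fillet can swallow a daughter ostium")
    outline = LumenOutline(spec=spec, branches=_make_branches(spec))
    poly = outline.polygon()
    if poly.interiors:
        raise GeometryError("outline contains holes")
    # the mid-span width of every branch must match its nominal diameter;
    # overlapping daughters or an over-aggressive fillet break this
    for name, br in outline.branches.items():
        got = outline.local_width(name, 0.5 * br.length)
        if abs(got - br.diameter) > 0.02 * br.diameter:
            raise GeometryError(
                f"{name} mid-span width {got:.3f} mm differs from the "
                f"requested diameter {br.diameter:.3f} mm: branches overlap "
                "or the fillet distorts the lumen (angle/fillet incompatible)")
    return outline


def apply_plaque(outline: LumenOutline, plaque: PlaqueSpec) -> LumenOutline:
    """Return a new outline with ``plaque`` carved into its branch wall."""
    br = outline.branches[plaque.branch]
    s_lo, s_hi = plaque.extent
    if s_lo < 0.0 or s_hi > br.length:
        raise GeometryError(
            f"plaque extent [{s_lo}, {s_hi}] mm exceeds branch "
            f"{plaque.branch} (length {br.length} mm)")
    for other in outline.plaques:
        if other.branch == plaque.branch:
            o_lo, o_hi = other.extent
            if s_lo < o_hi and o_lo < s_hi:
                raise GeometryError(
                    f"plaques overlap on branch {plaque.branch}")
    if not outline.nominal_wall_is_exposed(plaque.branch, s_lo, s_hi):
        raise GeometryError(
            f"plaque on {plaque.branch} at s={plaque.center_s} mm overlaps "
            "the junction fillet region; move it away from the bifurcation")

    new = copy.deepcopy(outline)
    new._polygon_cache = None
    nb = new.branches[plaque.branch]
    inside = np.abs(nb.s - plaque.center_s) <= 0.5 * plaque.length
    g = 0.5 * plaque.stenosis_fraction * (
        1.0 + np.cos(2.0 * np.pi * (nb.s[inside] - plaque.center_s)
                     / plaque.length))
    if plaque.eccentric:
        nb.half_left[inside] *= (1.0 - 2.0 * g)
    else:
        nb.half_left[inside] *= (1.0 - g)
        nb.half_right[inside] *= (1.0 - g)
    if (nb.half_left <= 0).any() or (nb.half_right <= 0).any():
        raise GeometryError("plaque closes the lumen completely")
    new.plaques = outline.plaques + [plaque]
    return new


def measure_stenosis(outline: LumenOutline, branch: str) -> float:
    """Percent diameter stenosis of ``branch``: 100*(1 - min width / D)."""
    br = outline.branches[branch]
    return 100.0 * (1.0 - float(br.width().min()) / br.diameter)


def define_sections(outline: LumenOutline, plaques=None,
                    lcx_group_center: float = 3.5) -> list["SectionPlane"]:
    """The fifteen cross-section planes A–O.

    A–E bracket the LMS plaque, F–J the LAD plaque, and K–O sample the
    proximal LCx; planes within a group are 0.5 mm apart.  ``plaques``
    defaults to the plaques already applied to ``outline`` — pass the plaque
    list explicitly to position the same planes on a plaque-free outline.
    """
    if plaques is None:
        plaques = outline.plaques
    centers = {}
    for p in plaques:
        centers[p.branch] = p.center_s
    centers.setdefault("LMS", 0.5 * outline.branches["LMS"].length)
    centers.setdefault("LAD", 6.0)
    centers["LCX"] = lcx_group_center
    planes = []
    for branch, labels in SECTION_GROUPS.items():
        br = outline.branches[branch]
        c = centers[branch]
        for i, label in enumerate(labels):
            s = c + (i - 2) * SECTION_SPACING
            if not (0.0 <= s <= br.length):
                raise GeometryError(
                    f"section {label} at s={s} mm falls outside branch "
                    f"{branch} (length {br.length} mm)")
            a, b = outline.section_segment(branch, s)
            planes.append(SectionPlane(label=label, branch=branch, s=s,
                                       start=a, end=b,
                                       streamwise=br.direction.copy()))
    return planes


@dataclass(frozen=True)
class SectionPlane:
    """One labelled cross-section: a segment spanning the local lumen."""

    label: str
    branch: str
    s: float  # arc-length station, mm
    start: np.ndarray  # (2,), mm
    end: np.ndarray  # (2,), mm
    streamwise: np.ndarray  # unit vector along the branch axis

    @property
    def width(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    def points(self, n: int = 51) -> np.ndarray:
        t = np.linspace(0.0, 1.0, n)[:, None]
        return self.start + t * (self.end - self.start)
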