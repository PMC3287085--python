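"""Triangular meshing of the lumen polygon.

The mesher places boundary nodes along the outline at a target spacing,
fills the interior with a staggered (near-equilateral) point lattice —
refined to ``h/2`` inside a band around each plaque — and triangulates the
point set with a Delaunay tessellation, discarding triangles whose centroid
falls outside the lumen.  A small seeded jitter on the interior lattice
avoids degenerate co-circular point sets, and makes the mesh a
deterministic function of (outline, h, seed).

Boundary edges are tagged ``inlet`` / ``outlet_lad`` / ``outlet_lcx`` on the
three end caps and ``wall`` elsewhere; the four tag sets partition the
boundary exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString, Polygon

__all__ = ["Mesh", "MeshError", "generate_mesh", "channel_mesh"]

BOUNDARY_TAGS = ("inlet", "outlet_lad", "outlet_lcx", "wall")


class MeshError(ValueError):
    """Raised when a valid mesh cannot be produced."""


@dataclass
class Mesh:
    """Triangulated lumen domain (coordinates in mm).

    ``boundary_edges`` are stored with the interior on their left, so the
    outward unit normal of edge (a, b) is ``(dy, -dx)/|ab|``.
    """

    points: np.ndarray  # (N, 2) node coordinates, mm
    triangles: np.ndarray  # (M, 3), positively oriented
    boundary_edges: np.ndarray  # (B, 2) node indices
    boundary_tags: np.ndarray  # (B,) strings from BOUNDARY_TAGS
    h: float  # characteristic element size, mm

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_lengths(self) -> np.ndarray:
        d = (self.points[self.boundary_edges[:, 1]]
             - self.points[self.boundary_edges[:, 0]])
        return np.hypot(d[:, 0], d[:, 1])

    def edge_normals(self) -> np.ndarray:
        """Outward unit normals of the boundary edges."""
        d = (self.points[self.boundary_edges[:, 1]]
             - self.points[self.boundary_edges[:, 0]])
        n = np.column_stack([d[:, 1], -d[:, 0]])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def edges_with_tag(self, tag: str) -> np.ndarray:
        return self.boundary_edges[self.boundary_tags == tag]

    def nodes_with_tag(self, tag: str) -> np.ndarray:
        return np.unique(self.edges_with_tag(tag))

    def triangle_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def validate(self) -> None:
        if (self.triangle_areas() <= 1e-12).any():
            raise MeshError("mesh contains zero-area triangles")
        # positive orientation
        p = self.points[self.triangles]
        cross = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                 - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
        if (cross <= 0).any():
            raise MeshError("mesh contains negatively oriented triangles")
        bad = ~np.isin(self.boundary_tags, BOUNDARY_TAGS)
        if bad.any():
            raise MeshError(f"unknown boundary tags: "
                            f"{set(self.boundary_tags[bad])}")


def _stagger_grid(bounds, spacing, rng, jitter=0.08):
    x0, y0, x1, y1 = bounds
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = []
    y = y0 + 0.5 * dy
    row = 0
    while y < y1:
        xs = np.arange(x0 + (0.25 + 0.5 * (row % 2)) * spacing, x1, spacing)
        pts = np.column_stack([xs, np.full_like(xs, y)])
        rows.append(pts)
        y += dy
        row += 1
    if not rows:
        return np.empty((0, 2))
    pts = np.vstack(rows)
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape) * spacing
    return pts


def _resample_chain(coords: np.ndarray, spacing: float) -> np.ndarray:
    """Resample an open polyline at ~``spacing``, keeping both endpoints."""
    seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    total = seg.sum()
    n = max(int(round(total / spacing)), 1)
    targets = np.linspace(0.0, total, n + 1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty((n + 1, 2))
    out[0], out[-1] = coords[0], coords[-1]
    for k in range(1, n):
        t = targets[k]
        i = np.searchsorted(cum, t) - 1
        i = min(max(i, 0), len(seg) - 1)
        f = (t - cum[i]) / max(seg[i], 1e-30)
        out[k] = coords[i] + f * (coords[i + 1] - coords[i])
    return out


def _point_segment_distance(pts, a, b):
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def _mesh_polygon(polygon: Polygon, cap_segments: dict, h: float,
                  refine_zones=None, seed: int = 0) -> Mesh:
    """Core mesher shared by the bifurcation and channel fixtures."""
    refine_zones = refine_zones or []
    rng = np.random.default_rng(seed)
    ring = np.asarray(polygon.exterior.coords)[:-1]

    # split the ring into chains at cap corner vertices, so the caps remain
    # exactly straight after resampling
    corner_pts = []
    for a, b in cap_segments.values():
        corner_pts.extend([np.asarray(a), np.asarray(b)])
    corner_idx = set()
    for c in corner_pts:
        i = int(np.argmin(np.linalg.norm(ring - c, axis=1)))
        # buffer-based filleting displaces convex corners by the sagitta of
        # its polygonal arcs (~1e-3 mm); snap back so caps stay exact
        if np.linalg.norm(ring[i] - c) < 0.01:
            ring[i] = c
        corner_idx.add(i)
    corner_idx = sorted(corner_idx)
    if not corner_idx:
        corner_idx = [0]
    ring = np.roll(ring, -corner_idx[0], axis=0)
    corner_idx = sorted({(i - corner_idx[0]) % len(ring) for i in corner_idx})

    def local_spacing(p):
        if any(zone.covers(shapely.points(p)) for zone in refine_zones):
            return 0.5 * h
        return h

    bpts = []
    breaks = corner_idx + [len(ring)]
    for k in range(len(breaks) - 1):
        chain = ring[breaks[k]:breaks[k + 1] + 1] if breaks[k + 1] < len(ring) \
            else np.vstack([ring[breaks[k]:], ring[:1]])
        mid = chain[len(chain) // 2]
        pts = _resample_chain(chain, local_spacing(mid))
        bpts.append(pts[:-1])  # endpoint repeats as next chain's start
    bpts = np.vstack(bpts)

    # interior lattices
    bounds = polygon.bounds
    inner_coarse = polygon.buffer(-0.62 * h)
    coarse = _stagger_grid(bounds, h, rng)
    keep = shapely.contains_xy(inner_coarse, coarse[:, 0], coarse[:, 1])
    if refine_zones:
        zone_union = shapely.unary_union(refine_zones)
        in_zone = shapely.contains_xy(zone_union, coarse[:, 0], coarse[:, 1])
        keep &= ~in_zone
        inner_fine = polygon.buffer(-0.31 * h)
        fine = _stagger_grid(bounds, 0.5 * h, rng)
        fkeep = shapely.contains_xy(inner_fine, fine[:, 0], fine[:, 1])
        fkeep &= shapely.contains_xy(zone_union, fine[:, 0], fine[:, 1])
        interior = np.vstack([coarse[keep], fine[fkeep]])
    else:
        interior = coarse[keep]

    # drop interior points that crowd a boundary node
    if len(interior):
        tree = cKDTree(bpts)
        d, _ = tree.query(interior)
        spac = np.array([local_spacing(p) for p in interior])
        interior = interior[d > 0.45 * spac]

    pts = np.vstack([bpts, interior])
    tri = Delaunay(pts)
    simplices = tri.simplices
    cx = pts[simplices].mean(axis=1)
    inside = shapely.contains_xy(polygon, cx[:, 0], cx[:, 1])
    simplices = simplices[inside]

    # boundary chains are straight to rounding error; Delaunay can emit
    # micro-slivers from three near-collinear boundary nodes — drop them
    p = pts[simplices]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    simplices = simplices[areas > 1e-6]

    # orient positively
    p = pts[simplices]
    cross = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))
    flip = cross < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]

    # compact unused nodes
    used = np.unique(simplices)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    simplices = remap[simplices]

    # boundary edges: edges owned by exactly one triangle, kept in the
    # owner's (CCW) order so the interior is on the left
    edges = np.vstack([simplices[:, [0, 1]], simplices[:, [1, 2]],
                       simplices[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    bedges = edges[counts[inv] == 1]

    tags = np.full(len(bedges), "wall", dtype=object)
    for tag, (a, b) in cap_segments.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        d0 = _point_segment_distance(pts[bedges[:, 0]], a, b)
        d1 = _point_segment_distance(pts[bedges[:, 1]], a, b)
        on_cap = (d0 < 1e-5) & (d1 < 1e-5)
        tags[on_cap] = tag
    tags = tags.astype(str)

    mesh = Mesh(points=pts, triangles=simplices, boundary_edges=bedges,
                boundary_tags=tags, h=h)
    mesh.validate()
    return mesh


def generate_mesh(outline, h: float, seed: int = 0) -> Mesh:
    """Mesh a lumen outline at target element size ``h`` (mm).

    A refinement band at ``h/2`` is placed around each plaque.  Rejects
    meshes too coarse to resolve the narrowest throat (fewer than ~3
    elements across).
    """
    if h <= 0:
        raise MeshError("h must be positive")
    min_width = min(float(br.width().min())
                    for br in outline.branches.values())
    if h > min_width / 3.0:
        raise MeshError(
            f"element size h={h} mm cannot resolve the minimum lumen width "
            f"{min_width:.3f} mm (need h <= {min_width / 3.0:.3f} mm)")
    zones = []
    for p in outline.plaques:
        br = outline.branches[p.branch]
        s_lo = max(p.center_s - p.length, 0.0)
        s_hi = min(p.center_s + p.length, br.length)
        axis = LineString([br.point(s_lo), br.point(s_hi)])
        zones.append(axis.buffer(0.75 * br.diameter))
    caps = {tag: outline.cap_segment(tag)
            for tag in ("inlet", "outlet_lad", "outlet_lcx")}
    return _mesh_polygon(outline.polygon(), caps, h,
                         refine_zones=zones, seed=seed)


def channel_mesh(length: float, height: float, h: float,
                 seed: int = 0) -> Mesh:
    """Straight-channel fixture mesh: inlet at x=0, outlet at x=length."""
    poly = Polygon([(0.0, 0.0), (length, 0.0), (length, height),
                    (0.0, height)])
    caps = {
        "inlet": (np.array([0.0, height]), np.array([0.0, 0.0])),
        "outlet_lad": (np.array([length, 0.0]), np.array([length, height])),
    }
    return _mesh_polygon(poly, caps, h, seed=seed)
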