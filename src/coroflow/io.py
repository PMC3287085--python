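"""Geometry and field export: binary STL, legacy VTK, CSV tables.

The 2-D lumen mesh is extruded to unit (1 mm) thickness for STL export so
that standard surface-mesh tools can open it; the result is watertight by
construction (caps from the triangulation, side walls from the boundary
edges).  Flow fields are written as ASCII legacy VTK unstructured grids,
readable by ParaView and meshio alike.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .meshing import Mesh

__all__ = ["export_stl", "load_stl", "write_vtk"]


def export_stl(mesh: Mesh, path, thickness: float = 1.0) -> "trimesh.Trimesh":
    """Write the lumen surface as a binary STL (mm units).

    The planar triangulation is extruded to ``thickness``: bottom and top
    caps plus quad side walls along the boundary edges, every edge shared
    by exactly two facets.
    """
    n = mesh.n_nodes
    bottom = np.column_stack([mesh.points, np.zeros(n)])
    top = np.column_stack([mesh.points, np.full(n, thickness)])
    verts = np.vstack([bottom, top])
    tri = mesh.triangles
    faces = [tri[:, ::-1],  # bottom cap, outward = -z
             tri + n]  # top cap, outward = +z
    for a, b in mesh.boundary_edges:
        # boundary edges run with the interior on the left, so (a, b, b+n)
        # winds outward
        faces.append(np.array([[a, b, b + n], [a, b + n, a + n]]))
    faces = np.vstack(faces)
    solid = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    solid.export(path, file_type="stl")
    return solid


def load_stl(path) -> "trimesh.Trimesh":
    return trimesh.load(path, file_type="stl", process=False)


def write_vtk(path, mesh: Mesh, point_data: dict | None = None) -> None:
    """ASCII legacy VTK unstructured grid with optional nodal fields.

    Scalar fields are (N,) arrays; vector fields (N, 2) are padded to 3-D.
    """
    point_data = point_data or {}
    n = mesh.n_nodes
    lines = ["# vtk DataFile Version 3.0", "coroflow field output", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {n} double"]
    for x, y in mesh.points:
        lines.append(f"{x:.9g} {y:.9g} 0")
    m = mesh.n_triangles
    lines.append(f"CELLS {m} {4 * m}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.9g} {v[1]:.9g} 0" for v in arr)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
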