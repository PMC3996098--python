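"""Legacy-ASCII VTK export/import of tagged meshes and field snapshots.

The writer stores triangles plus the tagged boundary edges as line cells,
with ``region_id``/``layer_id`` cell data (boundary lines carry the
boundary-tag code in ``region_id`` offset by 100) and the surface-fitted
(u, v) node coordinates as point data, so a written mesh can be read back
without loss of tagging.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshing import Mesh

__all__ = ["write_mesh_vtk", "read_mesh_vtk", "write_field_vtk"]

_BOUNDARY_TAGS = ("skin", "bone_interface", "top_flat")
_LINE_TAG_OFFSET = 100


def _header(n_points: int, nodes: np.ndarray, uv: np.ndarray) -> list[str]:
    lines = [
        "# vtk DataFile Version 3.0",
        "dtitherm heel mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n_points} double",
    ]
    for (x, y), (u, v) in zip(nodes, uv):
        lines.append(f"{x:.12e} {y:.12e} 0.0")
    return lines


def write_mesh_vtk(mesh: Mesh, path: str | Path, point_data: dict | None = None) -> None:
    tri = mesh.triangles
    edge_blocks = [(tag, mesh.boundary_edges[tag]) for tag in _BOUNDARY_TAGS]
    n_lines = sum(len(e) for _, e in edge_blocks)
    n_cells = len(tri) + n_lines

    lines = _header(mesh.n_nodes, mesh.nodes, mesh.uv)
    lines.append(f"CELLS {n_cells} {4 * len(tri) + 3 * n_lines}")
    for a, b, c in tri:
        lines.append(f"3 {a} {b} {c}")
    for _, edges in edge_blocks:
        for a, b in edges:
            lines.append(f"2 {a} {b}")
    lines.append(f"CELL_TYPES {n_cells}")
    lines += ["5"] * len(tri)
    lines += ["3"] * n_lines

    lines.append(f"CELL_DATA {n_cells}")
    lines.append("SCALARS region_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(r) for r in mesh.region_id]
    for ti, (_, edges) in enumerate(edge_blocks):
        lines += [str(_LINE_TAG_OFFSET + ti)] * len(edges)
    lines.append("SCALARS layer_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(r) for r in mesh.layer_id]
    lines += ["-1"] * n_lines

    lines.append(f"POINT_DATA {mesh.n_nodes}")
    lines.append("VECTORS uv double")
    for u, v in mesh.uv:
        lines.append(f"{u:.12e} {v:.12e} 0.0")
    if point_data:
        for name, arr in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{x:.10e}" for x in np.asarray(arr)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_vtk(mesh: Mesh, path: str | Path, fields: dict) -> None:
    """Mesh plus named nodal scalar fields (e.g. temperature snapshots)."""
    write_mesh_vtk(mesh, path, point_data=fields)


def read_mesh_vtk(path: str | Path) -> Mesh:
    tokens = Path(path).read_text().split()

    def find(word: str, start: int = 0) -> int:
        return tokens.index(word, start)

    i = find("POINTS")
    n_pts = int(tokens[i + 1])
    coords = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)
    nodes = coords[:, :2].copy()

    i = find("CELLS")
    n_cells = int(tokens[i + 1])
    total = int(tokens[i + 2])
    raw = np.array(tokens[i + 3 : i + 3 + total], dtype=int)
    cells, pos = [], 0
    for _ in range(n_cells):
        k = raw[pos]
        cells.append(raw[pos + 1 : pos + 1 + k])
        pos += k + 1

    i = find("SCALARS")  # region_id comes first
    region_all = np.array(tokens[i + 6 : i + 6 + n_cells], dtype=int)
    j = find("SCALARS", i + 1)
    layer_all = np.array(tokens[j + 6 : j + 6 + n_cells], dtype=int)
    u = find("VECTORS")
    uv = np.array(tokens[u + 3 : u + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)[:, :2]

    tri_mask = np.array([len(c) == 3 for c in cells])
    triangles = np.array([c for c in cells if len(c) == 3], dtype=np.int64)
    region_id = region_all[tri_mask]
    layer_id = layer_all[tri_mask]
    boundary_edges = {}
    for ti, tag in enumerate(_BOUNDARY_TAGS):
        sel = [c for c, r, m in zip(cells, region_all, tri_mask) if not m and r == _LINE_TAG_OFFSET + ti]
        boundary_edges[tag] = (
            np.array(sel, dtype=np.int64) if sel else np.empty((0, 2), dtype=np.int64)
        )

    skin_ids = np.unique(boundary_edges["skin"].ravel())
    order = np.argsort(uv[skin_ids, 0])
    skin_nodes = skin_ids[order]
    bone_ids = np.unique(boundary_edges["bone_interface"].ravel())
    bone_nodes = bone_ids[np.argsort(uv[bone_ids, 0])]
    return Mesh(
        nodes=nodes,
        uv=uv.copy(),
        triangles=triangles,
        region_id=region_id,
        layer_id=layer_id,
        boundary_edges=boundary_edges,
        skin_nodes=skin_nodes,
        skin_arc=uv[skin_nodes, 0].copy(),
        bone_nodes=bone_nodes,
    )
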