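"""Deterministic triangulation of the layered heel domain.

The mesher works in the surface-fitted (u, v) coordinates of
:class:`~dtitherm.geometry.HeelGeometry`: it lays down vertical *columns*
at arc positions u_i spanning the full depth of the soft-tissue band, puts
mandatory breakpoints on every column (skin, layer interfaces, bone, and
the column's crossings with the lesion / shell outlines), fills the gaps
to the requested element size, and triangulates each strip between
adjacent columns by merging the two node ladders in depth order.  The
construction is fully deterministic — identical inputs give identical
meshes — and conforming: layer interfaces are exact element edges and the
lesion outline is resolved polygonally through the per-column crossing
nodes.

Regions are tagged by element centroid (in parameter space), and each
element additionally records the *background layer* its centroid falls in,
which is what a healthy-stage lesion falls back to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import HeelGeometry
from .tissue import LAYER_NAMES, LayerSpec, layer_depth_bands

__all__ = ["Mesh", "MeshError", "generate_mesh", "arc_coordinate", "slab_mesh"]

REGION_NAMES: tuple[str, ...] = LAYER_NAMES + ("lesion_core", "lesion_shell")
_FINE_REGIONS = frozenset({"epidermis", "fat", "muscle", "lesion_core", "lesion_shell"})

# crossings closer than this to an interface/skin/bone are snapped onto it
_SNAP_TOL = 2.0e-5  # m


class MeshError(RuntimeError):
    pass


@dataclass
class Mesh:
    """Conforming triangulation with region and boundary tags.

    ``nodes`` are physical coordinates (m); ``uv`` the surface-fitted
    coordinates the mesh was built in.  ``region_id`` / ``layer_id`` index
    into :data:`REGION_NAMES` per triangle.  ``skin_nodes`` are the skin
    boundary nodes ordered by increasing arc coordinate ``skin_arc``.
    """

    nodes: np.ndarray
    uv: np.ndarray
    triangles: np.ndarray
    region_id: np.ndarray
    layer_id: np.ndarray
    boundary_edges: dict[str, np.ndarray]
    skin_nodes: np.ndarray
    skin_arc: np.ndarray
    bone_nodes: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def region_name(self) -> np.ndarray:
        return np.array(REGION_NAMES, dtype=object)[self.region_id]

    def layer_name(self) -> np.ndarray:
        return np.array(REGION_NAMES, dtype=object)[self.layer_id]

    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def uv_centroids(self) -> np.ndarray:
        return self.uv[self.triangles].mean(axis=1)

    def max_edge_lengths(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        e = np.stack(
            [
                np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
                np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
                np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
            ]
        )
        return e.max(axis=0)


def _column_positions(geom: HeelGeometry, h_fine: float) -> np.ndarray:
    """Arc positions of the mesh columns: quasi-uniform plus lesion anchors."""
    S = geom.total_arc
    du = 0.65 * h_fine
    n = max(4, math.ceil(S / du))
    base = np.linspace(0.0, S, n + 1)
    les = geom.lesion
    specials: list[float] = []
    if not les.is_degenerate:
        uc = geom.lesion_center_arc
        specials.append(uc)
        specials += [uc - les.d1 / 2.0, uc + les.d1 / 2.0]
        if les.stage.has_shell:
            half = les.d1 / 2.0 + les.shell_thickness
            specials += [uc - half, uc + half]
    keep = np.ones(len(base), bool)
    for s in specials:
        keep &= np.abs(base - s) >= 0.4 * du
    keep[0] = keep[-1] = True
    cols = np.sort(np.concatenate([base[keep], np.asarray(specials)]))
    return cols[(cols >= 0.0) & (cols <= S)]


def _column_breakpoints(geom: HeelGeometry, u: float) -> np.ndarray:
    """Mandatory node depths on one column, deduplicated and snapped."""
    D = geom.depth
    mandatory = np.array([0.0] + geom.interface_depths + [D])
    crossings = [c for c in geom.core_crossings(u) + geom.shell_crossings(u) if 0.0 < c < D]
    vals = list(mandatory)
    for c in crossings:
        if np.min(np.abs(mandatory - c)) < _SNAP_TOL:
            continue  # snap onto the nearby interface node
        vals.append(c)
    vals = np.sort(np.asarray(vals))
    # merge any residual near-duplicates (e.g. two crossings at a lesion tip)
    out = [vals[0]]
    for v in vals[1:]:
        if v - out[-1] < _SNAP_TOL:
            continue
        out.append(v)
    return np.asarray(out)


def _fill_column(
    geom: HeelGeometry, u: float, breaks: np.ndarray, h_fine: float, h_coarse: float
) -> np.ndarray:
    """Insert filler nodes between breakpoints to meet the size targets."""
    vs: list[float] = [breaks[0]]
    for v1, v2 in zip(breaks[:-1], breaks[1:]):
        region, _ = geom.region_at(u, 0.5 * (v1 + v2))
        target = 0.65 * (h_fine if region in _FINE_REGIONS else h_coarse)
        nsub = max(1, math.ceil((v2 - v1) / target))
        for j in range(1, nsub):
            vs.append(v1 + (v2 - v1) * j / nsub)
        vs.append(v2)
    return np.asarray(vs)


def _zip_strip(left: np.ndarray, right: np.ndarray, vleft: np.ndarray, vright: np.ndarray):
    """Triangulate the strip between two node ladders by depth-order merge."""
    tris = []
    i = j = 0
    while i < len(left) - 1 or j < len(right) - 1:
        adv_left = False
        if j >= len(right) - 1:
            adv_left = True
        elif i < len(left) - 1 and vleft[i + 1] <= vright[j + 1]:
            adv_left = True
        if adv_left:
            tris.append((left[i], right[j], left[i + 1]))
            i += 1
        else:
            tris.append((left[i], right[j], right[j + 1]))
            j += 1
    return tris


def generate_mesh(geom: HeelGeometry, h_fine: float = 1.3e-3, h_coarse: float = 2.4e-3) -> Mesh:
    """Triangulate the heel domain.

    ``h_fine`` bounds the element size in the epidermis, fat, muscle and
    lesion regions; ``h_coarse`` elsewhere (the dermis layers).
    """
    if not (0 < h_fine <= h_coarse):
        raise MeshError("require 0 < h_fine <= h_coarse")
    S = geom.total_arc
    # a laterally centred (or absent) lesion gives a mirror-symmetric domain;
    # build the left half and mirror it exactly, so that the triangulation
    # (and hence the discrete solution) is symmetric to round-off
    symmetric = geom.lesion.is_degenerate or geom.lesion_lateral_offset == 0.0
    cols_all = _column_positions(geom, h_fine)
    if symmetric:
        half = S / 2.0
        guard = 0.4 * 0.65 * h_fine
        left = cols_all[cols_all < half - guard]
        left = np.append(left, half)
        cols = np.concatenate([left, (S - left[:-1])[::-1]])
        left_vs = [
            _fill_column(geom, u, _column_breakpoints(geom, u), h_fine, h_coarse)
            for u in left
        ]
        col_vs = left_vs + [left_vs[i] for i in range(len(left) - 2, -1, -1)]
        n_left_strips = len(left) - 1
    else:
        cols = cols_all
        col_vs = [
            _fill_column(geom, u, _column_breakpoints(geom, u), h_fine, h_coarse)
            for u in cols
        ]
        n_left_strips = len(cols) - 1

    # global node numbering, column by column
    offsets = np.cumsum([0] + [len(v) for v in col_vs])
    uv = np.concatenate(
        [np.stack([np.full(len(v), u), v], axis=1) for u, v in zip(cols, col_vs)]
    )
    nodes = geom.to_physical(uv[:, 0], uv[:, 1])

    tris: list[tuple[int, int, int]] = []
    for c in range(len(cols) - 1):
        left_ids = np.arange(offsets[c], offsets[c + 1])
        right_ids = np.arange(offsets[c + 1], offsets[c + 2])
        if c < n_left_strips:
            tris += _zip_strip(left_ids, right_ids, col_vs[c], col_vs[c + 1])
        else:
            # mirrored strip: swap the ladder roles so the triangulation is
            # the exact mirror image of its left-half counterpart
            tris += _zip_strip(right_ids, left_ids, col_vs[c + 1], col_vs[c])
    triangles = np.asarray(tris, dtype=np.int64)

    # enforce counter-clockwise orientation in physical coordinates
    p = nodes[triangles]
    signed = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = signed < 0
    triangles[flip] = triangles[flip][:, [0, 2, 1]]
    if np.any(np.isclose(signed, 0.0, atol=1e-18)):
        raise MeshError("degenerate (zero-area) triangle produced; check geometry")

    # tag regions by parameter-space centroid
    cuv = uv[triangles].mean(axis=1)
    ridx = np.empty(len(triangles), dtype=np.int64)
    lidx = np.empty(len(triangles), dtype=np.int64)
    name_to_id = {n: i for i, n in enumerate(REGION_NAMES)}
    for e in range(len(triangles)):
        region, layer = geom.region_at(cuv[e, 0], cuv[e, 1])
        ridx[e] = name_to_id[region]
        lidx[e] = name_to_id[layer]

    # boundary edges
    tops = offsets[:-1]
    bottoms = offsets[1:] - 1
    skin_edges = np.stack([tops[:-1], tops[1:]], axis=1)
    bone_edges = np.stack([bottoms[:-1], bottoms[1:]], axis=1)
    first = np.arange(offsets[0], offsets[1])
    last = np.arange(offsets[-2], offsets[-1])
    flat_edges = np.concatenate(
        [np.stack([first[:-1], first[1:]], axis=1), np.stack([last[:-1], last[1:]], axis=1)]
    )
    return Mesh(
        nodes=nodes,
        uv=uv,
        triangles=triangles,
        region_id=ridx,
        layer_id=lidx,
        boundary_edges={
            "skin": skin_edges,
            "bone_interface": bone_edges,
            "top_flat": flat_edges,
        },
        skin_nodes=tops.astype(np.int64),
        skin_arc=cols.copy(),
        bone_nodes=bottoms.astype(np.int64),
    )


def arc_coordinate(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Skin boundary nodes and their arc-length coordinate l (m).

    l = 0 at the arc end with the lower x-coordinate, increasing along the
    heel periphery; the apex sits at half the total arc length.
    """
    edges = mesh.boundary_edges["skin"]
    counts = np.bincount(edges.ravel())
    if np.any(counts[counts > 0] > 2):
        raise MeshError("skin boundary is not a simple arc")
    ids, l = mesh.skin_nodes, mesh.skin_arc
    if mesh.nodes[ids[0], 0] > mesh.nodes[ids[-1], 0]:
        ids, l = ids[::-1], l[-1] - l[::-1]
    return ids, l


def slab_mesh(
    layers: list[LayerSpec],
    width: float = 1.0e-3,
    h: float = 0.25e-3,
    ny: int = 1,
) -> Mesh:
    """Pseudo-1D strip mesh through a layer stack (for slab verification).

    The strip runs in x from the skin (x = 0) to the bone interface
    (x = D) with lateral width ``width``; lateral sides are tagged
    ``top_flat`` (adiabatic), so the FEM solution is one-dimensional and
    comparable with the closed-form multilayer slab solution.
    """
    bands = layer_depth_bands(layers)
    xs = [0.0]
    for _, lo, hi in bands:
        nsub = max(1, math.ceil((hi - lo) / h))
        xs.extend(lo + (hi - lo) * np.arange(1, nsub + 1) / nsub)
    xs = np.asarray(xs)
    ys = np.linspace(0.0, width, ny + 1)
    nx = len(xs)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)

    def nid(i, j):
        return i * (ny + 1) + j

    tris, rids = [], []
    name_to_id = {n: i for i, n in enumerate(REGION_NAMES)}
    for i in range(nx - 1):
        xmid = 0.5 * (xs[i] + xs[i + 1])
        region = bands[-1][0]
        for nme, lo, hi in bands:
            if lo <= xmid < hi:
                region = nme
                break
        for j in range(ny):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            tris += [(a, b, c), (a, c, d)]
            rids += [name_to_id[region]] * 2
    triangles = np.asarray(tris, dtype=np.int64)
    region_id = np.asarray(rids, dtype=np.int64)

    skin_nodes = np.asarray([nid(0, j) for j in range(ny + 1)])
    bone_nodes = np.asarray([nid(nx - 1, j) for j in range(ny + 1)])
    skin_edges = np.stack([skin_nodes[:-1], skin_nodes[1:]], axis=1)
    bone_edges = np.stack([bone_nodes[:-1], bone_nodes[1:]], axis=1)
    side_lo = np.asarray([nid(i, 0) for i in range(nx)])
    side_hi = np.asarray([nid(i, ny) for i in range(nx)])
    flat_edges = np.concatenate(
        [
            np.stack([side_lo[:-1], side_lo[1:]], axis=1),
            np.stack([side_hi[:-1], side_hi[1:]], axis=1),
        ]
    )
    return Mesh(
        nodes=nodes,
        uv=nodes[:, ::-1].copy(),  # (u, v) = (lateral, depth)
        triangles=triangles,
        region_id=region_id,
        layer_id=region_id.copy(),
        boundary_edges={
            "skin": skin_edges,
            "bone_interface": bone_edges,
            "top_flat": flat_edges,
        },
        skin_nodes=skin_nodes,
        skin_arc=ys.copy(),
        bone_nodes=bone_nodes,
    )
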