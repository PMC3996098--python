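"""Mesh generation: conformity, tagging, sizes, arc coordinate, slab, VTK."""

import numpy as np
import pytest
from shapely.geometry import Polygon

import dtitherm as dt
from dtitherm.meshing import arc_coordinate, generate_mesh, slab_mesh
from dtitherm.geometry import build_geometry
from dtitherm.tissue import LesionSpec, LesionStage, default_layers
from dtitherm.vtk_io import read_mesh_vtk, write_mesh_vtk


@pytest.fixture(scope="module")
def mesh8(default_model):
    return default_model[1]


@pytest.fixture(scope="module")
def geom8(default_model):
    return default_model[0]


def test_area_conservation(mesh8):
    """Triangle areas sum exactly to the area of the meshed boundary polygon."""
    # the boundary polygon is built independently (shapely) from the tagged
    # boundary: skin arc, flat top ends, bone interface arc
    skin = mesh8.nodes[mesh8.skin_nodes]
    bone = mesh8.nodes[mesh8.bone_nodes][::-1]
    poly = Polygon(np.vstack([skin, bone]))
    assert poly.is_valid
    assert mesh8.areas().sum() == pytest.approx(poly.area, rel=1e-10)


def test_mesh_is_conforming(mesh8):
    """Every interior edge is shared by exactly two triangles, every tagged
    boundary edge by exactly one."""
    from collections import Counter

    count = Counter()
    for tri in mesh8.triangles:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            count[frozenset((int(a), int(b)))] += 1
    assert set(count.values()) <= {1, 2}
    boundary = [e for e, c in count.items() if c == 1]
    tagged = set()
    for edges in mesh8.boundary_edges.values():
        for a, b in edges:
            tagged.add(frozenset((int(a), int(b))))
    assert set(boundary) == tagged


def test_region_tags_partition_and_match_centroids(mesh8, geom8):
    """Region tagging is consistent with pointwise membership at centroids,
    and every lesion-core centroid lies inside the lesion outline."""
    cuv = mesh8.uv_centroids()
    names = mesh8.region_name()
    in_core = geom8.in_lesion_core(cuv[:, 0], cuv[:, 1])
    assert np.array_equal(in_core, names == "lesion_core")
    # lesion area (in the surface-fitted frame the lesion is an ellipse)
    # is close to pi*r1*r2
    p = mesh8.uv[mesh8.triangles]
    uv_areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    core_area = uv_areas[names == "lesion_core"].sum()
    ellipse_area = np.pi * (geom8.lesion.d1 / 2) * (geom8.lesion.d2 / 2)
    assert core_area == pytest.approx(ellipse_area, rel=0.05)


def test_element_size_bounds(mesh8):
    h_fine, h_coarse = 1.3e-3, 2.4e-3
    fine = np.isin(
        mesh8.region_name(), ["epidermis", "fat", "muscle", "lesion_core", "lesion_shell"]
    )
    edges = mesh8.max_edge_lengths()
    assert edges[fine].max() <= h_fine * 1.0001
    assert edges.max() <= h_coarse * 1.0001


def test_element_count_matches_reference_resolution(mesh8):
    """Default sizes give an element count within a factor ~2 of the 4932
    free triangles of the reference discretization."""
    assert 4932 / 2 <= mesh8.n_elements <= 4932 * 2


def test_arc_coordinate_properties(mesh8, geom8):
    ids, l = arc_coordinate(mesh8)
    assert np.all(np.diff(l) > 0)
    # l = 0 at the end with the lower x coordinate
    assert mesh8.nodes[ids[0], 0] == pytest.approx(-geom8.a_out, abs=1e-9)
    # total length equals the semi-ellipse perimeter within 0.1%
    from dtitherm.geometry import ellipse_half_perimeter

    assert l[-1] == pytest.approx(ellipse_half_perimeter(geom8.a_out, geom8.b_out), rel=1e-3)
    # apex maps to half the total arc length
    apex = ids[np.argmin(mesh8.nodes[ids, 1])]
    assert l[list(ids).index(apex)] == pytest.approx(l[-1] / 2, abs=1e-3)


def test_degenerate_lesion_mesh_equals_healthy_mesh():
    layers = default_layers()
    g0 = build_geometry(layers, LesionSpec(stage=LesionStage.HEALTHY, d1=0.0, d2=0.0))
    g1 = build_geometry(layers, LesionSpec(stage=LesionStage.ISCHEMIA, d1=0.0, d2=0.0))
    m0 = generate_mesh(g0)
    m1 = generate_mesh(g1)
    np.testing.assert_array_equal(m0.triangles, m1.triangles)
    np.testing.assert_array_equal(m0.nodes, m1.nodes)
    np.testing.assert_array_equal(m0.region_id, m1.region_id)


def test_mesh_is_deterministic(geom8):
    a = generate_mesh(geom8)
    b = generate_mesh(geom8)
    np.testing.assert_array_equal(a.nodes, b.nodes)
    np.testing.assert_array_equal(a.triangles, b.triangles)


def test_multilayer_shell_tagged(default_model):
    geom, _, layers = default_model
    gm = build_geometry(
        layers, LesionSpec(stage=LesionStage.MULTILAYER_MILD, center_depth=0.008)
    )
    mesh = generate_mesh(gm)
    names = set(mesh.region_name())
    assert "lesion_core" in names and "lesion_shell" in names


def test_slab_mesh_structure():
    layers = default_layers()
    mesh = slab_mesh(layers, width=1e-3, h=0.25e-3)
    assert mesh.areas().sum() == pytest.approx(11.3e-3 * 1e-3, rel=1e-12)
    # every layer is present with the right depth share
    areas = mesh.areas()
    names = mesh.region_name()
    for layer in layers:
        share = areas[names == layer.name].sum() / areas.sum()
        assert share == pytest.approx(layer.thickness / 11.3e-3, rel=1e-9)


def test_vtk_round_trip(tmp_path, mesh8):
    path = tmp_path / "mesh.vtk"
    write_mesh_vtk(mesh8, path)
    back = read_mesh_vtk(path)
    np.testing.assert_allclose(back.nodes, mesh8.nodes, atol=1e-15)
    np.testing.assert_array_equal(back.triangles, mesh8.triangles)
    np.testing.assert_array_equal(back.region_id, mesh8.region_id)
    np.testing.assert_array_equal(back.skin_nodes, mesh8.skin_nodes)
    for tag in mesh8.boundary_edges:
        np.testing.assert_array_equal(back.boundary_edges[tag], mesh8.boundary_edges[tag])
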