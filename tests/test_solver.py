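"""FEM assembly and solution: element matrices, oracles, conservation."""

import numpy as np
import pytest

import dtitherm as dt
from dtitherm.meshing import Mesh, slab_mesh
from dtitherm.solver import (
    Adiabatic,
    Convective,
    Dirichlet,
    ElementProperties,
    Phase,
    assemble,
    element_properties,
    solve_steady,
    solve_transient,
    steady_energy_balance,
)
from dtitherm.tissue import (
    ConfigurationError,
    LayerSpec,
    LesionStage,
    MaterialProperties,
    default_layers,
    with_overrides,
)

from oracles import halfspace_step_cooling, multilayer_slab_steady


def _single_triangle_mesh():
    """Unit right triangle tagged as muscle, all edges on one boundary."""
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    tris = np.array([[0, 1, 2]])
    edges = np.array([[0, 1], [1, 2], [2, 0]])
    return Mesh(
        nodes=nodes,
        uv=nodes.copy(),
        triangles=tris,
        region_id=np.array([4]),  # muscle
        layer_id=np.array([4]),
        boundary_edges={"skin": edges},
        skin_nodes=np.array([0, 1, 2]),
        skin_arc=np.array([0.0, 1.0, 2.0]),
        bone_nodes=np.array([], dtype=np.int64),
    )


def _uniform_props(n, k=1.0, rho_c=1.0, perf=0.0, q=0.0, T_b=37.0):
    return ElementProperties(
        k=np.full(n, k),
        rho_c=np.full(n, rho_c),
        perf=np.full(n, perf),
        q_met=np.full(n, q),
        T_b=np.full(n, T_b),
    )


def test_reference_triangle_stiffness_matrix():
    """Unit conductivity on the unit right triangle gives the textbook P1
    stiffness matrix."""
    mesh = _single_triangle_mesh()
    system = assemble(mesh, _uniform_props(1), {"skin": Adiabatic()})
    expected = np.array([[1.0, -0.5, -0.5], [-0.5, 0.5, 0.0], [-0.5, 0.0, 0.5]])
    np.testing.assert_allclose(system.K.toarray(), expected, atol=1e-14)


def test_stiffness_row_sums_vanish_without_reaction_terms():
    """Pure conduction with adiabatic boundaries keeps constants in the
    nullspace: K row sums are zero."""
    mesh = slab_mesh(default_layers(), h=0.5e-3, ny=2)
    props = _uniform_props(mesh.n_elements, k=0.4)
    bc = {t: Adiabatic() for t in mesh.boundary_edges}
    system = assemble(mesh, props, bc)
    np.testing.assert_allclose(np.asarray(system.K.sum(axis=1)).ravel(), 0.0, atol=1e-12)


def test_perfusion_adds_area_thirds_to_row_sums():
    """The perfusion reaction contributes w * A/3 per node (row sum of the
    consistent mass block), the mass-lumping value."""
    mesh = _single_triangle_mesh()
    w = 5.0
    props = _uniform_props(1, perf=w)
    system = assemble(mesh, props, {"skin": Adiabatic()})
    K_perf = system.components["K_perf"].toarray()
    np.testing.assert_allclose(K_perf.sum(axis=1), w * 0.5 / 3.0, rtol=1e-14)
    # and the consistent-matrix diagonal is w * A/6
    np.testing.assert_allclose(np.diag(K_perf), w * 0.5 / 6.0, rtol=1e-14)


def test_uniform_dirichlet_gives_uniform_field():
    """All boundaries at 37 degC, no sources or perfusion: T = 37."""
    mesh = slab_mesh(default_layers(), h=0.5e-3)
    props = _uniform_props(mesh.n_elements, k=0.4, rho_c=3e6)
    bc = {
        "skin": Dirichlet(37.0),
        "bone_interface": Dirichlet(37.0),
        "top_flat": Adiabatic(),
    }
    field = solve_steady(assemble(mesh, props, bc))
    np.testing.assert_allclose(field.values, 37.0, atol=1e-10)


def test_all_adiabatic_without_perfusion_is_singular():
    mesh = slab_mesh(default_layers(), h=0.5e-3)
    props = _uniform_props(mesh.n_elements, k=0.4)
    bc = {t: Adiabatic() for t in mesh.boundary_edges}
    with pytest.raises((ConfigurationError, dt.solver.SolverError)):
        solve_steady(assemble(mesh, props, bc))


def test_missing_property_and_boundary_coverage_errors():
    mesh = slab_mesh(default_layers(), h=0.5e-3)
    with pytest.raises(ConfigurationError):
        assemble(mesh, {"muscle": MaterialProperties(rho=1085, c=3600, k=0.51)}, {})
    props = _uniform_props(mesh.n_elements)
    with pytest.raises(ConfigurationError):
        assemble(mesh, props, {"skin": Adiabatic()})  # uncovered tags
    with pytest.raises(ConfigurationError):
        assemble(
            mesh,
            props,
            {
                "skin": Adiabatic(),
                "bone_interface": Adiabatic(),
                "top_flat": Adiabatic(),
                "ghost": Adiabatic(),
            },
        )


def test_steady_matches_multilayer_slab_oracle():
    """Pseudo-1D FEM vs the closed-form perfusion-slab solution: < 0.01 degC."""
    layers = default_layers()
    mesh = slab_mesh(layers, h=0.1e-3)
    props = element_properties(mesh, LesionStage.HEALTHY, layers=layers)
    bc = {
        "skin": Convective(12.0, 22.0),
        "bone_interface": Dirichlet(37.0),
        "top_flat": Adiabatic(),
    }
    field = solve_steady(assemble(mesh, props, bc))
    x = mesh.nodes[:, 0]
    oracle = multilayer_slab_steady(layers, 12.0, 22.0, 37.0, x)
    assert np.abs(field.values - oracle).max() < 0.01


def test_transient_matches_halfspace_erf_oracle():
    """Step surface cooling of a deep conduction-only slab follows the erf
    similarity solution at early times to < 2% of the applied step."""
    muscle = default_layers()[-1]
    props_nope = with_overrides(muscle.props, omega_b=0.0, q_met=0.0)
    deep = [LayerSpec(name="muscle", thickness=0.05, props=props_nope)]
    mesh = slab_mesh(deep, h=0.25e-3)
    props = element_properties(mesh, LesionStage.HEALTHY, layers=deep)
    T_i, T_s, t_end = 37.0, 15.0, 10.0
    bc = {
        "skin": Dirichlet(T_s),
        "bone_interface": Dirichlet(T_i),
        "top_flat": Adiabatic(),
    }
    T0 = dt.TemperatureField(time=0.0, values=np.full(mesh.n_nodes, T_i))
    snaps = solve_transient(
        mesh, props, [Phase(0.0, t_end, 0.05, bc)], T0, snapshot_times=[t_end]
    )
    alpha = props_nope.k / (props_nope.rho * props_nope.c)
    oracle = halfspace_step_cooling(mesh.nodes[:, 0], t_end, T_i, T_s, alpha)
    err = np.abs(snaps[-1].values - oracle).max()
    assert err < 0.02 * (T_i - T_s)


def test_transient_fixed_point_at_steady_state(default_model):
    """Starting from the steady field with unchanged BCs, the field stays
    constant to within 1e-8 degC."""
    geom, mesh, layers = default_model
    props = element_properties(mesh, LesionStage.HEALTHY, layers=layers)
    bc = {
        "skin": Convective(12.0, 22.0),
        "bone_interface": Dirichlet(37.0),
        "top_flat": Adiabatic(),
    }
    steady = solve_steady(assemble(mesh, props, bc))
    snaps = solve_transient(
        mesh, props, [Phase(0.0, 5.0, 0.1, bc)], steady, snapshot_times=[5.0]
    )
    assert np.abs(snaps[-1].values - steady.values).max() < 1e-8


def test_steady_energy_balance(default_model):
    """Metabolic + net perfusion + net convective heat equals the flux
    extracted at the Dirichlet core boundary, to 1e-8 relative."""
    geom, mesh, layers = default_model
    props = element_properties(mesh, LesionStage.ISCHEMIA, layers=layers)
    bc = {
        "skin": Convective(12.0, 22.0),
        "bone_interface": Dirichlet(37.0),
        "top_flat": Adiabatic(),
    }
    system = assemble(mesh, props, bc)
    field = solve_steady(system)
    bal = steady_energy_balance(system, field)
    scale = max(abs(bal["metabolic"]), abs(bal["convective_net"]), abs(bal["dirichlet_outflow"]))
    assert abs(bal["imbalance"]) < 1e-8 * scale


def test_steady_skin_temperatures_within_physical_bounds(default_model):
    """Maximum principle: with 22 degC ambient and a 37 degC core, steady
    skin temperatures lie strictly between the two."""
    geom, mesh, layers = default_model
    props = element_properties(mesh, LesionStage.HEALTHY, layers=layers)
    bc = {
        "skin": Convective(12.0, 22.0),
        "bone_interface": Dirichlet(37.0),
        "top_flat": Adiabatic(),
    }
    field = solve_steady(assemble(mesh, props, bc))
    skin = field.values[mesh.skin_nodes]
    assert np.all(skin > 22.0) and np.all(skin < 37.0)
    assert np.all(field.values >= 14.9) and np.all(field.values <= 45.0)


def test_dict_props_assembly_equivalent(default_model):
    """Assembling from a region->properties mapping matches the resolved
    per-element route when no healthy-stage fallback is involved."""
    geom, mesh, layers = default_model
    table = {l.name: l.props for l in layers}
    table["lesion_core"] = dt.properties_for("lesion_core", LesionStage.ISCHEMIA)
    bc = {
        "skin": Convective(12.0, 22.0),
        "bone_interface": Dirichlet(37.0),
        "top_flat": Adiabatic(),
    }
    sys_a = assemble(mesh, table, bc)
    props = element_properties(mesh, LesionStage.ISCHEMIA, layers=layers)
    sys_b = assemble(mesh, props, bc)
    assert abs(sys_a.K - sys_b.K).max() < 1e-12
    np.testing.assert_allclose(sys_a.f, sys_b.f, rtol=1e-14)
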