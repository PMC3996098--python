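"""Property tables, lesion staging and layer classification."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtitherm.tissue import (
    ConfigurationError,
    GeometryError,
    LesionSpec,
    LesionStage,
    MaterialProperties,
    classify_lesion_layers,
    default_layers,
    layer_at_depth,
    layer_depth_bands,
    properties_for,
    soft_tissue_thickness,
)


@pytest.mark.parametrize(
    "region, stage, expected",
    [
        # (region, stage) -> selected field values
        ("muscle", LesionStage.HEALTHY, dict(k=0.51, omega_b=2.7e-3, q_met=684.2, T_b=37.0)),
        (
            "lesion_core",
            LesionStage.ISCHEMIA,
            dict(k=0.1, omega_b=0.405e-3, q_met=342.1, T_b=35.0, c=2450.0, rho=1037.0),
        ),
        (
            "lesion_core",
            LesionStage.INFLAMMATION,
            dict(k=0.558, omega_b=6.95e-3, q_met=5262.5, T_b=37.0),
        ),
        ("epidermis", LesionStage.HEALTHY, dict(omega_b=0.0, q_met=0.0)),
        ("fat", LesionStage.HEALTHY, dict(k=0.185, rho=1000.0, c=2674.0, omega_b=0.08e-3)),
        ("papillary_dermis", LesionStage.HEALTHY, dict(k=0.445, omega_b=0.18e-3, q_met=368.1)),
        ("reticular_dermis", LesionStage.HEALTHY, dict(omega_b=1.26e-3)),
        ("lesion_shell", LesionStage.MULTILAYER_MILD, dict(k=0.558, omega_b=6.95e-3)),
        ("lesion_core", LesionStage.MULTILAYER_SEVERE, dict(k=0.1, T_b=35.0)),
    ],
)
def test_property_table_round_trip(region, stage, expected):
    """Every default property equals the published table cell exactly."""
    props = properties_for(region, stage)
    for name, value in expected.items():
        assert getattr(props, name) == pytest.approx(value, abs=0.0), name


def test_default_stack_thickness():
    layers = default_layers()
    assert soft_tissue_thickness(layers) == pytest.approx(11.3e-3)
    assert [l.name for l in layers] == [
        "epidermis",
        "papillary_dermis",
        "reticular_dermis",
        "fat",
        "muscle",
    ]


def test_healthy_stage_is_thermally_invisible():
    """Healthy-stage lesion points inherit the enclosing layer's row."""
    layers = default_layers()
    for name in ("fat", "muscle", "reticular_dermis"):
        got = properties_for("lesion_core", LesionStage.HEALTHY, enclosing_layer=name)
        assert got == properties_for(name)
        got = properties_for("lesion_shell", LesionStage.HEALTHY, enclosing_layer=name)
        assert got == properties_for(name)
    with pytest.raises(ConfigurationError):
        properties_for("lesion_core", LesionStage.HEALTHY)


def test_region_and_shell_errors():
    with pytest.raises(ConfigurationError):
        properties_for("bone", LesionStage.HEALTHY)
    with pytest.raises(ConfigurationError):
        properties_for("lesion_shell", LesionStage.ISCHEMIA)


@pytest.mark.parametrize(
    "depth_mm, expected",
    [
        (8.0, {"fat", "muscle"}),
        (6.0, {"fat"}),
        (3.8, {"reticular_dermis", "fat"}),
    ],
)
def test_classify_lesion_layers_study_depths(depth_mm, expected):
    lesion = LesionSpec(stage=LesionStage.ISCHEMIA, center_depth=depth_mm * 1e-3)
    assert classify_lesion_layers(lesion, default_layers()) == expected


def test_lesion_outside_soft_tissue_rejected():
    layers = default_layers()
    with pytest.raises(GeometryError):
        classify_lesion_layers(
            LesionSpec(stage=LesionStage.ISCHEMIA, center_depth=11.0e-3), layers
        )
    with pytest.raises(GeometryError):
        classify_lesion_layers(
            LesionSpec(stage=LesionStage.ISCHEMIA, center_depth=0.5e-3), layers
        )


@settings(derandomize=True, max_examples=100)
@given(depth_mm=st.floats(min_value=1.3, max_value=10.0))
def test_classify_matches_pointwise_membership(depth_mm):
    """A layer is reported iff some depth inside the lesion span lies in it."""
    layers = default_layers()
    lesion = LesionSpec(stage=LesionStage.ISCHEMIA, center_depth=depth_mm * 1e-3)
    got = classify_lesion_layers(lesion, layers)
    # independent check: dense sampling of the lesion's depth interval
    import numpy as np

    samples = np.linspace(lesion.depth_top + 1e-9, lesion.depth_bottom - 1e-9, 512)
    sampled = {layer_at_depth(d, layers) for d in samples}
    assert sampled == got


def test_material_invariants_enforced():
    with pytest.raises(ConfigurationError):
        MaterialProperties(rho=-1.0, c=3300.0, k=0.4)
    with pytest.raises(ConfigurationError):
        MaterialProperties(rho=1000.0, c=3300.0, k=0.4, omega_b=-1e-3)
    with pytest.raises(ConfigurationError):
        # perfused tissue with implausible arterial temperature
        MaterialProperties(rho=1000.0, c=3300.0, k=0.4, omega_b=1e-3, T_b=50.0)


def test_depth_bands_are_contiguous():
    bands = layer_depth_bands(default_layers())
    for (_, _, hi), (_, lo, _) in zip(bands[:-1], bands[1:]):
        assert hi == pytest.approx(lo)
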