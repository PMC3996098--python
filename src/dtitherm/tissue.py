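"""Thermophysical tissue model for the layered heel cross-section.

The heel soft tissue is represented as five homogeneous layers (epidermis,
papillary dermis, reticular dermis, fat, muscle) stacked from the skin
surface down to the muscle--bone interface, plus an embedded elliptical
deep-tissue-injury (DTI) lesion.  Each region carries the coefficients of
the Pennes bioheat equation

    rho c dT/dt = div(k grad T) + omega_b rho_b c_b (T_b - T) + q_met

with piecewise-constant properties per region.  The lesion is staged:
``ischemia`` (cold signature: low conductivity, reduced metabolism, cooler
arterial supply), ``inflammation`` (hot signature: raised conductivity,
perfusion and metabolism), or a multilayer combination of an ischemic core
wrapped in an inflammation shell.  A ``healthy`` stage makes the lesion
thermally invisible: every point falls back to the enclosing layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable

__all__ = [
    "MaterialProperties",
    "LayerSpec",
    "LesionStage",
    "LesionSpec",
    "ConfigurationError",
    "GeometryError",
    "BLOOD_DENSITY",
    "BLOOD_SPECIFIC_HEAT",
    "default_layers",
    "lesion_core_properties",
    "lesion_shell_properties",
    "properties_for",
    "classify_lesion_layers",
    "layer_depth_bands",
    "layer_at_depth",
    "soft_tissue_thickness",
]


class ConfigurationError(ValueError):
    """Invalid tissue/lesion configuration."""


class GeometryError(ValueError):
    """Geometrically inadmissible lesion or domain."""


# Blood properties entering the perfusion term.  Standard values for whole
# blood; not layer specific.
BLOOD_DENSITY = 1060.0  # kg/m^3
BLOOD_SPECIFIC_HEAT = 3770.0  # J/(kg K)


@dataclass(frozen=True)
class MaterialProperties:
    """Pennes-equation coefficients of one homogeneous tissue region.

    Attributes
    ----------
    rho : float
        Tissue density, kg/m^3.
    c : float
        Tissue specific heat, J/(kg K).
    k : float
        Thermal conductivity, W/(m K).
    omega_b : float
        Blood perfusion rate, 1/s.
    rho_b, c_b : float
        Blood density (kg/m^3) and specific heat (J/(kg K)).
    T_b : float
        Arterial blood temperature, degC (ignored when ``omega_b == 0``).
    q_met : float
        Metabolic heat generation, W/m^3.
    """

    rho: float
    c: float
    k: float
    omega_b: float = 0.0
    rho_b: float = BLOOD_DENSITY
    c_b: float = BLOOD_SPECIFIC_HEAT
    T_b: float = 37.0
    q_met: float = 0.0

    def __post_init__(self) -> None:
        if not (self.rho > 0 and self.c > 0 and self.k > 0):
            raise ConfigurationError(
                f"rho, c, k must be positive, got {self.rho}, {self.c}, {self.k}"
            )
        if self.omega_b < 0:
            raise ConfigurationError(f"omega_b must be >= 0, got {self.omega_b}")
        if self.q_met < 0:
            raise ConfigurationError(f"q_met must be >= 0, got {self.q_met}")
        if self.omega_b > 0 and not (30.0 <= self.T_b <= 40.0):
            raise ConfigurationError(
                f"arterial temperature {self.T_b} degC implausible for perfused tissue"
            )

    @property
    def perfusion_coefficient(self) -> float:
        """omega_b * rho_b * c_b, W/(m^3 K) — the volumetric heat-sink slope."""
        return self.omega_b * self.rho_b * self.c_b


@dataclass(frozen=True)
class LayerSpec:
    """One tissue layer: name, thickness (m) and material properties."""

    name: str
    thickness: float
    props: MaterialProperties

    def __post_init__(self) -> None:
        if self.name not in LAYER_NAMES:
            raise ConfigurationError(f"unknown layer name {self.name!r}")
        if not self.thickness > 0:
            raise ConfigurationError(f"layer {self.name}: thickness must be > 0")


class LesionStage(str, Enum):
    HEALTHY = "healthy"
    ISCHEMIA = "ischemia"
    INFLAMMATION = "inflammation"
    MULTILAYER_MILD = "multilayer_mild"
    MULTILAYER_SEVERE = "multilayer_severe"

    @property
    def has_shell(self) -> bool:
        return self in (LesionStage.MULTILAYER_MILD, LesionStage.MULTILAYER_SEVERE)


@dataclass(frozen=True)
class LesionSpec:
    """Elliptical DTI lesion embedded in the soft tissue.

    ``center_depth`` is the depth of the lesion *center* below the skin
    surface, measured along the symmetry axis; ``d1``/``d2`` are the full
    major (tangential) and minor (depth-wise) axes.  Multilayer stages add
    an inflammation shell of ``shell_thickness`` around the ischemic core.
    All lengths in meters.
    """

    stage: LesionStage = LesionStage.HEALTHY
    center_depth: float = 0.008
    d1: float = 0.015
    d2: float = 0.0025
    shell_thickness: float = 0.00125

    def __post_init__(self) -> None:
        if self.d1 < 0 or self.d2 < 0:
            raise ConfigurationError("lesion axes must be non-negative")
        if self.stage.has_shell and not self.shell_thickness > 0:
            raise ConfigurationError("multilayer stage requires shell_thickness > 0")

    @property
    def is_degenerate(self) -> bool:
        """Zero-size lesion: thermally and geometrically absent."""
        return self.d1 == 0.0 or self.d2 == 0.0

    @property
    def depth_top(self) -> float:
        return self.center_depth - self.d2 / 2.0

    @property
    def depth_bottom(self) -> float:
        return self.center_depth + self.d2 / 2.0

    @property
    def outer_depth_top(self) -> float:
        """Top of core plus shell (multilayer stages), else of the core."""
        if self.stage is LesionStage.MULTILAYER_SEVERE:
            return 0.0  # severe inflammation reaches the skin surface
        if self.stage is LesionStage.MULTILAYER_MILD:
            return self.depth_top - self.shell_thickness
        return self.depth_top

    @property
    def outer_depth_bottom(self) -> float:
        if self.stage.has_shell:
            return self.depth_bottom + self.shell_thickness
        return self.depth_bottom


LAYER_NAMES = ("epidermis", "papillary_dermis", "reticular_dermis", "fat", "muscle")

# Default layer stack.  Thickness in m; properties: rho, c, k, perfusion
# rate, arterial temperature, metabolic heat.  Epidermis is avascular and
# metabolically inert in this model.
_DEFAULT_LAYER_DATA = {
    # name: (thickness_m, rho, c, k, omega_b, T_b, q_met)
    "epidermis": (0.46e-3, 1200.0, 3589.0, 0.235, 0.0, 37.0, 0.0),
    "papillary_dermis": (1.67e-3, 1200.0, 3300.0, 0.445, 0.18e-3, 37.0, 368.1),
    "reticular_dermis": (1.67e-3, 1200.0, 3300.0, 0.445, 1.26e-3, 37.0, 368.1),
    "fat": (5.0e-3, 1000.0, 2674.0, 0.185, 0.08e-3, 37.0, 368.3),
    "muscle": (2.5e-3, 1085.0, 3600.0, 0.51, 2.7e-3, 37.0, 684.2),
}

# Lesion property rows: same column order as above (no thickness).
_LESION_DATA = {
    "ischemia": (1037.0, 2450.0, 0.1, 0.405e-3, 35.0, 342.1),
    "inflammation": (1037.0, 2450.0, 0.558, 6.95e-3, 37.0, 5262.5),
}


def _props_from_row(rho, c, k, omega_b, T_b, q_met) -> MaterialProperties:
    return MaterialProperties(rho=rho, c=c, k=k, omega_b=omega_b, T_b=T_b, q_met=q_met)


def default_layers() -> list[LayerSpec]:
    """The default five-layer heel stack (11.3 mm of soft tissue)."""
    out = []
    for name in LAYER_NAMES:
        t, rho, c, k, w, tb, q = _DEFAULT_LAYER_DATA[name]
        out.append(LayerSpec(name=name, thickness=t, props=_props_from_row(rho, c, k, w, tb, q)))
    return out


def lesion_core_properties(stage: LesionStage) -> MaterialProperties:
    if stage in (LesionStage.ISCHEMIA, LesionStage.MULTILAYER_MILD, LesionStage.MULTILAYER_SEVERE):
        row = _LESION_DATA["ischemia"]
    elif stage is LesionStage.INFLAMMATION:
        row = _LESION_DATA["inflammation"]
    else:
        raise ConfigurationError(
            "healthy stage has no intrinsic lesion properties; use the enclosing layer"
        )
    return _props_from_row(*row)


def lesion_shell_properties() -> MaterialProperties:
    return _props_from_row(*_LESION_DATA["inflammation"])


def properties_for(
    region: str,
    stage: LesionStage = LesionStage.HEALTHY,
    layers: Iterable[LayerSpec] | None = None,
    enclosing_layer: str | None = None,
) -> MaterialProperties:
    """Material properties of a tagged mesh region under a lesion stage.

    Parameters
    ----------
    region : str
        A layer name, ``"lesion_core"`` or ``"lesion_shell"``.
    stage : LesionStage
        Lesion stage; for ``healthy`` the lesion regions inherit the
        enclosing layer's row (``enclosing_layer`` must then be given).
    layers : iterable of LayerSpec, optional
        Layer stack providing layer rows (defaults to :func:`default_layers`).
    enclosing_layer : str, optional
        Background layer of the queried point, used for the healthy stage.
    """
    table = {l.name: l.props for l in (layers if layers is not None else default_layers())}
    if region in table:
        return table[region]
    if region == "lesion_core":
        if stage is LesionStage.HEALTHY:
            if enclosing_layer is None or enclosing_layer not in table:
                raise ConfigurationError(
                    "healthy-stage lesion needs a valid enclosing_layer"
                )
            return table[enclosing_layer]
        return lesion_core_properties(stage)
    if region == "lesion_shell":
        if stage is LesionStage.HEALTHY:
            if enclosing_layer is None or enclosing_layer not in table:
                raise ConfigurationError(
                    "healthy-stage lesion needs a valid enclosing_layer"
                )
            return table[enclosing_layer]
        if not stage.has_shell:
            raise ConfigurationError(
                f"lesion_shell is only defined for multilayer stages, not {stage.value}"
            )
        return lesion_shell_properties()
    raise ConfigurationError(f"unknown region tag {region!r}")


def layer_depth_bands(layers: Iterable[LayerSpec]) -> list[tuple[str, float, float]]:
    """Cumulative depth bands [start, end) per layer, from the skin down."""
    bands = []
    d = 0.0
    for layer in layers:
        bands.append((layer.name, d, d + layer.thickness))
        d += layer.thickness
    return bands


def soft_tissue_thickness(layers: Iterable[LayerSpec]) -> float:
    return sum(l.thickness for l in layers)


def layer_at_depth(depth: float, layers: Iterable[LayerSpec]) -> str:
    """Layer containing a given normal depth below the skin surface."""
    bands = layer_depth_bands(layers)
    for name, lo, hi in bands:
        if lo <= depth < hi:
            return name
    if depth == bands[-1][2]:
        return bands[-1][0]
    raise GeometryError(f"depth {depth * 1e3:.2f} mm outside the soft-tissue stack")


def classify_lesion_layers(lesion: LesionSpec, layers: Iterable[LayerSpec]) -> set[str]:
    """Names of the layers intersected by the lesion core's depth extent."""
    layers = list(layers)
    total = soft_tissue_thickness(layers)
    if lesion.is_degenerate:
        return set()
    if lesion.depth_top < 0 or lesion.depth_bottom > total:
        raise GeometryError(
            "lesion extends beyond the skin surface or into the bone "
            f"(span {lesion.depth_top * 1e3:.2f}-{lesion.depth_bottom * 1e3:.2f} mm, "
            f"soft tissue 0-{total * 1e3:.1f} mm)"
        )
    hit = set()
    for name, lo, hi in layer_depth_bands(layers):
        if lo < lesion.depth_bottom and hi > lesion.depth_top:
            hit.add(name)
    return hit


def with_overrides(props: MaterialProperties, **kwargs) -> MaterialProperties:
    """Copy of ``props`` with selected fields replaced (config overrides)."""
    return replace(props, **kwargs)
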