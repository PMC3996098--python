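"""Semi-elliptical heel cross-section geometry in surface-fitted coordinates.

The computational domain is the band of soft tissue between the heel skin
(the lower arc of an ellipse with semi-axes ``a_out`` x ``b_out``, cut by a
flat top edge at y = 0) and the muscle--bone interface, an inward normal
offset of the skin at the cumulative layer depth (11.3 mm by default).
Bone itself is excluded: the core temperature is imposed on the offset
curve.

All layer interfaces are inward normal offsets of the skin at cumulative
layer depths, honouring the uniform-thickness layer assumption.  The
natural coordinates are therefore *surface-fitted*:

    u  — arc length along the skin, from the arc end with the lower
         x-coordinate (u = 0 at (-a_out, 0)) to the other end (u = S),
    v  — normal depth below the skin surface (v = 0 skin, v = D bone).

The physical map is F(u, v) = skin(u) + v * n_in(u) with n_in the inward
unit normal; it is injective as long as D stays below the minimum radius
of curvature of the ellipse.  The DTI lesion is an ellipse in (u, v)
coordinates centred at (u_c, h): a lesion of depth h with major axis d1
tangential to the layers and minor axis d2 across them.  At the default
curvature this deviates from a Cartesian ellipse by well under a
millimetre while keeping "depth below the skin" exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tissue import (
    GeometryError,
    LayerSpec,
    LesionSpec,
    LesionStage,
    layer_depth_bands,
    soft_tissue_thickness,
)

__all__ = ["HeelGeometry", "build_geometry", "ellipse_half_perimeter"]

_N_ARC_TABLE = 4096


def ellipse_half_perimeter(a: float, b: float, n: int = 20000) -> float:
    """Arc length of the lower half of an ellipse, by dense quadrature."""
    th = np.linspace(np.pi, 2 * np.pi, n)
    speed = np.hypot(a * np.sin(th), b * np.cos(th))
    return float(np.trapezoid(speed, th))


@dataclass
class HeelGeometry:
    """Layered semi-elliptical heel domain with an optional embedded lesion."""

    a_out: float
    b_out: float
    layers: list[LayerSpec]
    lesion: LesionSpec
    lesion_lateral_offset: float = 0.0

    # filled in __post_init__
    _theta_tab: np.ndarray = field(init=False, repr=False)
    _arc_tab: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        th = np.linspace(np.pi, 2 * np.pi, _N_ARC_TABLE)
        speed = np.hypot(self.a_out * np.sin(th), self.b_out * np.cos(th))
        arc = np.concatenate(
            [[0.0], np.cumsum((speed[1:] + speed[:-1]) * 0.5 * np.diff(th))]
        )
        self._theta_tab = th
        self._arc_tab = arc

    # --- skin parametrization -------------------------------------------------

    @property
    def total_arc(self) -> float:
        """Length S of the skin arc (half-perimeter of the ellipse)."""
        return float(self._arc_tab[-1])

    @property
    def depth(self) -> float:
        """Total soft-tissue thickness D (skin to bone interface)."""
        return soft_tissue_thickness(self.layers)

    @property
    def interface_depths(self) -> list[float]:
        """Cumulative depths of the internal layer interfaces (excl. 0 and D)."""
        bands = layer_depth_bands(self.layers)
        return [hi for (_, _, hi) in bands[:-1]]

    def theta_of_arc(self, u) -> np.ndarray:
        return np.interp(u, self._arc_tab, self._theta_tab)

    def skin_point(self, u) -> np.ndarray:
        th = self.theta_of_arc(u)
        return np.stack([self.a_out * np.cos(th), self.b_out * np.sin(th)], axis=-1)

    def inward_normal(self, u) -> np.ndarray:
        th = self.theta_of_arc(u)
        tx = -self.a_out * np.sin(th)
        ty = self.b_out * np.cos(th)
        norm = np.hypot(tx, ty)
        # inward normal = tangent rotated by +90 deg: (-t_y, t_x)
        return np.stack([-ty / norm, tx / norm], axis=-1)

    def curvature(self, u) -> np.ndarray:
        th = self.theta_of_arc(u)
        a, b = self.a_out, self.b_out
        return a * b / (a * a * np.sin(th) ** 2 + b * b * np.cos(th) ** 2) ** 1.5

    def to_physical(self, u, v) -> np.ndarray:
        """Map surface-fitted (u, v) to physical (x, y) coordinates."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        return self.skin_point(u) + v[..., None] * self.inward_normal(u)

    # --- lesion ----------------------------------------------------------------

    @property
    def lesion_center_arc(self) -> float:
        return self.total_arc / 2.0 + self.lesion_lateral_offset

    def _core_level(self, t, v) -> np.ndarray:
        les = self.lesion
        r1, r2 = les.d1 / 2.0, les.d2 / 2.0
        return (t / r1) ** 2 + ((v - les.center_depth) / r2) ** 2

    def _shell_level(self, t, v) -> np.ndarray:
        les = self.lesion
        s = les.shell_thickness
        R1, R2 = les.d1 / 2.0 + s, les.d2 / 2.0 + s
        return (t / R1) ** 2 + ((v - les.center_depth) / R2) ** 2

    def in_lesion_core(self, u, v) -> np.ndarray:
        if self.lesion.is_degenerate:
            return np.zeros(np.broadcast(np.asarray(u), np.asarray(v)).shape, bool)
        t = np.asarray(u, float) - self.lesion_center_arc
        return self._core_level(t, np.asarray(v, float)) <= 1.0

    def in_lesion_shell(self, u, v) -> np.ndarray:
        """Inflammation shell region (excludes the core)."""
        les = self.lesion
        shape = np.broadcast(np.asarray(u), np.asarray(v)).shape
        if les.is_degenerate or not les.stage.has_shell:
            return np.zeros(shape, bool)
        t = np.asarray(u, float) - self.lesion_center_arc
        v = np.asarray(v, float)
        inside = self._shell_level(t, v) <= 1.0
        if les.stage is LesionStage.MULTILAYER_SEVERE:
            # severe inflammation also fills the normal-projection band from
            # the core outline up to the skin surface
            band = (np.abs(t) <= les.d1 / 2.0) & (v <= les.center_depth)
            inside = inside | band
        return inside & ~self.in_lesion_core(u, v)

    def region_at(self, u: float, v: float) -> tuple[str, str]:
        """(region_tag, background_layer) at a surface-fitted point."""
        bands = layer_depth_bands(self.layers)
        layer = bands[-1][0]
        for name, lo, hi in bands:
            if lo <= v < hi:
                layer = name
                break
        if self.in_lesion_core(u, v):
            return "lesion_core", layer
        if self.in_lesion_shell(u, v):
            return "lesion_shell", layer
        return layer, layer

    # --- crossing helpers used by the mesher ------------------------------------

    def core_crossings(self, u: float) -> list[float]:
        """Depths where a column at arc position u crosses the core outline."""
        les = self.lesion
        if les.is_degenerate:
            return []
        t = u - self.lesion_center_arc
        r1, r2 = les.d1 / 2.0, les.d2 / 2.0
        x = 1.0 - (t / r1) ** 2
        if x < 0:
            return []
        d = r2 * np.sqrt(x)
        if d < 1e-12:
            return [les.center_depth]
        return [les.center_depth - d, les.center_depth + d]

    def shell_crossings(self, u: float) -> list[float]:
        """Depths where a column crosses the outer shell boundary."""
        les = self.lesion
        if les.is_degenerate or not les.stage.has_shell:
            return []
        t = u - self.lesion_center_arc
        s = les.shell_thickness
        R1, R2 = les.d1 / 2.0 + s, les.d2 / 2.0 + s
        x = 1.0 - (t / R1) ** 2
        if x < 0:
            return []
        d = R2 * np.sqrt(x)
        if les.stage is LesionStage.MULTILAYER_SEVERE and abs(t) <= les.d1 / 2.0:
            # upper boundary is the skin surface itself inside the band
            return [les.center_depth + d]
        if d < 1e-12:
            return [les.center_depth]
        return [les.center_depth - d, les.center_depth + d]


def build_geometry(
    layers: list[LayerSpec],
    lesion: LesionSpec,
    a_out: float = 0.027,
    b_out: float = 0.030,
    lesion_lateral_offset: float = 0.0,
) -> HeelGeometry:
    """Validate and construct the heel geometry.

    Raises :class:`GeometryError` when the layer offsets would
    self-intersect (domain too thick for the outer curvature) or when the
    lesion (plus shell) is not strictly inside the soft tissue.
    """
    if not (a_out > 0 and b_out > 0):
        raise GeometryError("outer semi-axes must be positive")
    depth = soft_tissue_thickness(layers)
    min_curv_radius = min(a_out**2 / b_out, b_out**2 / a_out)
    if depth >= min_curv_radius:
        raise GeometryError(
            f"soft tissue depth {depth * 1e3:.1f} mm exceeds the minimum radius of "
            f"curvature {min_curv_radius * 1e3:.1f} mm: inward offsets self-intersect"
        )
    geom = HeelGeometry(
        a_out=a_out,
        b_out=b_out,
        layers=list(layers),
        lesion=lesion,
        lesion_lateral_offset=lesion_lateral_offset,
    )
    if not lesion.is_degenerate:
        if lesion.outer_depth_top < 0 or (
            lesion.stage is not LesionStage.MULTILAYER_SEVERE
            and lesion.outer_depth_top <= 0
        ):
            raise GeometryError("lesion (plus shell) breaches the skin surface")
        if lesion.outer_depth_bottom >= depth:
            raise GeometryError(
                f"lesion (plus shell) reaches the bone interface: bottom at "
                f"{lesion.outer_depth_bottom * 1e3:.2f} mm vs depth {depth * 1e3:.1f} mm"
            )
        half_extent = lesion.d1 / 2.0 + (
            lesion.shell_thickness if lesion.stage.has_shell else 0.0
        )
        uc = geom.lesion_center_arc
        if uc - half_extent <= 0.05 * geom.total_arc or uc + half_extent >= 0.95 * geom.total_arc:
            raise GeometryError("lesion arc extent too close to the top flat edge")
    return geom
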