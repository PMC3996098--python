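"""Diagnostic observables extracted from protocol runs.

The clinically relevant quantities are surface observables: the recovery
curve of the sub-lesion skin point P (on the symmetry axis, directly below
the lesion center), temperature profiles along the heel periphery as a
function of the arc coordinate l, and temperature differences
``delta_T = T_lesion - T_healthy`` between a lesion scenario and the
healthy baseline computed on the same mesh.

Arc lengths are reported in mm and times in seconds on the recovery clock
(t = 0 at cooling removal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import RecoveryResult

__all__ = [
    "AnalysisError",
    "RecoveryCurve",
    "SurfaceProfile",
    "DeltaTSeries",
    "point_curve",
    "profile",
    "delta_curve",
    "delta_profile",
    "extremum",
    "delta_at_point",
    "skin_delta_matrix",
]


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class RecoveryCurve:
    """Temperature of one skin point over the recovery period."""

    point: str
    times: np.ndarray  # s, recovery clock
    temps: np.ndarray  # degC

    def at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.temps))


@dataclass(frozen=True)
class SurfaceProfile:
    """Skin temperature along the heel periphery at one instant."""

    l: np.ndarray  # mm, arc coordinate
    temps: np.ndarray  # degC
    time: float | str


@dataclass(frozen=True)
class DeltaTSeries:
    """T_lesion - T_healthy at the monitored point over time."""

    pair: str
    times: np.ndarray
    delta: np.ndarray

    def at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.delta))


def _point_arc_mm(result: RecoveryResult, l_mm: float | None) -> float:
    if l_mm is None:
        l_mm = result.geom.lesion_center_arc * 1e3
    l_skin = result.mesh.skin_arc * 1e3
    if not (l_skin[0] - 1e-9 <= l_mm <= l_skin[-1] + 1e-9):
        raise AnalysisError(f"point at l={l_mm:.1f} mm outside the skin arc")
    return l_mm


def point_curve(result: RecoveryResult, l_mm: float | None = None) -> RecoveryCurve:
    """Recovery-phase temperature at point P (or any arc coordinate).

    P defaults to the skin point on the symmetry axis below the lesion
    center.  The temperature is linearly interpolated along the skin arc.
    """
    l_mm = _point_arc_mm(result, l_mm)
    times, l_skin, mat = result.skin_series()
    keep = times >= 0.0
    temps = np.array([np.interp(l_mm, l_skin, row) for row in mat[keep]])
    return RecoveryCurve(point="P", times=times[keep], temps=temps)


def profile(result: RecoveryResult, t: float | str) -> SurfaceProfile:
    """Skin-surface temperature profile at time t ('steady' allowed)."""
    vals = result.field_at(t)
    ids = result.mesh.skin_nodes
    return SurfaceProfile(l=result.mesh.skin_arc * 1e3, temps=vals[ids], time=t)


def delta_curve(dti: RecoveryCurve, healthy: RecoveryCurve, pair: str = "") -> DeltaTSeries:
    """Pointwise T_dti - T_healthy, resampling in time if the grids differ."""
    if len(dti.times) == len(healthy.times) and np.allclose(dti.times, healthy.times):
        return DeltaTSeries(pair=pair, times=dti.times.copy(), delta=dti.temps - healthy.temps)
    h = np.interp(dti.times, healthy.times, healthy.temps)
    return DeltaTSeries(pair=pair, times=dti.times.copy(), delta=dti.temps - h)


def delta_profile(
    dti: SurfaceProfile, healthy: SurfaceProfile, resample: bool = False
) -> SurfaceProfile:
    """Profile-wise T_dti - T_healthy at matched arc coordinates."""
    if len(dti.l) != len(healthy.l) or not np.allclose(dti.l, healthy.l):
        if not resample:
            raise AnalysisError(
                "profiles live on different skin discretizations; pass resample=True"
            )
        h = np.interp(dti.l, healthy.l, healthy.temps)
    else:
        h = healthy.temps
    return SurfaceProfile(l=dti.l.copy(), temps=dti.temps - h, time=dti.time)


def extremum(delta: SurfaceProfile) -> tuple[float, float]:
    """(l*, delta_T*) of the largest-magnitude signed temperature difference.

    Ties are broken toward the smaller arc coordinate.
    """
    mag = np.abs(delta.temps)
    i = int(np.argmax(mag))  # argmax returns the first (smallest-l) maximum
    return float(delta.l[i]), float(delta.temps[i])


def delta_at_point(
    dti: RecoveryResult, healthy: RecoveryResult, t: float, l_mm: float | None = None
) -> float:
    """T_dti - T_healthy at point P and recovery time t (same mesh)."""
    _check_same_mesh(dti, healthy)
    a = point_curve(dti, l_mm)
    b = point_curve(healthy, l_mm)
    return delta_curve(a, b).at(t)


def skin_delta_matrix(
    dti: RecoveryResult, healthy: RecoveryResult
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times, l_mm, delta[time, skin node]) over the recovery window."""
    _check_same_mesh(dti, healthy)
    ta, la, ma = dti.skin_series()
    tb, _, mb = healthy.skin_series()
    if len(ta) != len(tb) or not np.allclose(ta, tb):
        raise AnalysisError("snapshot schedules differ between scenarios")
    keep = ta >= 0.0
    return ta[keep], la, ma[keep] - mb[keep]


def _check_same_mesh(a: RecoveryResult, b: RecoveryResult) -> None:
    if a.mesh.n_nodes != b.mesh.n_nodes or not np.allclose(a.mesh.nodes, b.mesh.nodes):
        raise AnalysisError(
            "scenarios were run on different meshes; delta-T comparisons require "
            "a shared geometry (see run_pair)"
        )
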