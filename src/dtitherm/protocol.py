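"""Cool-then-recover dynamic thermography protocol on the heel model.

Each scenario runs the three-step experiment:

1. steady state with the skin exposed to ambient air (Robin boundary,
   h_inf = 12 W/m^2 K, T_inf = 22 degC; core at 37 degC on the bone
   interface; adiabatic flat top),
2. one minute of contact cooling: the skin surface held at 15 degC
   (strong Dirichlet), initialized from the steady field,
3. thermal recovery under the ambient Robin condition again, initialized
   from the end-of-cooling field.

The recovery clock places t = 0 at the removal of cooling; the cooling
phase is stored on the negative time axis.  Time stepping is backward
Euler with dt = 0.1 s up to 5 minutes of recovery and 1 s afterwards;
snapshots are retained every 0.5 s during the fine window and every 10 s
afterwards (full per-step storage would be wasteful).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import HeelGeometry, build_geometry
from .meshing import Mesh, generate_mesh
from .solver import (
    Adiabatic,
    Convective,
    Dirichlet,
    ElementProperties,
    Phase,
    TemperatureField,
    assemble,
    element_properties,
    solve_steady,
    solve_transient,
)
from .tissue import ConfigurationError, LayerSpec, LesionSpec, LesionStage, default_layers

__all__ = [
    "ProtocolConfig",
    "RecoveryResult",
    "build_model",
    "run_scenario",
    "run_pair",
    "run_paper_suite",
    "PAPER_SCENARIOS",
]

PAPER_DEPTHS = (0.0038, 0.006, 0.008)

# the ten study scenarios: healthy baseline, ischemia and inflammation at
# three depths, and the three multilayer cases
PAPER_SCENARIOS: dict[str, tuple[LesionStage, float | None]] = {
    "healthy": (LesionStage.HEALTHY, None),
    "ischemia_3_8mm": (LesionStage.ISCHEMIA, 0.0038),
    "ischemia_6mm": (LesionStage.ISCHEMIA, 0.006),
    "ischemia_8mm": (LesionStage.ISCHEMIA, 0.008),
    "inflammation_3_8mm": (LesionStage.INFLAMMATION, 0.0038),
    "inflammation_6mm": (LesionStage.INFLAMMATION, 0.006),
    "inflammation_8mm": (LesionStage.INFLAMMATION, 0.008),
    "multilayer_mild_8mm": (LesionStage.MULTILAYER_MILD, 0.008),
    "multilayer_severe_8mm": (LesionStage.MULTILAYER_SEVERE, 0.008),
    "multilayer_mild_3_8mm": (LesionStage.MULTILAYER_MILD, 0.0038),
}


@dataclass(frozen=True)
class ProtocolConfig:
    """Boundary/protocol parameters of the thermography experiment (SI)."""

    h_inf: float = 12.0  # W/(m^2 K)
    T_inf: float = 22.0  # degC ambient
    T_cool: float = 15.0  # degC applied during cooling
    t_cool: float = 60.0  # s of cooling
    T_core: float = 37.0  # degC at the muscle-bone interface
    t_end: float = 1800.0  # s of simulated recovery
    dt_fine: float = 0.1  # s, for recovery t <= t_fine
    t_fine: float = 300.0  # s
    dt_coarse: float = 1.0  # s, afterwards
    snap_fine_every: int = 5  # steps between snapshots in the fine window
    snap_coarse_every: int = 10
    snap_cool_every: int = 50

    def __post_init__(self) -> None:
        if not (self.t_cool < self.t_fine):
            raise ConfigurationError("require t_cool < t_fine")
        if not self.t_end > self.t_cool:
            raise ConfigurationError("require t_end > t_cool")
        for name in ("h_inf", "t_cool", "dt_fine", "dt_coarse", "t_end"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("T_inf", "T_cool", "T_core"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


@dataclass
class RecoveryResult:
    """Steady field plus the cooling/recovery snapshot sequence."""

    stage: LesionStage
    depth: float | None
    geom: HeelGeometry
    mesh: Mesh
    props: ElementProperties = field(repr=False)
    steady: TemperatureField = field(repr=False)
    snapshots: list[TemperatureField] = field(repr=False)
    cfg: ProtocolConfig = field(default_factory=ProtocolConfig)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots], dtype=float)

    def field_at(self, t: float | str) -> np.ndarray:
        """Nodal field at time t (recovery clock), linear in time."""
        if t == "steady":
            return self.steady.values
        times = self.times
        t = float(t)
        if t < times[0] - 1e-9 or t > times[-1] + 1e-9:
            raise ValueError(f"t={t} outside the simulated window [{times[0]}, {times[-1]}]")
        i = int(np.searchsorted(times, t))
        if i < len(times) and abs(times[i] - t) < 1e-9:
            return self.snapshots[i].values
        lo, hi = self.snapshots[i - 1], self.snapshots[i]
        w = (t - lo.time) / (hi.time - lo.time)
        return (1 - w) * lo.values + w * hi.values

    def skin_series(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times, arc l in mm, temperatures[time, skin node])."""
        ids = self.mesh.skin_nodes
        mat = np.stack([s.values[ids] for s in self.snapshots])
        return self.times, self.mesh.skin_arc * 1e3, mat


def _snapshot_times(cfg: ProtocolConfig) -> list[float]:
    snaps = []
    n_cool = int(round(cfg.t_cool / cfg.dt_fine))
    for n in range(0, n_cool + 1, cfg.snap_cool_every):
        snaps.append(-cfg.t_cool + n * cfg.dt_fine)
    if snaps[-1] != 0.0:
        snaps.append(0.0)
    t_fine = min(cfg.t_fine, cfg.t_end)
    n_fine = int(round(t_fine / cfg.dt_fine))
    for n in range(cfg.snap_fine_every, n_fine + 1, cfg.snap_fine_every):
        snaps.append(n * cfg.dt_fine)
    if snaps[-1] < t_fine:
        snaps.append(t_fine)
    if cfg.t_end > cfg.t_fine:
        n_coarse = int(round((cfg.t_end - cfg.t_fine) / cfg.dt_coarse))
        for n in range(cfg.snap_coarse_every, n_coarse + 1, cfg.snap_coarse_every):
            snaps.append(cfg.t_fine + n * cfg.dt_coarse)
        if snaps[-1] < cfg.t_end:
            snaps.append(cfg.t_end)
    return snaps


def build_model(
    stage: LesionStage,
    depth: float | None,
    *,
    layers: list[LayerSpec] | None = None,
    lesion: LesionSpec | None = None,
    a_out: float = 0.027,
    b_out: float = 0.030,
    lesion_lateral_offset: float = 0.0,
    h_fine: float = 1.3e-3,
    h_coarse: float = 2.4e-3,
) -> tuple[HeelGeometry, Mesh, list[LayerSpec]]:
    """Geometry and mesh for one scenario.

    ``depth=None`` (healthy baseline) builds the lesion-free domain; any
    other depth embeds the lesion curves so that lesion and healthy runs
    can share one mesh.
    """
    layers = layers if layers is not None else default_layers()
    if lesion is None:
        if depth is None:
            lesion = LesionSpec(stage=LesionStage.HEALTHY, d1=0.0, d2=0.0)
        else:
            lesion = LesionSpec(stage=stage, center_depth=depth)
    geom = build_geometry(
        layers, lesion, a_out=a_out, b_out=b_out, lesion_lateral_offset=lesion_lateral_offset
    )
    mesh = generate_mesh(geom, h_fine=h_fine, h_coarse=h_coarse)
    return geom, mesh, layers


def _bc_ambient(cfg: ProtocolConfig) -> dict:
    return {
        "skin": Convective(cfg.h_inf, cfg.T_inf),
        "top_flat": Adiabatic(),
        "bone_interface": Dirichlet(cfg.T_core),
    }


def _bc_cooling(cfg: ProtocolConfig) -> dict:
    return {
        "skin": Dirichlet(cfg.T_cool),
        "top_flat": Adiabatic(),
        "bone_interface": Dirichlet(cfg.T_core),
    }


def run_scenario(
    stage: LesionStage,
    depth: float | None = None,
    cfg: ProtocolConfig | None = None,
    *,
    model: tuple[HeelGeometry, Mesh, list[LayerSpec]] | None = None,
    core_props=None,
    shell_props=None,
    **model_kwargs,
) -> RecoveryResult:
    """Run steady state + cooling + recovery for one scenario.

    ``model`` allows several stages to share one geometry/mesh (the basis
    of all delta-T comparisons); otherwise the model is built from
    ``model_kwargs`` (see :func:`build_model`).
    """
    cfg = cfg or ProtocolConfig()
    if model is None:
        model = build_model(stage, depth, **model_kwargs)
    geom, mesh, layers = model
    props = element_properties(
        mesh, stage, layers=layers, core_props=core_props, shell_props=shell_props
    )

    steady = solve_steady(assemble(mesh, props, _bc_ambient(cfg)))

    phases = [Phase(-cfg.t_cool, 0.0, cfg.dt_fine, _bc_cooling(cfg))]
    t_fine = min(cfg.t_fine, cfg.t_end)
    phases.append(Phase(0.0, t_fine, cfg.dt_fine, _bc_ambient(cfg)))
    if cfg.t_end > cfg.t_fine:
        phases.append(Phase(cfg.t_fine, cfg.t_end, cfg.dt_coarse, _bc_ambient(cfg)))
    snapshots = solve_transient(
        mesh, props, phases, T0=steady, snapshot_times=_snapshot_times(cfg)
    )
    return RecoveryResult(
        stage=stage,
        depth=depth,
        geom=geom,
        mesh=mesh,
        props=props,
        steady=steady,
        snapshots=snapshots,
        cfg=cfg,
    )


def run_pair(
    stage: LesionStage,
    depth: float,
    cfg: ProtocolConfig | None = None,
    *,
    core_props=None,
    shell_props=None,
    **model_kwargs,
) -> tuple[RecoveryResult, RecoveryResult]:
    """A lesion scenario and its healthy baseline on the same mesh.

    Toggling only the region properties between the two runs removes any
    mesh-difference noise from the computed temperature differences.
    """
    model = build_model(stage, depth, **model_kwargs)
    lesion_res = run_scenario(
        stage, depth, cfg, model=model, core_props=core_props, shell_props=shell_props
    )
    healthy_res = run_scenario(LesionStage.HEALTHY, depth, cfg, model=model)
    return lesion_res, healthy_res


def run_paper_suite(
    cfg: ProtocolConfig | None = None, **model_kwargs
) -> dict[str, RecoveryResult]:
    """All ten study scenarios (healthy, ischemia/inflammation at three
    depths, three multilayer cases), each on its own lesion geometry."""
    results: dict[str, RecoveryResult] = {}
    errors: dict[str, Exception] = {}
    for name, (stage, depth) in PAPER_SCENARIOS.items():
        try:
            results[name] = run_scenario(stage, depth, cfg, **model_kwargs)
        except Exception as err:  # noqa: BLE001 - report partial completion
            errors[name] = err
    if errors:
        done = ", ".join(results) or "none"
        failed = "; ".join(f"{k}: {v}" for k, v in errors.items())
        raise RuntimeError(f"suite incomplete (completed: {done}); failures: {failed}")
    return results
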