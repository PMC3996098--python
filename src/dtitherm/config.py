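"""Configuration schema, loading and scenario fixtures.

All lengths in configuration files are expressed in millimetres (the unit
of discourse for skin anatomy) and converted to SI internally;
temperatures are degC throughout.  Unknown keys are rejected, and basic
unit sanity checks catch metre-valued lengths slipping into mm fields.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .geometry import HeelGeometry, build_geometry
from .meshing import Mesh, generate_mesh
from .protocol import ProtocolConfig
from .tissue import (
    LAYER_NAMES,
    ConfigurationError,
    LayerSpec,
    LesionSpec,
    LesionStage,
    MaterialProperties,
    default_layers,
    with_overrides,
)

__all__ = [
    "RunConfig",
    "load_config",
    "fixtures",
    "layers_from_config",
    "lesion_from_config",
    "protocol_from_config",
    "model_from_config",
]


class _Base(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


def _check_mm(name: str, value: float, lo: float, hi: float) -> float:
    if not lo <= value <= hi:
        hint = ""
        if 0 < value < lo:
            hint = " (value looks like metres; config lengths are in mm)"
        raise ValueError(f"{name}={value} mm outside the plausible range [{lo}, {hi}]{hint}")
    return value


class GeometryConfig(_Base):
    a_out_mm: float = 27.0
    b_out_mm: float = 30.0
    lesion_lateral_offset_mm: float = 0.0

    @field_validator("a_out_mm", "b_out_mm")
    @classmethod
    def _plausible(cls, v, info):
        return _check_mm(info.field_name, v, 10.0, 200.0)


class LayerOverride(_Base):
    thickness_mm: float | None = None
    rho: float | None = None
    c: float | None = None
    k: float | None = None
    omega_b: float | None = None
    T_b: float | None = None
    q_met: float | None = None

    @field_validator("thickness_mm")
    @classmethod
    def _plausible(cls, v):
        if v is not None:
            _check_mm("thickness_mm", v, 0.05, 50.0)
        return v


class TissueConfig(_Base):
    rho_b: float = 1060.0  # blood density, kg/m^3
    c_b: float = 3770.0  # blood specific heat, J/(kg K)
    layers: dict[str, LayerOverride] = Field(default_factory=dict)

    @field_validator("layers")
    @classmethod
    def _known_layers(cls, v):
        unknown = set(v) - set(LAYER_NAMES)
        if unknown:
            raise ValueError(f"unknown layer name(s) {sorted(unknown)}")
        return v


class PropsOverride(_Base):
    rho: float | None = None
    c: float | None = None
    k: float | None = None
    omega_b: float | None = None
    T_b: float | None = None
    q_met: float | None = None


class LesionConfig(_Base):
    stage: LesionStage = LesionStage.HEALTHY
    depth_mm: float | None = 8.0  # None: lesion-free domain
    d1_mm: float = 15.0
    d2_mm: float = 2.5
    shell_mm: float = 1.25
    core: PropsOverride | None = None
    shell: PropsOverride | None = None

    @field_validator("depth_mm")
    @classmethod
    def _plausible_depth(cls, v):
        if v is not None:
            _check_mm("depth_mm", v, 0.5, 25.0)
        return v


class SolverConfig(_Base):
    h_fine_mm: float = 1.3
    h_coarse_mm: float = 2.4
    dt_fine_s: float = 0.1
    dt_coarse_s: float = 1.0
    t_fine_s: float = 300.0

    @field_validator("h_fine_mm", "h_coarse_mm", "dt_fine_s", "dt_coarse_s", "t_fine_s")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v


class ProtocolSection(_Base):
    h_inf: float = 12.0
    T_inf: float = 22.0
    T_cool: float = 15.0
    t_cool_s: float = 60.0
    T_core: float = 37.0
    t_end_s: float = 1800.0

    @field_validator("h_inf", "t_cool_s", "t_end_s")
    @classmethod
    def _positive(cls, v, info):
        if not v > 0:
            raise ValueError(f"{info.field_name} must be positive, got {v}")
        return v


class RunConfig(_Base):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    tissue: TissueConfig = Field(default_factory=TissueConfig)
    lesion: LesionConfig = Field(default_factory=LesionConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    protocol: ProtocolSection = Field(default_factory=ProtocolSection)
    out_dir: str = "results"
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            json.loads(self.model_dump_json()), sort_keys=True, default_flow_style=False
        )

    def config_hash(self) -> str:
        payload = json.dumps(json.loads(self.model_dump_json()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML/JSON config; empty or None gives defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as err:
        raise ConfigurationError(f"cannot parse {path}: {err}") from err
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig(**data)
    except ValidationError as err:
        locs = "; ".join(
            "/".join(str(p) for p in e["loc"]) + ": " + e["msg"] for e in err.errors()
        )
        raise ConfigurationError(f"invalid config {path}: {locs}") from err


# --- bridge to domain objects -------------------------------------------------


def layers_from_config(cfg: RunConfig) -> list[LayerSpec]:
    out = []
    for layer in default_layers():
        ov = cfg.tissue.layers.get(layer.name)
        props = with_overrides(layer.props, rho_b=cfg.tissue.rho_b, c_b=cfg.tissue.c_b)
        thickness = layer.thickness
        if ov is not None:
            fields = {
                k: v
                for k, v in ov.model_dump().items()
                if v is not None and k != "thickness_mm"
            }
            props = with_overrides(props, **fields)
            if ov.thickness_mm is not None:
                thickness = ov.thickness_mm * 1e-3
        out.append(LayerSpec(name=layer.name, thickness=thickness, props=props))
    return out


def lesion_from_config(cfg: RunConfig) -> LesionSpec:
    lc = cfg.lesion
    if lc.depth_mm is None:
        return LesionSpec(stage=LesionStage.HEALTHY, d1=0.0, d2=0.0)
    return LesionSpec(
        stage=lc.stage,
        center_depth=lc.depth_mm * 1e-3,
        d1=lc.d1_mm * 1e-3,
        d2=lc.d2_mm * 1e-3,
        shell_thickness=lc.shell_mm * 1e-3,
    )


def lesion_props_from_config(cfg: RunConfig, base: MaterialProperties, which: str):
    ov = getattr(cfg.lesion, which)
    if ov is None:
        return None
    fields = {k: v for k, v in ov.model_dump().items() if v is not None}
    return with_overrides(
        base, rho_b=cfg.tissue.rho_b, c_b=cfg.tissue.c_b, **fields
    )


def protocol_from_config(cfg: RunConfig) -> ProtocolConfig:
    p, s = cfg.protocol, cfg.solver
    return ProtocolConfig(
        h_inf=p.h_inf,
        T_inf=p.T_inf,
        T_cool=p.T_cool,
        t_cool=p.t_cool_s,
        T_core=p.T_core,
        t_end=p.t_end_s,
        dt_fine=s.dt_fine_s,
        t_fine=s.t_fine_s,
        dt_coarse=s.dt_coarse_s,
    )


def model_from_config(cfg: RunConfig) -> tuple[HeelGeometry, Mesh, list[LayerSpec]]:
    layers = layers_from_config(cfg)
    lesion = lesion_from_config(cfg)
    geom = build_geometry(
        layers,
        lesion,
        a_out=cfg.geometry.a_out_mm * 1e-3,
        b_out=cfg.geometry.b_out_mm * 1e-3,
        lesion_lateral_offset=cfg.geometry.lesion_lateral_offset_mm * 1e-3,
    )
    mesh = generate_mesh(
        geom, h_fine=cfg.solver.h_fine_mm * 1e-3, h_coarse=cfg.solver.h_coarse_mm * 1e-3
    )
    return geom, mesh, layers


def fixtures() -> dict[str, RunConfig]:
    """Named configurations reproducing every study scenario.

    Names are stable across releases; ``mesh_refined`` is the healthy
    steady-state at the halved fine element size used for the mesh
    convergence check.
    """
    out: dict[str, RunConfig] = {}
    out["healthy"] = RunConfig(lesion=LesionConfig(stage=LesionStage.HEALTHY, depth_mm=None))
    for stage in (LesionStage.ISCHEMIA, LesionStage.INFLAMMATION):
        for depth, tag in ((3.8, "3_8mm"), (6.0, "6mm"), (8.0, "8mm")):
            out[f"{stage.value}_{tag}"] = RunConfig(
                lesion=LesionConfig(stage=stage, depth_mm=depth)
            )
    out["multilayer_mild_8mm"] = RunConfig(
        lesion=LesionConfig(stage=LesionStage.MULTILAYER_MILD, depth_mm=8.0)
    )
    out["multilayer_severe_8mm"] = RunConfig(
        lesion=LesionConfig(stage=LesionStage.MULTILAYER_SEVERE, depth_mm=8.0)
    )
    out["multilayer_mild_3_8mm"] = RunConfig(
        lesion=LesionConfig(stage=LesionStage.MULTILAYER_MILD, depth_mm=3.8)
    )
    out["mesh_refined"] = RunConfig(
        lesion=LesionConfig(stage=LesionStage.HEALTHY, depth_mm=None),
        solver=SolverConfig(h_fine_mm=0.65),
    )
    return out
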