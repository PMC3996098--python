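"""Headline diagnostic quantities of the heel DTI model.

Recomputes, from scratch, the handful of numbers that summarize the
model's predictions: steady sub-lesion temperature offsets, peak
periphery delta-T during thermal recovery, the multilayer transient
extremes, and the mesh-refinement sensitivity of the healthy steady
state.  Everything runs on the default configuration (Tables of layer and
lesion properties, 12 W/m^2 K ambient convection at 22 degC, 60 s of
15 degC cooling).
"""

from __future__ import annotations

import numpy as np

from .analysis import delta_at_point, skin_delta_matrix
from .protocol import ProtocolConfig, build_model, run_pair, run_scenario
from .solver import Convective, Adiabatic, Dirichlet, assemble, element_properties, solve_steady
from .tissue import LesionStage

__all__ = ["compute_headline_results"]


def _steady_values(mesh, layers, stage, cfg):
    props = element_properties(mesh, stage, layers=layers)
    bc = {
        "skin": Convective(cfg.h_inf, cfg.T_inf),
        "top_flat": Adiabatic(),
        "bone_interface": Dirichlet(cfg.T_core),
    }
    return solve_steady(assemble(mesh, props, bc)).values


def _at_P(geom, mesh, values):
    return float(np.interp(geom.lesion_center_arc, mesh.skin_arc, values[mesh.skin_nodes]))


def compute_headline_results(recovery_window: float = 300.0) -> dict[str, dict]:
    """All headline quantities as {name: {"value": degC or %, "n": elements}}.

    ``recovery_window`` is the simulated recovery span in seconds; all
    transient observables live within the first five minutes.
    """
    cfg = ProtocolConfig(t_end=recovery_window)
    out: dict[str, dict] = {}

    # --- steady offsets below a 6 mm lesion -------------------------------
    geom6, mesh6, layers = build_model(LesionStage.ISCHEMIA, 0.006)
    steady_h = _steady_values(mesh6, layers, LesionStage.HEALTHY, cfg)
    steady_i = _steady_values(mesh6, layers, LesionStage.ISCHEMIA, cfg)
    steady_f = _steady_values(mesh6, layers, LesionStage.INFLAMMATION, cfg)
    n6 = int(mesh6.n_elements)
    out["steady_deficit_ischemia_6mm"] = {
        "value": _at_P(geom6, mesh6, steady_h) - _at_P(geom6, mesh6, steady_i),
        "n": n6,
    }
    out["steady_excess_inflammation_6mm"] = {
        "value": _at_P(geom6, mesh6, steady_f) - _at_P(geom6, mesh6, steady_h),
        "n": n6,
    }

    # --- ischemia recovery observables ------------------------------------
    pairs = {}
    for depth, tag in ((0.008, "8mm"), (0.006, "6mm"), (0.0038, "3_8mm")):
        pairs[tag] = run_pair(LesionStage.ISCHEMIA, depth, cfg)

    les8, heal8 = pairs["8mm"]
    times, _, dmat = skin_delta_matrix(les8, heal8)
    i35 = int(np.argmin(np.abs(times - 210.0)))
    out["peak_arc_deficit_ischemia_8mm_3p5min"] = {
        "value": float(-dmat[i35].min()),
        "n": int(les8.mesh.n_elements),
    }
    for tag, key in (("8mm", "delta_ischemia_8mm_5min"), ("6mm", "delta_ischemia_6mm_5min"),
                     ("3_8mm", "delta_ischemia_3_8mm_5min")):
        les, heal = pairs[tag]
        out[key] = {
            "value": float(delta_at_point(les, heal, 300.0)),
            "n": int(les.mesh.n_elements),
        }

    # --- shallow multilayer lesion: transient extremes and steady ----------
    ml, heal_ml = run_pair(LesionStage.MULTILAYER_MILD, 0.0038, cfg)
    tm, _, dml = skin_delta_matrix(ml, heal_ml)
    early = (tm > 0) & (tm < 120.0)
    window5 = (tm > 0) & (tm <= 300.0)
    n_ml = int(ml.mesh.n_elements)
    out["multilayer_3_8mm_max_decrease_early"] = {"value": float(dml[early].min()), "n": n_ml}
    out["multilayer_3_8mm_max_increase_5min"] = {"value": float(dml[window5].max()), "n": n_ml}
    steady_delta = ml.steady.values[ml.mesh.skin_nodes] - heal_ml.steady.values[
        heal_ml.mesh.skin_nodes
    ]
    out["multilayer_3_8mm_steady_max_increase"] = {"value": float(steady_delta.max()), "n": n_ml}

    # --- mesh refinement sensitivity (healthy steady state) ----------------
    out["mesh_refinement_max_change_pct"] = {
        "value": mesh_refinement_change(),
        "n": n6,
    }
    return out


def mesh_refinement_change(h_fine: float = 1.3e-3, h_refined: float = 0.65e-3) -> float:
    """Max relative change (%) of healthy steady skin temperatures when the
    fine-region element size is halved."""
    cfg = ProtocolConfig()
    geom_c, mesh_c, layers = build_model(LesionStage.HEALTHY, None, h_fine=h_fine)
    geom_r, mesh_r, _ = build_model(LesionStage.HEALTHY, None, h_fine=h_refined)
    coarse = _steady_values(mesh_c, layers, LesionStage.HEALTHY, cfg)
    refined = _steady_values(mesh_r, layers, LesionStage.HEALTHY, cfg)
    skin_c = coarse[mesh_c.skin_nodes]
    skin_r = np.interp(mesh_c.skin_arc, mesh_r.skin_arc, refined[mesh_r.skin_nodes])
    return float(np.max(np.abs(skin_r - skin_c) / np.abs(skin_c)) * 100.0)
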