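"""P1 finite-element solver for the Pennes bioheat equation.

Discretizes

    rho c dT/dt = div(k grad T) + omega_b rho_b c_b (T_b - T) + q_met

on a tagged triangle mesh with linear elements and a consistent mass
matrix.  Perfusion contributes a positive reaction term (mass-matrix
pattern scaled by omega_b rho_b c_b) plus a constant load toward the
arterial temperature, so the assembled operator is symmetric positive
definite whenever any Dirichlet or Robin boundary is present.  Interface
continuity of temperature and flux between tissue layers is implicit in
the conforming single-field discretization.

Transient stepping is backward Euler (unconditionally stable); with the
constant coefficients of this model each phase needs a single sparse LU
factorization followed by one triangular solve per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import Mesh, REGION_NAMES
from .tissue import (
    ConfigurationError,
    LayerSpec,
    LesionStage,
    MaterialProperties,
    default_layers,
    lesion_core_properties,
    lesion_shell_properties,
)

__all__ = [
    "TemperatureField",
    "Convective",
    "Dirichlet",
    "Adiabatic",
    "ElementProperties",
    "AssembledSystem",
    "SolverError",
    "element_properties",
    "assemble",
    "solve_steady",
    "solve_transient",
    "Phase",
    "steady_energy_balance",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class TemperatureField:
    """Nodal temperatures (degC) at one time instant ('steady' or seconds)."""

    time: float | str
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise SolverError(f"non-finite temperatures at t={self.time}")


@dataclass(frozen=True)
class Convective:
    h_inf: float
    T_inf: float


@dataclass(frozen=True)
class Dirichlet:
    T_fixed: float


@dataclass(frozen=True)
class Adiabatic:
    pass


BCSet = dict  # tag -> Convective | Dirichlet | Adiabatic


@dataclass
class ElementProperties:
    """Per-element Pennes coefficients resolved from region tags."""

    k: np.ndarray
    rho_c: np.ndarray
    perf: np.ndarray  # omega_b rho_b c_b, W/(m^3 K)
    q_met: np.ndarray
    T_b: np.ndarray

    @property
    def source(self) -> np.ndarray:
        """Constant volumetric load q_met + perf * T_b."""
        return self.q_met + self.perf * self.T_b


def element_properties(
    mesh: Mesh,
    stage: LesionStage = LesionStage.HEALTHY,
    layers: Sequence[LayerSpec] | None = None,
    core_props: MaterialProperties | None = None,
    shell_props: MaterialProperties | None = None,
) -> ElementProperties:
    """Resolve per-element properties for a lesion stage.

    Lesion-tagged elements take the stage's core/shell rows; under the
    ``healthy`` stage they fall back to each element's background layer,
    making the lesion thermally invisible on an unchanged mesh.
    """
    layer_table = {l.name: l.props for l in (layers if layers is not None else default_layers())}
    by_region: dict[str, MaterialProperties] = dict(layer_table)
    if stage is not LesionStage.HEALTHY:
        by_region["lesion_core"] = core_props or lesion_core_properties(stage)
        if stage.has_shell:
            by_region["lesion_shell"] = shell_props or lesion_shell_properties()
        elif stage is LesionStage.INFLAMMATION:
            # a plain inflammation lesion has no distinct shell; treat any
            # shell-tagged element as core
            by_region["lesion_shell"] = by_region["lesion_core"]

    n = mesh.n_elements
    out = ElementProperties(
        k=np.empty(n), rho_c=np.empty(n), perf=np.empty(n), q_met=np.empty(n), T_b=np.empty(n)
    )
    region = mesh.region_name()
    layer = mesh.layer_name()
    for e in range(n):
        tag = region[e]
        if tag not in by_region:  # healthy stage: background layer
            tag = layer[e]
        p = by_region[tag]
        out.k[e] = p.k
        out.rho_c[e] = p.rho * p.c
        out.perf[e] = p.perfusion_coefficient
        out.q_met[e] = p.q_met
        out.T_b[e] = p.T_b
    return out


@dataclass
class AssembledSystem:
    """Discrete operators: K (stiffness+perfusion+Robin), M (capacity), f."""

    K: sp.csr_matrix
    M: sp.csr_matrix
    f: np.ndarray
    dirichlet_nodes: np.ndarray
    dirichlet_values: np.ndarray
    components: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.K.shape[0]

    @property
    def free(self) -> np.ndarray:
        mask = np.ones(self.n, bool)
        mask[self.dirichlet_nodes] = False
        return np.flatnonzero(mask)


def _p1_matrices(mesh: Mesh):
    """Element stiffness geometry factors and consistent mass pattern."""
    p = mesh.nodes[mesh.triangles]
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    # grad(phi_i) = (b_i, c_i) / (2A);  Ke_ij = (b_i b_j + c_i c_j) / (4A)
    Ke = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) / (4.0 * area)[
        :, None, None
    ]
    Mpat = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    Me = area[:, None, None] * Mpat[None, :, :]
    return area, Ke, Me


def _scatter(mesh: Mesh, elem_mats: np.ndarray) -> sp.csr_matrix:
    tri = mesh.triangles
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    return sp.coo_matrix(
        (elem_mats.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()


def assemble(mesh: Mesh, props: ElementProperties | dict, bc: BCSet) -> AssembledSystem:
    """Assemble the discrete bioheat system under the given boundary set.

    ``props`` is either an :class:`ElementProperties` bundle or a mapping
    region-tag -> :class:`MaterialProperties` covering every tag present
    in the mesh.  ``bc`` must cover every boundary tag of the mesh exactly
    once.
    """
    if isinstance(props, dict):
        region = mesh.region_name()
        missing = set(region) - set(props)
        if missing:
            raise ConfigurationError(f"missing properties for region(s) {sorted(missing)}")
        n = mesh.n_elements
        ep = ElementProperties(
            k=np.array([props[r].k for r in region]),
            rho_c=np.array([props[r].rho * props[r].c for r in region]),
            perf=np.array([props[r].perfusion_coefficient for r in region]),
            q_met=np.array([props[r].q_met for r in region]),
            T_b=np.array([props[r].T_b for r in region]),
        )
    else:
        ep = props

    missing_tags = set(mesh.boundary_edges) - set(bc)
    if missing_tags:
        raise ConfigurationError(f"boundary tag(s) {sorted(missing_tags)} not covered by bc")
    unknown = set(bc) - set(mesh.boundary_edges)
    if unknown:
        raise ConfigurationError(f"bc refers to unknown boundary tag(s) {sorted(unknown)}")

    area, Ke, Me = _p1_matrices(mesh)
    K_cond = _scatter(mesh, ep.k[:, None, None] * Ke)
    K_perf = _scatter(mesh, ep.perf[:, None, None] * Me)
    M = _scatter(mesh, ep.rho_c[:, None, None] * Me)

    f_met = np.zeros(mesh.n_nodes)
    f_perf = np.zeros(mesh.n_nodes)
    vol_met = ep.q_met * area / 3.0
    vol_perf = ep.perf * ep.T_b * area / 3.0
    for loc in range(3):
        np.add.at(f_met, mesh.triangles[:, loc], vol_met)
        np.add.at(f_perf, mesh.triangles[:, loc], vol_perf)

    # Robin (convective) edges and Dirichlet node collection
    H = sp.csr_matrix((mesh.n_nodes, mesh.n_nodes))
    f_robin = np.zeros(mesh.n_nodes)
    dir_nodes: list[np.ndarray] = []
    dir_vals: list[np.ndarray] = []
    for tag, spec in bc.items():
        edges = mesh.boundary_edges[tag]
        if isinstance(spec, Adiabatic):
            continue
        if isinstance(spec, Dirichlet):
            nn = np.unique(edges.ravel())
            dir_nodes.append(nn)
            dir_vals.append(np.full(len(nn), spec.T_fixed))
            continue
        if isinstance(spec, Convective):
            le = np.linalg.norm(mesh.nodes[edges[:, 0]] - mesh.nodes[edges[:, 1]], axis=1)
            he = spec.h_inf * le
            data = np.stack(
                [he / 3.0, he / 6.0, he / 6.0, he / 3.0], axis=1
            ).ravel()
            rows = np.stack([edges[:, 0], edges[:, 0], edges[:, 1], edges[:, 1]], axis=1).ravel()
            cols = np.stack([edges[:, 0], edges[:, 1], edges[:, 0], edges[:, 1]], axis=1).ravel()
            H = H + sp.coo_matrix((data, (rows, cols)), shape=H.shape).tocsr()
            np.add.at(f_robin, edges[:, 0], spec.h_inf * spec.T_inf * le / 2.0)
            np.add.at(f_robin, edges[:, 1], spec.h_inf * spec.T_inf * le / 2.0)
            continue
        raise ConfigurationError(f"unknown boundary condition {spec!r} for tag {tag!r}")

    if dir_nodes:
        nodes_cat = np.concatenate(dir_nodes)
        vals_cat = np.concatenate(dir_vals)
        nodes_u, idx = np.unique(nodes_cat, return_index=True)
        vals_u = vals_cat[idx]
    else:
        nodes_u = np.empty(0, dtype=np.int64)
        vals_u = np.empty(0)

    K = (K_cond + K_perf + H).tocsr()
    f = f_met + f_perf + f_robin
    return AssembledSystem(
        K=K,
        M=M.tocsr(),
        f=f,
        dirichlet_nodes=nodes_u,
        dirichlet_values=vals_u,
        components={
            "K_cond": K_cond,
            "K_perf": K_perf,
            "H": H,
            "f_met": f_met,
            "f_perf": f_perf,
            "f_robin": f_robin,
        },
    )


def solve_steady(system: AssembledSystem, rtol: float = 1e-10) -> TemperatureField:
    """Direct sparse solve of the steady system, with a residual check."""
    if len(system.dirichlet_nodes) == 0 and system.components:
        robin = system.components["H"]
        perf = system.components["K_perf"]
        if (abs(robin).max() if robin.nnz else 0.0) == 0.0 and (
            abs(perf).max() if perf.nnz else 0.0
        ) == 0.0:
            raise ConfigurationError(
                "steady system is singular: no Dirichlet or Robin boundary and "
                "no perfusion anchors the temperature level"
            )
    x = np.zeros(system.n)
    x[system.dirichlet_nodes] = system.dirichlet_values
    free = system.free
    K = system.K
    rhs = system.f[free] - K[np.ix_(free, system.dirichlet_nodes)] @ system.dirichlet_values
    Kff = K[np.ix_(free, free)].tocsc()
    try:
        lu = spla.splu(Kff)
    except RuntimeError as err:  # singular: e.g. all-adiabatic with no perfusion
        raise ConfigurationError(f"steady system is singular: {err}") from err
    x[free] = lu.solve(rhs)
    resid = np.linalg.norm(Kff @ x[free] - rhs)
    scale = max(np.linalg.norm(rhs), 1.0)
    if not np.isfinite(resid) or resid > rtol * scale:
        raise SolverError(f"steady solve residual {resid:.3e} exceeds {rtol:.0e} * |f|")
    return TemperatureField(time="steady", values=x)


@dataclass(frozen=True)
class Phase:
    """One constant-BC interval of a transient run."""

    t_start: float
    t_end: float
    dt: float
    bc: BCSet


def solve_transient(
    mesh: Mesh,
    props: ElementProperties | dict,
    phases: Sequence[Phase],
    T0: TemperatureField,
    snapshot_times: Sequence[float] | None = None,
) -> list[TemperatureField]:
    """Backward-Euler time integration across constant-BC phases.

    Boundary-condition switches occur exactly at phase boundaries.  The
    returned snapshots are taken at ``snapshot_times`` (which must lie on
    the step grid); when omitted, every step is returned.
    """
    if len(T0.values) != mesh.n_nodes:
        raise SolverError("initial field does not match the mesh")
    for a, b in zip(phases[:-1], phases[1:]):
        if not np.isclose(a.t_end, b.t_start):
            raise SolverError("phases must be contiguous in time")
    want = None if snapshot_times is None else np.asarray(sorted(snapshot_times), float)
    out: list[TemperatureField] = []
    T = T0.values.copy()

    def record(t: float, vals: np.ndarray) -> None:
        if want is None or np.any(np.isclose(want, t, rtol=0.0, atol=1e-9)):
            out.append(TemperatureField(time=float(t), values=vals.copy()))

    for phase in phases:
        nsteps = int(round((phase.t_end - phase.t_start) / phase.dt))
        if not np.isclose(phase.t_start + nsteps * phase.dt, phase.t_end):
            raise SolverError(
                f"phase [{phase.t_start}, {phase.t_end}] not divisible by dt={phase.dt}"
            )
        system = assemble(mesh, props, phase.bc)
        free = system.free
        dn, dv = system.dirichlet_nodes, system.dirichlet_values
        A = (system.M / phase.dt + system.K).tocsr()
        Aff = A[np.ix_(free, free)].tocsc()
        Afd = A[np.ix_(free, dn)]
        lu = spla.splu(Aff)
        Mdt = (system.M / phase.dt).tocsr()
        # impose the new Dirichlet data instantaneously at the phase start
        if len(dn):
            T[dn] = dv
        if phase is phases[0]:
            record(phase.t_start, T)
        base = system.f[free] - (Afd @ dv if len(dn) else 0.0)
        for n in range(1, nsteps + 1):
            rhs = (Mdt @ T)[free] + base
            T[free] = lu.solve(rhs)
            record(phase.t_start + n * phase.dt, T)
    return out


def steady_energy_balance(system: AssembledSystem, field: TemperatureField) -> dict:
    """Discrete steady heat budget (W per unit depth of the 2D section).

    Sources (metabolism + net perfusion + net convective intake) balance
    the reaction fluxes extracted at Dirichlet boundaries.
    """
    x = field.values
    c = system.components
    ones = np.ones(system.n)
    q_met = float(ones @ c["f_met"])
    q_perf = float(ones @ (c["f_perf"] - c["K_perf"] @ x))
    q_robin = float(ones @ (c["f_robin"] - c["H"] @ x))
    r = system.K @ x - system.f
    # r_d is the discrete flux a Dirichlet node injects into the domain, so
    # the heat the boundary extracts is its negative
    q_dirichlet_out = float(-r[system.dirichlet_nodes].sum())
    free_residual = float(np.linalg.norm(r[system.free]))
    return {
        "metabolic": q_met,
        "perfusion_net": q_perf,
        "convective_net": q_robin,
        "dirichlet_outflow": q_dirichlet_out,
        "free_residual": free_residual,
        "imbalance": q_met + q_perf + q_robin - q_dirichlet_out,
    }
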