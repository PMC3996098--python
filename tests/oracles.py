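"""Independent closed-form references used to verify the FEM solver.

These are deliberately written against the analytic structure of the
bioheat equation, not against the solver's discretization:

* :func:`multilayer_slab_steady` solves the steady 1D perfusion-slab
  problem per layer in closed form (cosh/sinh for perfused layers,
  parabolic/linear for non-perfused ones) and matches temperature and
  flux at the interfaces by solving a small dense linear system.
* :func:`halfspace_step_cooling` is the erf similarity solution for a
  conduction half-space whose surface temperature is stepped.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf


def multilayer_slab_steady(layers, h_inf, T_inf, T_core, x_eval):
    """Closed-form steady temperature of a layered 1D perfusion slab.

    The slab runs from the skin surface (x = 0, Robin condition with
    ``h_inf``/``T_inf``) to the core boundary (x = L, fixed ``T_core``).
    Each layer solves k T'' + w (T_b - T) + q = 0 with w = omega_b rho_b
    c_b.  Returns temperatures at ``x_eval``.
    """
    n = len(layers)
    x_if = np.concatenate([[0.0], np.cumsum([l.thickness for l in layers])])
    # per-layer particular solution and homogeneous basis evaluated locally
    params = []
    for layer in layers:
        p = layer.props
        w = p.perfusion_coefficient
        if w > 0:
            m = np.sqrt(w / p.k)
            part = lambda xh, p=p, w=w: np.full_like(xh, p.T_b + p.q_met / w, dtype=float)
            dpart = lambda xh: np.zeros_like(xh, dtype=float)
            f1 = lambda xh, m=m: np.cosh(m * xh)
            f2 = lambda xh, m=m: np.sinh(m * xh)
            d1 = lambda xh, m=m: m * np.sinh(m * xh)
            d2 = lambda xh, m=m: m * np.cosh(m * xh)
        else:
            part = lambda xh, p=p: -p.q_met / (2 * p.k) * xh**2
            dpart = lambda xh, p=p: -p.q_met / p.k * xh
            f1 = lambda xh: np.ones_like(xh, dtype=float)
            f2 = lambda xh: xh.astype(float) if hasattr(xh, "astype") else float(xh)
            d1 = lambda xh: np.zeros_like(xh, dtype=float)
            d2 = lambda xh: np.ones_like(xh, dtype=float)
        params.append((part, dpart, f1, f2, d1, d2))

    # unknowns: (A_i, B_i) per layer; equations: Robin at 0, continuity of
    # T and k T' at each interface, Dirichlet at L
    A = np.zeros((2 * n, 2 * n))
    b = np.zeros(2 * n)
    row = 0
    # Robin at x=0 (local coordinate 0 of layer 0): k T'(0) = h (T(0) - T_inf)
    part, dpart, f1, f2, d1, d2 = params[0]
    k0 = layers[0].props.k
    z = np.array(0.0)
    A[row, 0] = k0 * d1(z) - h_inf * f1(z)
    A[row, 1] = k0 * d2(z) - h_inf * f2(z)
    b[row] = h_inf * (part(z) - T_inf) - k0 * dpart(z)
    row += 1
    for i in range(n - 1):
        Li = np.array(layers[i].thickness)
        z = np.array(0.0)
        pa, dpa, f1a, f2a, d1a, d2a = params[i]
        pb, dpb, f1b, f2b, d1b, d2b = params[i + 1]
        ka, kb = layers[i].props.k, layers[i + 1].props.k
        # temperature continuity
        A[row, 2 * i] = f1a(Li)
        A[row, 2 * i + 1] = f2a(Li)
        A[row, 2 * i + 2] = -f1b(z)
        A[row, 2 * i + 3] = -f2b(z)
        b[row] = pb(z) - pa(Li)
        row += 1
        # flux continuity
        A[row, 2 * i] = ka * d1a(Li)
        A[row, 2 * i + 1] = ka * d2a(Li)
        A[row, 2 * i + 2] = -kb * d1b(z)
        A[row, 2 * i + 3] = -kb * d2b(z)
        b[row] = kb * dpb(z) - ka * dpa(Li)
        row += 1
    Ln = np.array(layers[-1].thickness)
    pa, dpa, f1a, f2a, _, _ = params[-1]
    A[row, 2 * n - 2] = f1a(Ln)
    A[row, 2 * n - 1] = f2a(Ln)
    b[row] = T_core - pa(Ln)
    coeffs = np.linalg.solve(A, b)

    out = np.empty_like(np.asarray(x_eval, dtype=float))
    for j, x in enumerate(np.atleast_1d(x_eval)):
        i = min(np.searchsorted(x_if, x, side="right") - 1, n - 1)
        xh = np.array(x - x_if[i])
        part, dpart, f1, f2, _, _ = params[i]
        out[j] = part(xh) + coeffs[2 * i] * f1(xh) + coeffs[2 * i + 1] * f2(xh)
    return out


def halfspace_step_cooling(x, t, T_init, T_surface, alpha):
    """erf similarity solution: surface stepped to T_surface at t = 0."""
    return T_surface + (T_init - T_surface) * erf(
        np.asarray(x, float) / (2.0 * np.sqrt(alpha * t))
    )
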