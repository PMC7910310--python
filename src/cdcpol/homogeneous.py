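"""Homogeneous (well-mixed) analysis: steady states and the trapping region.

The spatially averaged reduced system is

    dū/dτ = γ f(ū, v̄),
    dv̄/dτ = γ (−f(ū, v̄) + q0(ū, v̄)),

with q0 the averaged flux (cytosol eliminated via mass conservation).  Steady
states satisfy f = q0 = 0.  From f = 0 the inactive form is slaved,
v = u/(c2 + u²); substituting into q0 = 0 and clearing denominators yields a
degree-6 polynomial in u, so there are at most six positive steady states and
(for simple roots) an even number of them.  Physically valid states live in the
trapping region A = {u, v ≥ 0 : u + v ≤ min(c_max, V0/a)}, which homogeneous
trajectories cannot leave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import ModelParams, q0_homogeneous, reaction_f

__all__ = [
    "SteadyState",
    "TrappingRegion",
    "steady_state_polynomial",
    "find_steady_states",
    "newton_refine",
    "in_trapping_region",
    "necessary_condition",
    "select_patterning_state",
    "integrate_homogeneous",
    "v_slaved",
]


def v_slaved(u, params: ModelParams):
    """Inactive-form concentration on the f = 0 nullcline: v = u/(c2 + u²)."""
    u = np.asarray(u, dtype=float)
    return u / (params.c2 + u * u)


@dataclass(frozen=True)
class SteadyState:
    """A root (u*, v*, V*) of the homogeneous system with stability metadata."""

    u_star: float
    v_star: float
    V_star: float
    in_trapping_region: bool
    satisfies_necessary_condition: bool
    homogeneous_stable: bool
    degenerate: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.u_star, self.v_star, self.V_star)


@dataclass(frozen=True)
class TrappingRegion:
    """The invariant region A of the homogeneous dynamics."""

    bound: float
    m: float

    @classmethod
    def of(cls, params: ModelParams) -> "TrappingRegion":
        return cls(bound=params.trapping_bound, m=params.m)

    def contains(self, u, v, tol: float = 0.0) -> bool | np.ndarray:
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        inside = (u >= -tol) & (v >= -tol) & (u + v <= self.bound + tol)
        return bool(inside) if inside.ndim == 0 else inside


def in_trapping_region(u, v, params: ModelParams, tol: float = 0.0):
    """True iff (u, v) lies in A = {u, v >= 0, u + v <= min(c_max, m)}."""
    return TrappingRegion.of(params).contains(u, v, tol=tol)


def steady_state_polynomial(params: ModelParams) -> np.ndarray:
    """Coefficients (ascending) of the degree-6 steady-state polynomial in u.

    With P(u) = c2 + u² and s(u)·P = u·(P + 1), the condition q0(u, v(u)) = 0
    multiplied by P² reads

        c1·a·(c_max·P − u(P+1))·(m·P − u(P+1)) − c_minus1·u·P = 0.
    """
    c2 = params.c2
    P = np.array([c2, 0.0, 1.0])  # c2 + u^2
    uP1 = np.array([0.0, c2 + 1.0, 0.0, 1.0])  # u*(P+1)
    A = npoly.polysub(params.c_max * P, uP1)
    B = npoly.polysub(params.m * P, uP1)
    poly = params.c1 * params.a * npoly.polymul(A, B)
    poly = npoly.polysub(poly, params.c_minus1 * npoly.polymul([0.0, 1.0], P))
    return poly


def _homogeneous_jacobian_entries(u: float, v: float, params: ModelParams):
    """Entries of the Jacobian of (γf, γ(−f + q0)) at (u, v)."""
    g = params.gamma
    f_u = 2.0 * u * v - 1.0
    f_v = params.c2 + u * u
    s = u + v
    dq0 = -params.c1 * params.a * ((params.m - s) + (params.c_max - s))
    q0_u = dq0
    q0_v = dq0 - params.c_minus1
    return np.array(
        [[g * f_u, g * f_v], [g * (-f_u + q0_u), g * (-f_v + q0_v)]]
    )


def _is_stable(J: np.ndarray, tol: float = 0.0) -> bool:
    tr = J[0, 0] + J[1, 1]
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    return (tr < -tol) and (det > tol)


def _make_state(u: float, params: ModelParams, degenerate: bool = False) -> SteadyState:
    v = float(v_slaved(u, params))
    V = params.V0 - params.a * (u + v)
    J = _homogeneous_jacobian_entries(u, v, params)
    bound = params.trapping_bound
    nec = (np.sqrt(params.c2) < bound) and (np.sqrt(params.c2) < u < bound)
    return SteadyState(
        u_star=u,
        v_star=v,
        V_star=V,
        in_trapping_region=bool(in_trapping_region(u, v, params)),
        satisfies_necessary_condition=bool(nec),
        homogeneous_stable=_is_stable(J),
        degenerate=degenerate,
    )


def find_steady_states(
    params: ModelParams,
    tol: float = 1e-10,
    degeneracy_rtol: float = 1e-6,
) -> list[SteadyState]:
    """All positive steady states of the homogeneous system, ascending in u*.

    Roots come from the companion matrix of the steady-state polynomial and are
    polished by Newton iteration on q0(u, v(u)).  Near-multiple roots (closer
    than ``degeneracy_rtol`` relative spacing) are flagged ``degenerate``; for
    simple roots the count of strictly positive states is even (0, 2, 4 or 6).
    """
    coeffs = steady_state_polynomial(params)
    roots = npoly.polyroots(coeffs)
    scale = 1.0 + max(params.c_max, params.m)
    real = roots[np.abs(roots.imag) < 1e-9 * scale].real
    positive = np.sort(real[real > tol])

    # Newton polish on g(u) = q0(u, v(u)); the polynomial roots are already
    # accurate, this just tightens against the original (unscaled) residual.
    polished = []
    for u in positive:
        for _ in range(50):
            g = float(q0_homogeneous(u, v_slaved(u, params), params))
            h = 1e-7 * (1.0 + abs(u))
            gp = (
                float(q0_homogeneous(u + h, v_slaved(u + h, params), params))
                - float(q0_homogeneous(u - h, v_slaved(u - h, params), params))
            ) / (2.0 * h)
            if gp == 0.0:
                break
            step = g / gp
            u_new = u - step
            if u_new <= 0:
                break
            u = u_new
            if abs(step) < 1e-14 * (1.0 + abs(u)):
                break
        polished.append(u)
    polished = np.sort(np.asarray(polished))

    states: list[SteadyState] = []
    for i, u in enumerate(polished):
        near = False
        if i > 0 and abs(u - polished[i - 1]) < degeneracy_rtol * scale:
            near = True
        if i + 1 < len(polished) and abs(polished[i + 1] - u) < degeneracy_rtol * scale:
            near = True
        if near and states and abs(states[-1].u_star - u) < degeneracy_rtol * scale:
            # collapse a near-multiple pair into one flagged root
            continue
        states.append(_make_state(float(u), params, degenerate=near))
    return states


def newton_refine(
    u0: float,
    params: ModelParams,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> SteadyState:
    """Newton's method on (f, q0) from a start guess in the necessary-condition bracket.

    The start pair is (u0, v0) with v0 = u0/(c2 + u0²).  If the Jacobian turns
    singular or the iteration leaves (0, ∞) the solver falls back to bracketed
    bisection on the reduced polynomial, so a converged result is always a true
    root, never a spurious one.

    Raises
    ------
    RuntimeError
        if neither Newton nor the bisection fallback converges.
    """
    u, v = float(u0), float(v_slaved(u0, params))
    for _ in range(max_iter):
        F = np.array(
            [
                float(reaction_f(u, v, params)),
                float(q0_homogeneous(u, v, params)),
            ]
        )
        if np.max(np.abs(F)) < tol:
            return _make_state(u, params)
        f_u = 2.0 * u * v - 1.0
        f_v = params.c2 + u * u
        s = u + v
        dq0 = -params.c1 * params.a * ((params.m - s) + (params.c_max - s))
        J = np.array([[f_u, f_v], [dq0, dq0 - params.c_minus1]])
        detJ = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        if abs(detJ) < 1e-14:
            break  # singular Jacobian -> fallback
        du, dv = np.linalg.solve(J, -F)
        u, v = u + du, v + dv
        if not (np.isfinite(u) and np.isfinite(v)) or u <= 0:
            break

    # Bracketed fallback: bisection on the steady-state polynomial around u0.
    coeffs = steady_state_polynomial(params)
    g = lambda x: npoly.polyval(x, coeffs)
    lo, hi = max(1e-12, 0.5 * u0), 2.0 * u0
    for _ in range(60):
        if g(lo) * g(hi) < 0:
            root = brentq(g, lo, hi, xtol=1e-14)
            return _make_state(float(root), params)
        lo *= 0.7
        hi *= 1.3
    raise RuntimeError(
        f"newton_refine diverged from u0={u0!r} and no bracket was found"
    )


def necessary_condition(params: ModelParams, ss: SteadyState) -> bool:
    """Necessary condition for diffusion-driven instability of a steady state.

    Requires sqrt(c2) < min(c_max, m) and u* strictly inside
    (sqrt(c2), min(c_max, m)).
    """
    bound = params.trapping_bound
    root = np.sqrt(params.c2)
    return bool(root < bound and root < ss.u_star < bound)


def select_patterning_state(params: ModelParams) -> SteadyState | None:
    """The steady state a simulation perturbs: the lowest-u* root satisfying
    the necessary condition (mirrors the Newton start-guess bracket)."""
    for ss in find_steady_states(params):
        if ss.satisfies_necessary_condition:
            return ss
    return None


def integrate_homogeneous(
    u0: float,
    v0: float,
    params: ModelParams,
    horizon: float,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
):
    """Integrate the averaged system dū/dτ = γf, dv̄/dτ = γ(−f + q0).

    Returns the scipy ``OdeResult``; uses a stiff-capable method so large γ
    poses no step-size problems.  Raises RuntimeError on integration failure,
    attaching the last valid state.
    """

    def rhs(_t, y):
        f = float(reaction_f(y[0], y[1], params))
        q0 = float(q0_homogeneous(y[0], y[1], params))
        return [params.gamma * f, params.gamma * (-f + q0)]

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [float(u0), float(v0)],
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        dense_output=t_eval is None,
    )
    if not sol.success:
        raise RuntimeError(
            f"homogeneous integration failed: {sol.message}; "
            f"last state t={sol.t[-1] if len(sol.t) else 0.0}, y={sol.y[:, -1] if sol.y.size else None}"
        )
    return sol
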