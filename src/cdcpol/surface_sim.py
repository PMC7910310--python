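"""Reaction-diffusion simulation of the reduced two-state system on the sphere.

The membrane is a triangulated unit sphere (subdivided icosahedron).  Surface
diffusion is discretised with the cotangent Laplace-Beltrami stiffness matrix
and a barycentric lumped mass matrix; time stepping is IMEX: diffusion is
treated implicitly (backward Euler, unconditionally stable) and the reactions
explicitly, with the uniform cytosolic concentration V recomputed from the
mass-conservation functional after every step.  Because V is defined as
V0 - (1/|Omega|) * sum_i w_i (u_i + v_i), the total discrete amount
|Omega|*V + sum_i w_i (u_i + v_i) = |Omega|*V0 is conserved identically.

Starting from a steady state perturbed by multiplicative uniform noise, an
unstable parameter set grows an inhomogeneous pattern; the run terminates when
the pole-recognition measures are stationary over a time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .model_core import (
    BALL_VOLUME,
    FieldPair,
    ModelParams,
    flux_q,
    nonlocal_V,
    reaction_f,
)
from .homogeneous import SteadyState, in_trapping_region, select_patterning_state

__all__ = [
    "SurfaceMesh",
    "SimOptions",
    "Trajectory",
    "build_icosphere",
    "assemble_laplace_beltrami",
    "initial_condition",
    "Stepper",
    "step",
    "simulate",
    "simulate_to_polarisation",
]


@dataclass
class SurfaceMesh:
    """Triangulated unit sphere with Laplace-Beltrami operators.

    ``stiffness`` is the (symmetric PSD) cotangent stiffness matrix with
    constants in its kernel; ``vertex_areas`` are barycentric lumped masses
    (one third of each incident triangle's area), summing to the discrete
    surface area.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_areas: np.ndarray
    stiffness: sp.csr_matrix
    adjacency: sp.csr_matrix

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def area(self) -> float:
        return float(self.vertex_areas.sum())

    @property
    def mass(self) -> sp.dia_matrix:
        return sp.diags(self.vertex_areas)

    def euler_characteristic(self) -> int:
        n_edges = (self.adjacency.nnz) // 2
        return self.n_vertices - n_edges + self.faces.shape[0]

    def integrate(self, field_values: np.ndarray) -> float:
        """Surface integral of a vertex field with lumped quadrature."""
        return float(self.vertex_areas @ field_values)


def assemble_laplace_beltrami(
    vertices: np.ndarray, faces: np.ndarray
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Cotangent stiffness matrix and lumped vertex areas for a triangle mesh.

    Raises
    ------
    ValueError
        if a triangle is degenerate (area below 1e-14), naming it.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    p0, p1, p2 = (vertices[faces[:, k]] for k in range(3))
    cross = np.cross(p1 - p0, p2 - p0)
    double_area = np.linalg.norm(cross, axis=1)
    bad = np.nonzero(double_area < 2e-14)[0]
    if bad.size:
        raise ValueError(f"degenerate triangle(s) at face index {bad[0]} (area < 1e-14)")

    rows, cols, vals = [], [], []
    # cot(angle at vertex c) weights edge (a, b)
    for ia, ib, ic in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        pa, pb, pc = vertices[faces[:, ia]], vertices[faces[:, ib]], vertices[faces[:, ic]]
        e1, e2 = pa - pc, pb - pc
        cot = np.einsum("ij,ij->i", e1, e2) / double_area
        w = 0.5 * cot
        rows += [faces[:, ia], faces[:, ib], faces[:, ia], faces[:, ib]]
        cols += [faces[:, ib], faces[:, ia], faces[:, ia], faces[:, ib]]
        vals += [-w, -w, w, w]
    n = vertices.shape[0]
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    areas = np.zeros(n)
    np.add.at(areas, faces.ravel(), np.repeat(double_area / 6.0, 3))
    return K, areas


def build_icosphere(subdivisions: int) -> SurfaceMesh:
    """Icosahedron subdivided ``subdivisions`` times, projected to the sphere.

    Levels above 8 are rejected (the operator assembly would need gigabytes).
    Vertex count is 10*4^L + 2.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if subdivisions > 8:
        raise ValueError("subdivisions > 8 rejected (memory guard)")
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vertices = np.asarray(ico.vertices, dtype=float)
    vertices /= np.linalg.norm(vertices, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, dtype=np.int64)

    K, areas = assemble_laplace_beltrami(vertices, faces)
    n = vertices.shape[0]
    i = np.concatenate([faces[:, 0], faces[:, 1], faces[:, 2]])
    j = np.concatenate([faces[:, 1], faces[:, 2], faces[:, 0]])
    adj = sp.coo_matrix(
        (
            np.ones(2 * i.size, dtype=bool),
            (np.concatenate([i, j]), np.concatenate([j, i])),
        ),
        shape=(n, n),
    ).tocsr()
    adj.data[:] = True
    return SurfaceMesh(
        vertices=vertices,
        faces=faces,
        vertex_areas=areas,
        stiffness=K,
        adjacency=adj,
    )


@dataclass
class SimOptions:
    """Numerical options for a surface simulation.

    ``noise_amplitude`` is the relative amplitude of the multiplicative uniform
    noise perturbing the steady state; the seed is recorded in every report.
    """

    subdivisions: int = 5
    dt_initial: float = 1e-4
    dt_max: float = 5e-3
    noise_amplitude: float = 0.05
    seed: int = 0
    tau_max: float = 40.0
    stationarity_tol: float = 1e-4
    stationarity_window: float = 0.2
    output_stride: int = 50
    threshold_fraction: float = 0.5
    min_pole_area_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_amplitude <= 0:
            raise ValueError("noise_amplitude must be > 0")
        if self.dt_initial <= 0 or self.dt_max <= 0:
            raise ValueError("time steps must be > 0")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class Trajectory:
    """Snapshots and summary series of one simulation run."""

    times: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    mass: list = field(default_factory=list)
    u_max_series: list = field(default_factory=list)
    termination_reason: str = "running"
    tau_final: float = 0.0
    final_state: FieldPair | None = None
    seed: int | None = None

    def record(self, tau: float, state: FieldPair, mesh: SurfaceMesh) -> None:
        self.times.append(tau)
        self.snapshots.append(state.copy())
        self.mass.append(total_mass(state, mesh))
        self.u_max_series.append(float(state.u.max()))


def total_mass(state: FieldPair, mesh: SurfaceMesh) -> float:
    """Total discrete amount |Omega|*V + integral of (u + v) over the surface."""
    return BALL_VOLUME * state.V + mesh.integrate(state.u + state.v)


def initial_condition(
    ss: SteadyState, opts: SimOptions, mesh: SurfaceMesh, params: ModelParams
) -> FieldPair:
    """Steady state with multiplicative uniform noise: u_i = u*(1 + sigma*xi_i).

    xi are i.i.d. uniform on (-1, 1) from a generator seeded with ``opts.seed``,
    so identical options give identical fields.  Warns (via nonlocal_V /
    trapping check) if the perturbed field leaves the valid region pointwise.
    """
    rng = np.random.default_rng(opts.seed)
    n = mesh.n_vertices
    xi_u = rng.uniform(-1.0, 1.0, size=n)
    xi_v = rng.uniform(-1.0, 1.0, size=n)
    u = ss.u_star * (1.0 + opts.noise_amplitude * xi_u)
    v = ss.v_star * (1.0 + opts.noise_amplitude * xi_v)
    inside = in_trapping_region(u, v, params)
    if not np.all(inside):
        import warnings

        warnings.warn(
            "initial condition leaves the trapping region at "
            f"{int(np.sum(~inside))} vertices",
            stacklevel=2,
        )
    V = nonlocal_V(u, v, mesh, params)
    return FieldPair(u=u, v=v, V=V)


class Stepper:
    """IMEX (implicit diffusion / explicit reaction) integrator on a mesh.

    Sparse LU factors of M + dt*K and M + dt*d*K are cached per dt, so the
    adaptive controller pays a refactorisation only when dt changes.
    """

    def __init__(self, mesh: SurfaceMesh, params: ModelParams):
        self.mesh = mesh
        self.params = params
        self._lu_cache: dict[float, tuple] = {}

    def _factors(self, dt: float):
        lu = self._lu_cache.get(dt)
        if lu is None:
            M = self.mesh.mass.tocsc()
            K = self.mesh.stiffness.tocsc()
            lu = (
                splu((M + dt * K)),
                splu((M + dt * self.params.d * K)),
            )
            self._lu_cache[dt] = lu
        return lu

    def step(self, state: FieldPair, dt: float) -> FieldPair:
        """One IMEX backward-Euler step; V recomputed from the functional."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        p = self.params
        f = reaction_f(state.u, state.v, p)
        q = flux_q(state.u, state.v, state.V, p)
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(q))):
            raise FloatingPointError(
                "NaN/Inf in reaction terms; state max |u|="
                f"{np.abs(state.u).max():.3e}, |v|={np.abs(state.v).max():.3e}"
            )
        w = self.mesh.vertex_areas
        rhs_u = w * (state.u + dt * p.gamma * f)
        rhs_v = w * (state.v + dt * p.gamma * (-f + q))
        lu_u, lu_v = self._factors(dt)
        u_new = lu_u.solve(rhs_u)
        v_new = lu_v.solve(rhs_v)
        if not (np.all(np.isfinite(u_new)) and np.all(np.isfinite(v_new))):
            raise FloatingPointError("linear solve produced non-finite values")
        V_new = nonlocal_V(u_new, v_new, self.mesh, p, warn=False)
        return FieldPair(u=u_new, v=v_new, V=V_new)


def step(state: FieldPair, dt: float, params: ModelParams, mesh: SurfaceMesh) -> FieldPair:
    """Single IMEX step (convenience wrapper over :class:`Stepper`)."""
    return Stepper(mesh, params).step(state, dt)


def _quantised_dt(dt: float) -> float:
    # keep dt on a discrete ladder so LU factors are reused
    return float(np.round(dt, 12))


def simulate(
    params: ModelParams,
    opts: SimOptions,
    mesh: SurfaceMesh | None = None,
    ss: SteadyState | None = None,
    record: bool = True,
):
    """Run the surface simulation until pattern stationarity or tau_max.

    Adaptive stepping: dt grows by 1.2 (up to dt_max, additionally capped by
    0.5/γ for the explicit reactions) while the relative change per step is
    below 1%, and halves when it exceeds 10%.  Every ``stationarity_window``
    of τ the pole measures are evaluated; the run terminates as ``polarised``
    when the pole count and relative area are unchanged across a window and
    the field moves less than ``stationarity_tol`` relative per window, or as
    ``no_pattern`` when the same stationarity holds with zero poles.  Runs
    reaching ``tau_max`` are labelled ``max_tau`` if poles are present (a
    pattern that never went fully stationary, e.g. slowly competing poles) and
    ``no_pattern`` otherwise.

    Returns (trajectory, mesh).
    """
    from .pole_metrics import detect_poles

    if mesh is None:
        mesh = build_icosphere(opts.subdivisions)
    if ss is None:
        ss = select_patterning_state(params)
        if ss is None:
            raise ValueError("no steady state satisfies the necessary condition")

    state = initial_condition(ss, opts, mesh, params)
    stepper = Stepper(mesh, params)
    traj = Trajectory(seed=opts.seed)
    traj.record(0.0, state, mesh)

    dt_cap = min(opts.dt_max, 0.5 / params.gamma)
    dt = min(opts.dt_initial, dt_cap)
    tau = 0.0
    n_steps = 0
    next_check = opts.stationarity_window
    prev_u_at_check = state.u.copy()
    prev_measures = None
    u_scale = max(abs(ss.u_star), 1e-12)

    while tau < opts.tau_max:
        new_state = stepper.step(state, dt)
        rel_change = float(np.max(np.abs(new_state.u - state.u))) / max(
            float(np.max(np.abs(state.u))), u_scale
        )
        tau += dt
        state = new_state
        n_steps += 1
        if record and n_steps % opts.output_stride == 0:
            traj.record(tau, state, mesh)

        if rel_change < 0.01 and dt < dt_cap:
            dt = _quantised_dt(min(dt * 1.2, dt_cap))
        elif rel_change > 0.10 and dt > opts.dt_initial:
            dt = _quantised_dt(max(dt * 0.5, opts.dt_initial))

        if tau >= next_check:
            count, area, _ = detect_poles(
                state.u,
                mesh,
                threshold_fraction=opts.threshold_fraction,
                min_area_fraction=opts.min_pole_area_fraction,
            )
            window_change = float(np.max(np.abs(state.u - prev_u_at_check))) / max(
                float(np.max(np.abs(state.u))), u_scale
            )
            measures = (count, round(area, 4))
            stationary = (
                prev_measures is not None
                and measures == prev_measures
                and window_change < opts.stationarity_tol
            )
            if stationary and tau > 1.0:
                traj.termination_reason = "polarised" if count >= 1 else "no_pattern"
                break
            prev_measures = measures
            prev_u_at_check = state.u.copy()
            next_check += opts.stationarity_window

    if traj.termination_reason == "running":
        count, _, _ = detect_poles(
            state.u,
            mesh,
            threshold_fraction=opts.threshold_fraction,
            min_area_fraction=opts.min_pole_area_fraction,
        )
        traj.termination_reason = "max_tau" if count >= 1 else "no_pattern"
    traj.tau_final = tau
    traj.final_state = state
    if record and (not traj.times or traj.times[-1] != tau):
        traj.record(tau, state, mesh)
    return traj, mesh


def simulate_to_polarisation(
    params: ModelParams,
    opts: SimOptions,
    mesh: SurfaceMesh | None = None,
    ss: SteadyState | None = None,
):
    """Simulate and summarise: returns (Trajectory, PoleReport)."""
    from .pole_metrics import summarise

    traj, mesh = simulate(params, opts, mesh=mesh, ss=ss)
    report = summarise(
        traj,
        mesh,
        params,
        threshold_fraction=opts.threshold_fraction,
        min_area_fraction=opts.min_pole_area_fraction,
    )
    return traj, report
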