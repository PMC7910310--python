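"""Pole recognition and quantitative polarisation measures.

A pole is a connected patch of elevated active-form concentration on the
membrane.  Recognition thresholds the vertex field at a fraction of its range
(u >= u_min + theta*(u_max - u_min)), takes connected components under mesh
adjacency, and discards components smaller than a minimum area fraction.  The
measures reported per run are the pole count, the pole area relative to the
total membrane area, the extreme concentrations u_max/u_min and the
polarisation time tau_final; sweeps over a parameter aggregate these over
seeded replicates as 5/50/95% quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .model_core import ModelParams

__all__ = [
    "PoleReport",
    "SweepTable",
    "detect_poles",
    "summarise",
    "sweep",
    "derive_seed",
]

MEASURES = ("pole_count", "relative_pole_area", "u_max", "u_min", "tau_final")


@dataclass
class PoleReport:
    """Final-pattern measures of one simulation run."""

    pole_count: int
    relative_pole_area: float
    u_max: float
    u_min: float
    tau_final: float
    seed: int | None = None
    termination_reason: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_pole_area <= 1.0):
            raise ValueError("relative_pole_area must lie in [0, 1]")
        if self.pole_count < 0:
            raise ValueError("pole_count must be >= 0")
        if self.u_min > self.u_max:
            raise ValueError("u_min must be <= u_max")

    def to_dict(self) -> dict:
        return {
            "pole_count": self.pole_count,
            "relative_pole_area": self.relative_pole_area,
            "u_max": self.u_max,
            "u_min": self.u_min,
            "tau_final": self.tau_final,
            "seed": self.seed,
            "termination_reason": self.termination_reason,
            "params": self.params,
        }


def detect_poles(
    u_field: np.ndarray,
    mesh,
    threshold_fraction: float = 0.5,
    min_area_fraction: float = 0.01,
) -> tuple[int, float, np.ndarray]:
    """Count poles of a vertex field and their total relative area.

    Vertices with u >= u_min + theta*(u_max - u_min) form the candidate set;
    connected components under mesh adjacency are candidate poles; components
    covering less than ``min_area_fraction`` of the surface are discarded.
    A constant field has no poles by definition.  The detection is invariant
    under affine rescaling u -> alpha*u + beta with alpha > 0.

    Returns (pole_count, relative_area, labels) where ``labels`` assigns each
    vertex its pole index (-1 outside any pole).
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    u = np.asarray(u_field, dtype=float)
    labels = np.full(u.size, -1, dtype=int)
    u_min, u_max = float(u.min()), float(u.max())
    if u_max - u_min < 1e-12 * max(1.0, abs(u_max)):
        return 0, 0.0, labels

    cut = u_min + threshold_fraction * (u_max - u_min)
    candidate = np.nonzero(u >= cut)[0]
    if candidate.size == 0:
        return 0, 0.0, labels

    sub = mesh.adjacency[candidate][:, candidate]
    n_comp, comp = connected_components(sub, directed=False)
    total_area = mesh.area
    pole_id = 0
    rel_area = 0.0
    for c in range(n_comp):
        members = candidate[comp == c]
        area = float(mesh.vertex_areas[members].sum())
        if area / total_area >= min_area_fraction:
            labels[members] = pole_id
            rel_area += area / total_area
            pole_id += 1
    return pole_id, rel_area, labels


def summarise(
    trajectory,
    mesh,
    params: ModelParams | None = None,
    threshold_fraction: float = 0.5,
    min_area_fraction: float = 0.01,
) -> PoleReport:
    """Pole measures of a terminated trajectory, evaluated at tau_final."""
    state = trajectory.final_state
    if state is None:
        raise ValueError("trajectory has no final state (not terminated)")
    count, rel_area, _ = detect_poles(
        state.u,
        mesh,
        threshold_fraction=threshold_fraction,
        min_area_fraction=min_area_fraction,
    )
    return PoleReport(
        pole_count=count,
        relative_pole_area=rel_area,
        u_max=float(state.u.max()),
        u_min=float(state.u.min()),
        tau_final=trajectory.tau_final,
        seed=trajectory.seed,
        termination_reason=trajectory.termination_reason,
        params={} if params is None else params.to_dict(),
    )


def derive_seed(base_seed: int, value_index: int, replicate: int) -> int:
    """Deterministic per-run seed for sweeps, below 2^31."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(value_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SweepTable:
    """Per-run reports and quantile summaries of a one-parameter sweep."""

    parameter: str
    values: tuple
    runs: pd.DataFrame
    quantiles: pd.DataFrame
    failures: int = 0

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        payload = {
            "parameter": self.parameter,
            "values": list(self.values),
            "runs": self.runs.to_dict(orient="records"),
            "quantiles": self.quantiles.to_dict(orient="records"),
            "failures": self.failures,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def sweep(
    param_name: str,
    values,
    base_params: ModelParams,
    opts,
    n_seeds: int = 20,
    base_seed: int = 0,
    mesh=None,
) -> SweepTable:
    """Run ``n_seeds`` seeded simulations per parameter value and aggregate.

    ``param_name`` is one of the ModelParams fields (typically d or gamma).
    Per-run seeds derive deterministically from ``base_seed`` so the whole
    table is reproducible; individual run failures are recorded and excluded
    from the quantiles.
    """
    from dataclasses import replace as dc_replace

    from .surface_sim import build_icosphere, simulate_to_polarisation

    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    values = tuple(values)
    if mesh is None:
        mesh = build_icosphere(opts.subdivisions)

    rows = []
    failures = 0
    for vi, value in enumerate(values):
        params = base_params.replace(**{param_name: float(value)})
        for rep in range(n_seeds):
            run_seed = derive_seed(base_seed, vi, rep)
            run_opts = dc_replace(opts, seed=run_seed)
            try:
                _, report = simulate_to_polarisation(params, run_opts, mesh=mesh)
            except (RuntimeError, FloatingPointError, ValueError) as exc:
                failures += 1
                rows.append(
                    {
                        param_name: value,
                        "replicate": rep,
                        "seed": run_seed,
                        "failed": True,
                        "error": str(exc),
                    }
                )
                continue
            row = {
                param_name: value,
                "replicate": rep,
                "seed": run_seed,
                "failed": False,
                "error": "",
            }
            row.update({k: getattr(report, k) for k in MEASURES})
            row["termination_reason"] = report.termination_reason
            rows.append(row)

    runs = pd.DataFrame(rows)
    ok = runs[~runs["failed"]]
    qrows = []
    for value in values:
        sub = ok[ok[param_name] == value]
        for measure in MEASURES:
            if sub.empty:
                continue
            q5, q50, q95 = np.quantile(sub[measure].to_numpy(float), [0.05, 0.5, 0.95])
            qrows.append(
                {
                    param_name: value,
                    "measure": measure,
                    "q05": q5,
                    "q50": q50,
                    "q95": q95,
                    "n": len(sub),
                }
            )
    quantiles = pd.DataFrame(qrows)
    return SweepTable(
        parameter=param_name,
        values=values,
        runs=runs,
        quantiles=quantiles,
        failures=failures,
    )


def plot_sweep(table: SweepTable, measure: str, path=None):
    """Quantile plot (5/50/95%) of one measure against the swept parameter."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table.quantiles[table.quantiles["measure"] == measure]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = sub[table.parameter]
    ax.plot(x, sub["q50"], "-o", label="median")
    ax.plot(x, sub["q05"], "--", color="grey", label="5%")
    ax.plot(x, sub["q95"], "--", color="grey", label="95%")
    ax.set_xlabel(table.parameter)
    ax.set_ylabel(measure)
    ax.legend()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
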