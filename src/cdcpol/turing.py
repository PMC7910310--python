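"""Linear stability: dispersion relation and classic/non-classic Turing maps.

Perturbations of a homogeneous steady state split into the spatially uniform
mode (degree l = 0) and inhomogeneous spherical-harmonic modes (l >= 1, squared
wavenumber k² = l(l+1)).  The uniform mode feels the mass-conservation
coupling through the averaged flux q0 and is governed by the homogeneous
Jacobian.  Inhomogeneous modes integrate to zero over the sphere, so the
nonlocal cytosolic term drops out and they are governed by the *local*
Jacobian J_loc (q linearised at fixed V = V*) shifted by diffusion:

    M(k²) = γ·J_loc − diag(k², d·k²).

Two routes to diffusion-driven instability:

* classic — J_loc is itself stable but unequal diffusion (d > 1) opens a band
  of unstable wavenumbers: det J_loc > 0 and d·a11 + a22 > 2·sqrt(d·det J_loc);
* non-classic — J_loc is a saddle (det J_loc < 0) while the uniform mode is
  stabilised by the mass coupling; holds for every d, including d = 1.

Classification uses these algebraic conditions on the continuous wavenumber
(they are γ-free, exactly d-independent in the non-classic case, and classic
regions are exactly nested in d); :func:`dispersion` additionally evaluates the
integer sphere spectrum, which decides whether an unstable mode actually fits
on the sphere for a given γ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .homogeneous import (
    SteadyState,
    _homogeneous_jacobian_entries,
    find_steady_states,
)
from .model_core import ModelParams

__all__ = [
    "CLASSIC",
    "NONCLASSIC",
    "NONE",
    "INDETERMINATE",
    "DispersionResult",
    "RegionMap",
    "homogeneous_jacobian",
    "local_jacobian",
    "mode_matrix",
    "dispersion",
    "classify",
    "map_parameter_plane",
]

CLASSIC = "classic"
NONCLASSIC = "nonclassic"
NONE = "none"
INDETERMINATE = "indeterminate"

#: |det J_loc| below this (relative to the squared matrix scale) is too close
#: to the saddle/node boundary to classify; such points are excluded from maps.
DET_TOL = 1e-9


def homogeneous_jacobian(ss: SteadyState, params: ModelParams) -> np.ndarray:
    """Jacobian of the averaged system (γf, γ(−f + q0)) at the steady state.

    Includes the mass-conservation coupling: the derivative of the
    (c_max − s)(m − s) factor with respect to both states.
    """
    return _homogeneous_jacobian_entries(ss.u_star, ss.v_star, params)


def local_jacobian(ss: SteadyState, params: ModelParams) -> np.ndarray:
    """Reaction Jacobian seen by inhomogeneous modes (q at fixed V = V*).

    J_loc = [[f_u, f_v], [−f_u + q_u, −f_v + q_v]] with q_u = −c1·V*,
    q_v = −c1·V* − c_minus1.
    """
    u, v = ss.u_star, ss.v_star
    f_u = 2.0 * u * v - 1.0
    f_v = params.c2 + u * u
    q_u = -params.c1 * ss.V_star
    q_v = q_u - params.c_minus1
    return np.array([[f_u, f_v], [-f_u + q_u, -f_v + q_v]])


def mode_matrix(ss: SteadyState, params: ModelParams, k2: float) -> np.ndarray:
    """Linearised operator of an inhomogeneous mode with squared wavenumber k²."""
    if k2 < 0:
        raise ValueError("squared wavenumber k2 must be >= 0")
    M = params.gamma * local_jacobian(ss, params)
    M[0, 0] -= k2
    M[1, 1] -= params.d * k2
    return M


def _max_real_eig_2x2(a11, a12, a21, a22):
    """Largest real part of the eigenvalues of stacked 2x2 matrices."""
    tr = a11 + a22
    disc = (a11 - a22) ** 2 + 4.0 * a12 * a21
    disc = np.asarray(disc, dtype=complex)
    return np.real(0.5 * (tr + np.sqrt(disc)))


@dataclass
class DispersionResult:
    """Growth rates per spherical-harmonic degree plus the classification."""

    steady_state: SteadyState
    degrees: np.ndarray
    growth_rates: np.ndarray
    classification: str
    unstable_degrees: np.ndarray
    reason: str = ""

    @property
    def growth_rate_by_degree(self) -> dict[int, float]:
        return {int(l): float(g) for l, g in zip(self.degrees, self.growth_rates)}


def _algebraic_class(ss: SteadyState, params: ModelParams) -> tuple[str, str]:
    """Continuous-wavenumber Turing classification; returns (label, reason)."""
    J_hom = homogeneous_jacobian(ss, params)
    tr_h = J_hom[0, 0] + J_hom[1, 1]
    det_h = J_hom[0, 0] * J_hom[1, 1] - J_hom[0, 1] * J_hom[1, 0]
    if not (tr_h < 0 and det_h > 0):
        return NONE, "homogeneous_unstable"

    J = local_jacobian(ss, params)
    a11, a22 = J[0, 0], J[1, 1]
    det = a11 * a22 - J[0, 1] * J[1, 0]
    scale = max(np.abs(J).max() ** 2, 1e-30)
    if abs(det) < DET_TOL * scale:
        return INDETERMINATE, "det_jloc_near_zero"
    if det < 0:
        return NONCLASSIC, "saddle_inhomogeneous"
    h = params.d * a11 + a22
    if h > 0 and h * h > 4.0 * params.d * det:
        return CLASSIC, "diffusion_band"
    return NONE, "no_unstable_band"


def dispersion(
    ss: SteadyState, params: ModelParams, l_max: int = 50
) -> DispersionResult:
    """Growth rates over sphere degrees l = 0..l_max and the classification.

    Degree 0 uses the homogeneous Jacobian (mass coupling included); degrees
    l >= 1 use the mode matrix at k² = l(l+1).  The classification follows the
    algebraic conditions but is demoted to ``none`` when no integer degree
    l >= 1 is actually unstable (γ too small to fit an unstable mode).
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    degrees = np.arange(l_max + 1)
    k2 = degrees * (degrees + 1.0)

    J_hom = homogeneous_jacobian(ss, params)
    J = params.gamma * local_jacobian(ss, params)
    a11 = J[0, 0] - k2
    a22 = J[1, 1] - params.d * k2
    growth = _max_real_eig_2x2(a11, J[0, 1], J[1, 0], a22)
    growth[0] = _max_real_eig_2x2(
        J_hom[0, 0], J_hom[0, 1], J_hom[1, 0], J_hom[1, 1]
    )

    unstable = degrees[(degrees >= 1) & (growth > 0.0)]
    label, reason = _algebraic_class(ss, params)
    if label in (CLASSIC, NONCLASSIC) and unstable.size == 0:
        label, reason = NONE, "no_unstable_integer_degree"
    if growth[0] >= 0.0:
        label, reason = NONE, "homogeneous_unstable"
    return DispersionResult(
        steady_state=ss,
        degrees=degrees,
        growth_rates=growth,
        classification=label,
        unstable_degrees=unstable,
        reason=reason,
    )


def classify(
    ss: SteadyState, params: ModelParams, l_max: int | None = None
) -> str:
    """Turing classification of a steady state: classic, nonclassic, none.

    With ``l_max`` given, an unstable integer degree l <= l_max is additionally
    required (as in :func:`dispersion`); without it the γ-free algebraic
    conditions alone decide, which is what the parameter-plane maps use.
    """
    if l_max is not None:
        return dispersion(ss, params, l_max=l_max).classification
    return _algebraic_class(ss, params)[0]


def classify_params(params: ModelParams, l_max: int | None = None) -> str:
    """Classify a parameter point via its patterning steady state.

    Selects the lowest-u* root inside the bracket (sqrt(c2), min(c_max, m));
    returns ``none`` when no steady state satisfies the necessary condition.
    """
    from .homogeneous import select_patterning_state

    ss = select_patterning_state(params)
    if ss is None:
        return NONE
    return classify(ss, params, l_max=l_max)


@dataclass
class RegionMap:
    """Classification of a 2-parameter plane for a list of relative diffusions.

    ``classic`` maps each d to a boolean grid; ``nonclassic`` and ``none`` are
    d-independent boolean grids; ``indeterminate`` counts excluded points.
    """

    axis_names: tuple[str, str]
    axis1: np.ndarray
    axis2: np.ndarray
    d_list: tuple[float, ...]
    classic: dict[float, np.ndarray]
    nonclassic: np.ndarray
    none: np.ndarray
    indeterminate_count: int = 0
    fixed: dict = field(default_factory=dict)

    def to_dataframe(self):
        """Long-format table: axis1, axis2, d, label."""
        import pandas as pd

        rows = []
        A1, A2 = np.meshgrid(self.axis1, self.axis2, indexing="ij")
        for d in self.d_list:
            label = np.where(
                self.classic[d], CLASSIC, np.where(self.nonclassic, NONCLASSIC, NONE)
            )
            rows.append(
                pd.DataFrame(
                    {
                        self.axis_names[0]: A1.ravel(),
                        self.axis_names[1]: A2.ravel(),
                        "d": d,
                        "label": label.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def map_parameter_plane(
    axes: tuple[str, str],
    grid: tuple[np.ndarray, np.ndarray],
    fixed: ModelParams,
    d_list: tuple[float, ...] = (5.0, 10.0, 30.0),
) -> RegionMap:
    """Classify every point of a 2-parameter grid for each relative diffusion.

    ``axes`` names two of (c1, c_minus1, c2); ``grid`` carries the coordinate
    vectors.  Per point the steady states are computed once (degree-6
    polynomial roots), the patterning root selected, and the algebraic
    conditions evaluated; the classic flag is then evaluated per d while the
    non-classic flag is d-independent.  Points with no admissible steady state
    are labelled none; near-boundary points are excluded as indeterminate.
    """
    ax1, ax2 = axes
    g1 = np.asarray(grid[0], dtype=float)
    g2 = np.asarray(grid[1], dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("grid resolution must be >= 2 per axis")
    if not d_list:
        raise ValueError("d_list must be nonempty")

    n1, n2 = g1.size, g2.size
    classic = {float(d): np.zeros((n1, n2), dtype=bool) for d in d_list}
    nonclassic = np.zeros((n1, n2), dtype=bool)
    indeterminate = 0

    for i, x1 in enumerate(g1):
        for j, x2 in enumerate(g2):
            p = fixed.replace(**{ax1: float(x1), ax2: float(x2)})
            ss = None
            for cand in find_steady_states(p):
                if cand.satisfies_necessary_condition:
                    ss = cand
                    break
            if ss is None:
                continue
            label, _ = _algebraic_class(ss, p.replace(d=float(d_list[0])))
            if label == INDETERMINATE:
                indeterminate += 1
                continue
            if label == NONCLASSIC:
                nonclassic[i, j] = True
                continue
            # classic condition depends on d only through the band criterion
            J = local_jacobian(ss, p)
            a11, a22 = J[0, 0], J[1, 1]
            det = a11 * a22 - J[0, 1] * J[1, 0]
            if label == NONE and det < 0:
                continue
            J_hom = homogeneous_jacobian(ss, p)
            tr_h = J_hom[0, 0] + J_hom[1, 1]
            det_h = J_hom[0, 0] * J_hom[1, 1] - J_hom[0, 1] * J_hom[1, 0]
            if not (tr_h < 0 and det_h > 0):
                continue
            for d in d_list:
                h = float(d) * a11 + a22
                if h > 0 and h * h > 4.0 * float(d) * det:
                    classic[float(d)][i, j] = True

    none_grid = ~nonclassic
    for d in d_list:
        none_grid &= ~classic[float(d)]
    return RegionMap(
        axis_names=(ax1, ax2),
        axis1=g1,
        axis2=g2,
        d_list=tuple(float(d) for d in d_list),
        classic=classic,
        nonclassic=nonclassic,
        none=none_grid,
        indeterminate_count=indeterminate,
        fixed=fixed.to_dict(),
    )


def render_region_map(rmap: RegionMap, path=None):
    """Five-level colouring of a region map: classic per d layered (smallest d
    on top), then non-classic, then no symmetry breaking."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    levels = np.zeros((rmap.axis1.size, rmap.axis2.size))
    # layering: largest d painted first, smallest d on top
    for rank, d in enumerate(sorted(rmap.d_list, reverse=True), start=2):
        levels[rmap.classic[d]] = rank
    levels[rmap.nonclassic] = 1
    cmap = ListedColormap(
        ["#1a2a6c", "#7fd4f0", "#2e8b8b", "#7ac143", "#f5e642"][: 2 + len(rmap.d_list)]
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.pcolormesh(rmap.axis1, rmap.axis2, levels.T, cmap=cmap, shading="auto")
    ax.set_xlabel(rmap.axis_names[0])
    ax.set_ylabel(rmap.axis_names[1])
    fig.colorbar(im, ax=ax, label="region")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return path
    return fig
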