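"""Dimensionless bulk-surface model of Cdc42 activation: parameters and kinetics.

The cell is the unit ball Omega with membrane Gamma (the unit sphere).  Three
forms of the GTPase are tracked: the active membrane-bound form ``u``, the
inactive membrane-bound form ``v`` and the cytosolic GDI-bound form ``V``.
In the fast-cytosol limit the cytosolic concentration is spatially uniform and
enters only through the mass-conservation functional

    V[u + v] = V0 - (1/|Omega|) * integral_Gamma (u + v) ds.

Membrane kinetics are governed by two reaction terms:

* ``f(u, v) = c2*v - u + u^2*v`` — activation/inactivation plus a quadratic
  positive feedback loop,
* ``q(u, v, V) = c1*V*(c_max - (u + v)) - c_minus1*v`` — flux of the GDI-bound
  form onto the membrane, saturating at the maximum membrane load ``c_max``,
  minus dissociation back into the cytosol.

All quantities are dimensionless; :func:`nondimensionalise` maps a dimensional
rate-constant set onto this parametrisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "SPHERE_AREA",
    "BALL_VOLUME",
    "DimensionalParams",
    "ModelParams",
    "Scales",
    "FieldPair",
    "reaction_f",
    "flux_q",
    "q0_homogeneous",
    "nonlocal_V",
    "nondimensionalise",
    "redimensionalise",
    "NegativeCytosolWarning",
]

#: Surface area of the unit sphere and volume of the unit ball; their ratio is
#: the geometry constant a = |Gamma|/|Omega| = 3.
SPHERE_AREA = 4.0 * np.pi
BALL_VOLUME = 4.0 * np.pi / 3.0


class NegativeCytosolWarning(UserWarning):
    """Cytosolic concentration from the mass functional went negative.

    The state left the physically valid region; this is tolerated (e.g. a
    transient quadrature undershoot) but surfaced so callers can react.
    """


def _check_finite(name: str, *arrays) -> None:
    for arr in arrays:
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite values in input '{name}'")


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional rate constants and geometry of the bulk-surface model.

    Units: rates per the reaction scheme (k1 in volume·amount^-1·time^-1,
    k_minus1/k2/k_minus2 in time^-1, k3 in concentration^-2·time^-1), k_max in
    mol·m^-2, diffusivities in m^2·time^-1, R in m, G0 in mol·m^-3.
    """

    k1: float
    k_minus1: float
    k2: float
    k_minus2: float
    k3: float
    k_max: float
    D_A: float
    D_I: float
    D_G: float
    R: float
    G0: float

    def __post_init__(self) -> None:
        for f_ in fields(self):
            value = getattr(self, f_.name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"DimensionalParams.{f_.name} must be finite and > 0, got {value!r}"
                )


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameter set of the reduced two-state model.

    Attributes
    ----------
    c1, c_minus1, c2 :
        Relative influx, dissociation and activation rates (GDI, GDI-extraction
        and GEF/GAP activity respectively).
    c_max :
        Maximum membrane load: u + v <= c_max.
    V0 :
        Total average concentration of all three forms.
    gamma :
        Reaction strength relative to membrane diffusion; proportional to the
        membrane area.
    d :
        Diffusivity of the inactive form relative to the active form.
    a :
        Surface-to-volume ratio |Gamma|/|Omega|; 3 for the unit ball.
    """

    c1: float
    c_minus1: float
    c2: float
    c_max: float = 3.0
    V0: float = 6.0
    gamma: float = 25.0
    d: float = 10.0
    a: float = 3.0

    def __post_init__(self) -> None:
        for f_ in fields(self):
            value = getattr(self, f_.name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(
                    f"ModelParams.{f_.name} must be finite and > 0, got {value!r}"
                )

    @property
    def m(self) -> float:
        """Membrane-accessible cytosolic budget m = V0/a."""
        return self.V0 / self.a

    @property
    def trapping_bound(self) -> float:
        """Upper bound min(c_max, m) of u + v inside the trapping region."""
        return min(self.c_max, self.m)

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f_.name: getattr(self, f_.name) for f_ in fields(self)}


@dataclass(frozen=True)
class Scales:
    """Scales recovered from non-dimensionalisation.

    ``concentration`` is sqrt(k_minus2/k3) (membrane concentration unit),
    ``time`` is R^2/D_A, ``length`` is R and ``D`` is the relative cytosolic
    diffusivity D_G/D_A (not part of the reduced model's parameters).
    """

    concentration: float
    time: float
    length: float
    D: float


@dataclass
class FieldPair:
    """Membrane fields u, v on mesh vertices plus the uniform cytosolic V."""

    u: np.ndarray
    v: np.ndarray
    V: float

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must live on the same mesh (equal shapes)")
        self.V = float(self.V)

    def copy(self) -> "FieldPair":
        return FieldPair(self.u.copy(), self.v.copy(), self.V)


def reaction_f(u, v, params: ModelParams):
    """Membrane activation kinetics f(u, v) = c2*v - u + u^2*v (elementwise)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_finite("u", u)
    _check_finite("v", v)
    return params.c2 * v - u + u * u * v


def flux_q(u, v, V, params: ModelParams):
    """Membrane attachment flux q(u, v, V) = c1*V*(c_max - (u+v)) - c_minus1*v."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_finite("u", u)
    _check_finite("v", v)
    _check_finite("V", V)
    return params.c1 * V * (params.c_max - (u + v)) - params.c_minus1 * v


def q0_homogeneous(u_bar, v_bar, params: ModelParams):
    """Spatially averaged flux q0 = c1*a*(c_max - s)*(m - s) - c_minus1*v̄, s = ū+v̄.

    This is ``flux_q`` with the cytosolic pool eliminated through mass
    conservation, V̄ = V0 - a*(ū + v̄) = a*(m - s).
    """
    u_bar = np.asarray(u_bar, dtype=float)
    v_bar = np.asarray(v_bar, dtype=float)
    _check_finite("u_bar", u_bar)
    _check_finite("v_bar", v_bar)
    s = u_bar + v_bar
    return (
        params.c1 * params.a * (params.c_max - s) * (params.m - s)
        - params.c_minus1 * v_bar
    )


def nonlocal_V(u, v, mesh, params: ModelParams, warn: bool = True) -> float:
    """Cytosolic concentration from the mass functional V0 - (1/|Omega|)∫(u+v) ds.

    ``mesh`` must expose ``vertex_areas`` (lumped quadrature weights).  A
    negative result is physically invalid (the state left the trapping region)
    and raises :class:`NegativeCytosolWarning` rather than an error.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    total = float(mesh.vertex_areas @ (u + v))
    V = params.V0 - total / BALL_VOLUME
    if warn and V < 0:
        warnings.warn(
            f"nonlocal_V produced a negative cytosolic concentration ({V:.3e})",
            NegativeCytosolWarning,
            stacklevel=2,
        )
    return V


def nondimensionalise(dp: DimensionalParams) -> tuple[ModelParams, Scales]:
    """Map dimensional rate constants onto the dimensionless parameter set.

    Concentrations scale with sqrt(k_minus2/k3), time with R^2/D_A and length
    with R; the resulting parameters are

        gamma = R^2 k_minus2 / D_A,   c1 = (k1/k_minus2) sqrt(k_minus2/k3),
        c_minus1 = k_minus1/k_minus2, c2 = k2/k_minus2,
        c_max = k_max sqrt(k3/k_minus2), V0 = G0 sqrt(k3/k_minus2),
        d = D_I/D_A (and D = D_G/D_A for the full bulk model).
    """
    conc = np.sqrt(dp.k_minus2 / dp.k3)
    mp = ModelParams(
        c1=dp.k1 / dp.k_minus2 * conc,
        c_minus1=dp.k_minus1 / dp.k_minus2,
        c2=dp.k2 / dp.k_minus2,
        c_max=dp.k_max / conc,
        V0=dp.G0 / conc,
        gamma=dp.R**2 * dp.k_minus2 / dp.D_A,
        d=dp.D_I / dp.D_A,
        a=3.0,
    )
    scales = Scales(
        concentration=conc,
        time=dp.R**2 / dp.D_A,
        length=dp.R,
        D=dp.D_G / dp.D_A,
    )
    return mp, scales


def redimensionalise(mp: ModelParams, scales: Scales) -> DimensionalParams:
    """Invert :func:`nondimensionalise` given the retained scales."""
    k_minus2 = mp.gamma / scales.time
    D_A = scales.length**2 / scales.time
    k3 = k_minus2 / scales.concentration**2
    return DimensionalParams(
        k1=mp.c1 * k_minus2 / scales.concentration,
        k_minus1=mp.c_minus1 * k_minus2,
        k2=mp.c2 * k_minus2,
        k_minus2=k_minus2,
        k3=k3,
        k_max=mp.c_max * scales.concentration,
        D_A=D_A,
        D_I=mp.d * D_A,
        D_G=scales.D * D_A,
        R=scales.length,
        G0=mp.V0 * scales.concentration,
    )
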