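"""Mechanistic drag model of maximum prolonged-swimming speed for rigid bodies.

A fish that powers prolonged swimming with its pectoral fins keeps a rigid
body, so the body behaves hydrodynamically like a towed streamline body of
revolution: the only body force relevant to shape optimisation is parasite
drag.  This module predicts the maximum prolonged-swimming speed ``U_max``
attainable by such a body from its fineness ratio ``f`` (length over
equivalent diameter) by combining

* semi-empirical volume-specific drag coefficients for streamline bodies of
  revolution (Hoerner's compendium), valid in the laminar
  (``Re`` roughly 1e4-1e5) and transitional (``Re`` roughly 1e5-1e6) regimes,
  with skin friction ``C_f = 1.328 Re^-0.5`` (Blasius) and
  ``C_f = 0.427 (log10 Re - 0.407)^-2.64`` respectively, and
* a Froude-efficiency power balance: at the maximum aerobic power ``P_max``
  the attainable speed satisfies
  ``U_max = (2 eta P_max / (rho V^(2/3) C_D))^(1/3)``.

Because ``C_D`` depends on ``Re`` and hence on speed, ``U_max`` is found by
fixed-point iteration (:func:`solve_umax`).  :func:`sweep_fineness` evaluates
bodies of equal volume across a fineness grid and locates the optimal
fineness either as the drag minimiser at a fixed reference speed or as the
speed maximiser under the full power balance.

Regime selection is always an explicit caller choice; nothing switches
regimes automatically based on the computed Reynolds number (the validity
bands above only trigger warnings).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "LAMINAR",
    "TRANSITIONAL",
    "FluidEnvironment",
    "BodyOfRevolution",
    "PropulsionParams",
    "DragResult",
    "UmaxSolution",
    "FinenessSweep",
    "friction_coefficient",
    "form_factor",
    "body_geometry",
    "reynolds",
    "volumetric_drag_coefficient",
    "solve_umax",
    "sweep_fineness",
    "slope_table",
]

LAMINAR = "laminar"
TRANSITIONAL = "transitional"
Regime = Literal["laminar", "transitional"]

#: Reynolds-number bands inside which each semi-empirical friction law was fit.
REGIME_BANDS = {LAMINAR: (1e4, 1e5), TRANSITIONAL: (1e5, 1e6)}

# The transitional friction law diverges as log10(Re) -> 0.407 from above.
_TRANSITIONAL_RE_FLOOR = 10.0 ** 0.407


def _check_regime(regime: str) -> None:
    if regime not in (LAMINAR, TRANSITIONAL):
        raise ValueError(f"unknown flow regime {regime!r}; use {LAMINAR!r} or {TRANSITIONAL!r}")


@dataclass(frozen=True)
class FluidEnvironment:
    """Sea water properties.

    Defaults are for tropical reef seawater at about 27 degC and 35 g/kg
    salinity: density 1025 kg m^-3, kinematic viscosity 8.8e-7 m^2 s^-1.
    """

    density: float = 1025.0  # kg m^-3
    kinematic_viscosity: float = 8.8e-7  # m^2 s^-1

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("fluid density must be positive")
        if self.kinematic_viscosity <= 0:
            raise ValueError("kinematic viscosity must be positive")


@dataclass(frozen=True)
class BodyOfRevolution:
    """Idealised axisymmetric body of fixed volume, fineness and bluntness.

    The prismatic coefficient ``Cp`` is the ratio of the body's volume to
    that of the cylinder with the same maximum section and length; 0.65 is
    a typical streamline-body value.  Diameter and length follow from
    ``V = Cp (pi/4) d^2 l`` with ``l = f d``.
    """

    volume: float  # m^3
    fineness: float  # dimensionless, l/d
    prismatic: float = 0.65

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("body volume must be positive")
        if self.fineness < 1:
            raise ValueError("fineness must be >= 1")
        # 4/pi (slightly above 1) admits the exact cube-equivalent body
        if not 0 < self.prismatic <= 4 / math.pi:
            raise ValueError("prismatic coefficient must lie in (0, 4/pi]")

    @property
    def diameter(self) -> float:
        return body_geometry(self.volume, self.fineness, self.prismatic)[0]

    @property
    def length(self) -> float:
        return body_geometry(self.volume, self.fineness, self.prismatic)[1]


@dataclass(frozen=True)
class PropulsionParams:
    """Aerobic propulsion budget of a pectoral-fin swimmer.

    ``efficiency`` is the Froude (propulsive) efficiency of the fin stroke,
    the mean of simulated peak efficiencies for rowing (0.09) and flapping
    (0.59) pectoral fins.  ``muscle_power`` is the mass-specific sustained
    power of pectoral-fin muscle (W per kg muscle, bluegill value) and
    ``muscle_fraction`` the propulsive muscle mass as a fraction of body
    mass, so ``P_max = muscle_power * muscle_fraction * M``.
    """

    efficiency: float = 0.34
    muscle_power: float = 16.5  # W kg^-1 (of propulsive muscle)
    muscle_fraction: float = 0.019  # propulsive muscle mass / body mass

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must lie in (0, 1]")
        if self.muscle_power <= 0:
            raise ValueError("muscle power must be positive")
        if not 0 < self.muscle_fraction < 1:
            raise ValueError("muscle fraction must lie in (0, 1)")

    def max_power(self, mass: float) -> float:
        """Maximum aerobic propulsive power (W) for a fish of ``mass`` kg."""
        if mass <= 0:
            raise ValueError("body mass must be positive")
        return self.muscle_power * self.muscle_fraction * mass


@dataclass(frozen=True)
class DragResult:
    reynolds: float
    friction: float  # skin-friction coefficient C_f
    drag: float  # volume-specific drag coefficient C_D
    regime: str


@dataclass(frozen=True)
class UmaxSolution:
    speed: float  # m s^-1
    iterations: int
    converged: bool
    drag: DragResult


def friction_coefficient(reynolds, regime: Regime):
    """Skin-friction coefficient ``C_f`` of a flat-plate boundary layer.

    Laminar regime uses the Blasius solution ``1.328 Re^-0.5``; the
    transitional regime uses the semi-empirical
    ``0.427 (log10 Re - 0.407)^-2.64``.  Accepts scalars or arrays.
    """
    _check_regime(regime)
    re = np.asarray(reynolds, dtype=float)
    if np.any(re <= 0):
        raise ValueError("Reynolds number must be positive")
    if regime == LAMINAR:
        out = 1.328 * re ** -0.5
    else:
        if np.any(re <= _TRANSITIONAL_RE_FLOOR):
            raise ValueError(
                "transitional friction law requires log10(Re) > 0.407 "
                f"(Re > {_TRANSITIONAL_RE_FLOOR:.3g})"
            )
        out = 0.427 * (np.log10(re) - 0.407) ** -2.64
    return out if out.ndim else float(out)


def form_factor(fineness, regime: Regime):
    """Fineness polynomial converting ``C_f`` to the volume-specific ``C_D``.

    ``C_D = C_f * form_factor(f)``, with drag referenced to ``V^(2/3)``.
    The transitional form is Hoerner's volume-specific streamline-body
    equation; the laminar form combines the wetted-area form factor
    ``1 + 1.5 f^-1.5 + 7 f^-3`` with the wetted-area-to-volume conversion
    ``S / V^(2/3) ~ 4 f^(1/3)``.  At fixed ``C_f`` the transitional bracket
    has an interior minimum near ``f = 4.65``; the laminar form, combined
    with the ``Re(f)`` dependence of ``C_f`` at constant volume and speed,
    decreases monotonically with ``f``.
    """
    _check_regime(regime)
    f = np.asarray(fineness, dtype=float)
    if np.any(f < 1):
        raise ValueError("fineness must be >= 1")
    third = f ** (1.0 / 3.0)
    if regime == TRANSITIONAL:
        out = 4.0 * third + 6.0 * f ** (-7.0 / 6.0) + 24.0 * f ** (-8.0 / 3.0)
    else:
        out = 4.0 * third * (1.0 + 1.5 * f ** -1.5 + 7.0 * f ** -3.0)
    return out if out.ndim else float(out)


def body_geometry(volume: float, fineness: float, prismatic: float = 0.65):
    """Diameter and length of the constant-volume body of revolution.

    ``d = (4 V / (Cp pi f))^(1/3)`` and ``l = f d``, the unique pair
    satisfying ``V = Cp (pi/4) d^2 l`` with ``l = f d``.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if fineness < 1:
        raise ValueError("fineness must be >= 1")
    if not 0 < prismatic <= 4 / math.pi:
        raise ValueError("prismatic coefficient must lie in (0, 4/pi]")
    d = (4.0 * volume / (prismatic * math.pi * fineness)) ** (1.0 / 3.0)
    return d, fineness * d


def reynolds(speed: float, length: float, viscosity: float) -> float:
    """Reynolds number ``U l / nu`` with body length as reference length."""
    if speed <= 0 or length <= 0 or viscosity <= 0:
        raise ValueError("speed, length and viscosity must all be positive")
    return speed * length / viscosity


def volumetric_drag_coefficient(
    fineness: float, re: float, regime: Regime, *, warn_band: bool = True
) -> DragResult:
    """Volume-specific drag coefficient ``C_D = C_f(Re) * form_factor(f)``.

    Warns (but does not fail) when ``Re`` falls outside the band in which
    the regime's friction law was calibrated.
    """
    _check_regime(regime)
    cf = friction_coefficient(re, regime)
    if warn_band:
        lo, hi = REGIME_BANDS[regime]
        if not lo <= re <= hi:
            warnings.warn(
                f"Re = {re:.3g} outside the {regime} calibration band [{lo:.0e}, {hi:.0e}]",
                stacklevel=2,
            )
    return DragResult(
        reynolds=float(re),
        friction=float(cf),
        drag=float(cf * form_factor(fineness, regime)),
        regime=regime,
    )


def solve_umax(
    body: BodyOfRevolution,
    fluid: FluidEnvironment | None = None,
    propulsion: PropulsionParams | None = None,
    regime: Regime = LAMINAR,
    *,
    seed_speed: float | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
    mass: float | None = None,
    drag_coefficient: float | None = None,
    warn_band: bool = False,
) -> UmaxSolution:
    """Fixed-point solution of the Froude-efficiency speed equation.

    Iterates ``U <- (2 eta P_max / (rho V^(2/3) C_D(Re(U, l))))^(1/3)``
    starting from ``seed_speed`` (default two body lengths per second) until
    successive iterates differ by at most ``tol`` (m/s).  ``mass`` defaults
    to the neutrally buoyant ``rho * V``.  Passing ``drag_coefficient``
    freezes ``C_D`` (no Reynolds feedback) and returns the closed form in a
    single step.
    """
    fluid = fluid or FluidEnvironment()
    propulsion = propulsion or PropulsionParams()
    _check_regime(regime)
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    d, length = body_geometry(body.volume, body.fineness, body.prismatic)
    m = fluid.density * body.volume if mass is None else mass
    p_max = propulsion.max_power(m)
    scale = 2.0 * propulsion.efficiency * p_max / (fluid.density * body.volume ** (2.0 / 3.0))

    if drag_coefficient is not None:
        if drag_coefficient <= 0:
            raise ValueError("drag coefficient must be positive")
        u = (scale / drag_coefficient) ** (1.0 / 3.0)
        re = reynolds(u, length, fluid.kinematic_viscosity)
        drag = DragResult(re, friction_coefficient(re, regime), drag_coefficient, regime)
        return UmaxSolution(speed=u, iterations=1, converged=True, drag=drag)

    u = 2.0 * length if seed_speed is None else seed_speed
    if u <= 0:
        raise ValueError("seed speed must be positive")
    drag = None
    for iteration in range(1, max_iter + 1):
        re = reynolds(u, length, fluid.kinematic_viscosity)
        drag = volumetric_drag_coefficient(body.fineness, re, regime, warn_band=warn_band)
        u_next = (scale / drag.drag) ** (1.0 / 3.0)
        if abs(u_next - u) <= tol:
            return UmaxSolution(speed=u_next, iterations=iteration, converged=True, drag=drag)
        u = u_next
    return UmaxSolution(speed=u, iterations=max_iter, converged=False, drag=drag)


@dataclass(frozen=True)
class FinenessSweep:
    """Performance of equal-volume bodies across a fineness grid."""

    fineness: np.ndarray
    diameter: np.ndarray
    length: np.ndarray
    reynolds: np.ndarray
    friction: np.ndarray
    drag: np.ndarray
    umax: np.ndarray
    f_opt: float  # grid optimum refined by quadratic interpolation, 0.1 resolution
    f_opt_refined: float
    mode: str
    regime: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "f": self.fineness,
                "d": self.diameter,
                "l": self.length,
                "Re": self.reynolds,
                "C_f": self.friction,
                "C_D": self.drag,
                "U_max": self.umax,
            }
        )


def _refine_quadratic(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through the grid point ``i`` and neighbours."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0.0:
        return float(x[i])
    step = x[1] - x[0]
    return float(x[i] + 0.5 * step * (a - c) / denom)


def sweep_fineness(
    volume: float,
    fluid: FluidEnvironment | None = None,
    propulsion: PropulsionParams | None = None,
    regime: Regime = TRANSITIONAL,
    *,
    f_min: float = 1.0,
    f_max: float = 20.0,
    step: float = 0.1,
    mode: str = "max_umax",
    speed: float | None = None,
    prismatic: float = 0.65,
    tol: float = 1e-3,
) -> FinenessSweep:
    """Evaluate equal-volume bodies over a fineness grid and locate ``f_opt``.

    ``mode="min_cd_at_speed"`` holds the swimming speed fixed at ``speed``
    and minimises the volume-specific drag coefficient over the grid (all
    bodies share volume and speed, so Reynolds number varies with ``f``).
    ``mode="max_umax"`` solves the full power balance per grid point and
    maximises the converged ``U_max``.  The optimum is the best grid point
    refined by 3-point quadratic interpolation and reported at 0.1
    resolution in ``f_opt`` (``f_opt_refined`` keeps the raw value).
    """
    fluid = fluid or FluidEnvironment()
    propulsion = propulsion or PropulsionParams()
    _check_regime(regime)
    if mode not in ("min_cd_at_speed", "max_umax"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    if mode == "min_cd_at_speed" and (speed is None or speed <= 0):
        raise ValueError("mode 'min_cd_at_speed' requires a positive fixed speed")
    grid = np.arange(f_min, f_max + 0.5 * step, step)
    if grid.size == 0:
        raise ValueError("empty fineness grid")

    n = grid.size
    diam = np.empty(n)
    length = np.empty(n)
    re = np.empty(n)
    umax = np.empty(n)
    for i, f in enumerate(grid):
        body = BodyOfRevolution(volume, float(f), prismatic)
        diam[i], length[i] = body_geometry(volume, float(f), prismatic)
        sol = solve_umax(body, fluid, propulsion, regime, tol=tol)
        umax[i] = sol.speed
        if mode == "min_cd_at_speed":
            re[i] = reynolds(speed, length[i], fluid.kinematic_viscosity)
        else:
            re[i] = sol.drag.reynolds
    cf = friction_coefficient(re, regime)
    cd = cf * form_factor(grid, regime)

    if mode == "min_cd_at_speed":
        i_opt = int(np.argmin(cd))
        refined = _refine_quadratic(grid, cd, i_opt)
    else:
        i_opt = int(np.argmax(umax))
        refined = _refine_quadratic(grid, -umax, i_opt)
    return FinenessSweep(
        fineness=grid,
        diameter=diam,
        length=length,
        reynolds=re,
        friction=np.asarray(cf),
        drag=np.asarray(cd),
        umax=umax,
        f_opt=round(refined, 1),
        f_opt_refined=refined,
        mode=mode,
        regime=regime,
    )


def slope_table(
    sweep: FinenessSweep,
    f_points: Iterable[float] = range(1, 11),
    *,
    sd_f: float | None = None,
    sd_u: float | None = None,
    normalization: str = "percent",
) -> pd.DataFrame:
    """Local slopes ``alpha`` of the ``U_max(f)`` curve at chosen finenesses.

    ``normalization="percent"`` expresses the central-difference slope as a
    percentage of the local ``U_max`` per unit fineness (approximately the
    percent speed gain of a unit fineness increase); ``"raw"`` leaves it in
    m/s per unit fineness.  When the caller supplies the standard deviations
    of fineness and of (adjusted) ``U_max`` observed in a comparative
    sample, a standardised slope ``alpha_std = alpha * sd_f / sd_u`` is
    added, expressing the effect in response-SD units per fineness-SD.
    """
    if normalization not in ("percent", "raw"):
        raise ValueError(f"unknown normalization {normalization!r}")
    grid = sweep.fineness
    step = grid[1] - grid[0] if grid.size > 1 else math.nan
    rows = []
    for fp in f_points:
        j = int(np.argmin(np.abs(grid - fp)))
        if abs(grid[j] - fp) > 1e-9 or j == 0 or j == grid.size - 1:
            raise ValueError(
                f"f = {fp} not covered (with margin for central differences) by the sweep grid"
            )
        slope = (sweep.umax[j + 1] - sweep.umax[j - 1]) / (2.0 * step)
        alpha = 100.0 * slope / sweep.umax[j] if normalization == "percent" else slope
        alpha_std = alpha * sd_f / sd_u if (sd_f is not None and sd_u is not None) else math.nan
        rows.append({"f": float(grid[j]), "alpha": float(alpha), "alpha_std": float(alpha_std)})
    return pd.DataFrame(rows)
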