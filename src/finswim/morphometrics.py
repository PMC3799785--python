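"""Morphometric derivations: equivalent diameter, fineness, fin aspect ratio.

Real fish have transverse sections deeper than wide, so a single fineness
number requires mapping the elliptical section to an "equivalent" circle.
Two conventions are used, matched to the propulsion mode of the species:

* pectoral-fin (MPF) swimmers keep a rigid body whose flow-separation
  behaviour is dominated by the narrower dimension, so the equivalent
  diameter is the *geometric* mean of maximum depth and breadth
  (equal-area circle);
* body-caudal-fin (BCF) swimmers shed no separated flow while undulating,
  so the equivalent diameter is the *elliptical* mean (equal-perimeter
  circle, standardising by surface area).

Fineness is then ``f = standard length / d_e``.  Fin aspect ratio follows
the wing convention: ``2 L^2 / area`` for a single pectoral fin (doubled so
the pair matches a wing), ``height^2 / area`` for the caudal fin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ellipe

__all__ = [
    "MPF",
    "BCF",
    "GAITS",
    "SpeciesRecord",
    "MorphometricDerived",
    "geometric_mean_diameter",
    "elliptical_mean_diameter",
    "fineness",
    "fin_aspect_ratio",
    "derive",
    "derive_table",
]

MPF = "MPF"
BCF = "BCF"
GAITS = (MPF, BCF)


@dataclass(frozen=True)
class SpeciesRecord:
    """Species-mean morphometrics and maximum prolonged-swimming speed.

    ``umax`` is the gait-transition speed for MPF swimmers and the critical
    swimming speed for BCF swimmers, both in m/s.  Lengths are in metres and
    mass in kg.
    """

    species: str
    gait: str
    length: float  # standard length, m
    depth: float  # maximum body depth, m
    breadth: float  # maximum body breadth, m
    mass: float  # kg
    fin_aspect_ratio: float  # pectoral AR (MPF) or caudal AR (BCF)
    umax: float  # m s^-1

    def __post_init__(self) -> None:
        if self.gait not in GAITS:
            raise ValueError(f"{self.species}: unknown gait {self.gait!r}; expected MPF or BCF")
        for name in ("length", "depth", "breadth", "mass", "fin_aspect_ratio", "umax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.species}: {name} must be positive")
        if self.breadth > self.depth:
            warnings.warn(
                f"{self.species}: breadth exceeds depth (unusual body orientation?)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MorphometricDerived:
    equivalent_diameter: float  # m
    fineness: float
    reynolds: float  # at measured umax, standard length as reference


def geometric_mean_diameter(depth: float, breadth: float) -> float:
    """Equal-area equivalent diameter ``sqrt(depth * breadth)``."""
    if depth <= 0 or breadth <= 0:
        raise ValueError("depth and breadth must be positive")
    return math.sqrt(depth * breadth)


def elliptical_mean_diameter(depth: float, breadth: float, method: str = "quadratic") -> float:
    """Equal-perimeter equivalent diameter of the elliptical section.

    The default ``"quadratic"`` method uses the standard first-order
    perimeter approximation ``P ~ 2 pi sqrt((r_d^2 + r_b^2)/2)``, giving
    ``d_e = sqrt((depth^2 + breadth^2)/2)``.  ``"exact"`` evaluates the
    true ellipse perimeter with the complete elliptic integral; the two
    agree within 1% for depth:breadth up to about 3:1.
    """
    if depth <= 0 or breadth <= 0:
        raise ValueError("depth and breadth must be positive")
    if method == "quadratic":
        return math.sqrt(0.5 * (depth * depth + breadth * breadth))
    if method == "exact":
        a = 0.5 * max(depth, breadth)  # semi-major
        b = 0.5 * min(depth, breadth)
        m = 1.0 - (b / a) ** 2  # scipy parameter m = e^2
        perimeter = 4.0 * a * ellipe(m)
        return perimeter / math.pi
    raise ValueError(f"unknown elliptical mean method {method!r}")


def fineness(length: float, equivalent_diameter: float) -> float:
    """Fineness ratio: standard length over equivalent diameter."""
    if length <= 0 or equivalent_diameter <= 0:
        raise ValueError("length and equivalent diameter must be positive")
    return length / equivalent_diameter


def fin_aspect_ratio(span: float, area: float, fin: str = "pectoral") -> float:
    """Aspect ratio of a propulsive fin from its span and planform area.

    ``span`` is the leading-edge length of a single pectoral fin or the
    tip-to-tip height of the caudal fin.  The pectoral value is doubled to
    conform to the aerodynamic wing definition.
    """
    if span <= 0 or area <= 0:
        raise ValueError("span and area must be positive")
    if fin == "pectoral":
        return 2.0 * span * span / area
    if fin == "caudal":
        return span * span / area
    raise ValueError(f"unknown fin type {fin!r}")


def derive(
    record: SpeciesRecord,
    *,
    viscosity: float = 8.8e-7,
    elliptical: str = "quadratic",
) -> MorphometricDerived:
    """Equivalent diameter, fineness and Reynolds number for one species.

    Gait dispatch: MPF uses the geometric (equal-area) mean, BCF the
    elliptical (equal-perimeter) mean.  The Reynolds number is computed at
    the measured ``umax`` with standard length as the reference length.
    """
    if record.gait == MPF:
        d_e = geometric_mean_diameter(record.depth, record.breadth)
    elif record.gait == BCF:
        d_e = elliptical_mean_diameter(record.depth, record.breadth, method=elliptical)
    else:  # pragma: no cover - SpeciesRecord already validates
        raise ValueError(f"unknown gait {record.gait!r}")
    return MorphometricDerived(
        equivalent_diameter=d_e,
        fineness=fineness(record.length, d_e),
        reynolds=record.umax * record.length / viscosity,
    )


def derive_table(
    records,
    *,
    viscosity: float = 8.8e-7,
    elliptical: str = "quadratic",
) -> pd.DataFrame:
    """Tabulate raw and derived morphometrics for a set of records."""
    rows = []
    for rec in records:
        der = derive(rec, viscosity=viscosity, elliptical=elliptical)
        rows.append(
            {
                "species": rec.species,
                "gait": rec.gait,
                "sl": rec.length,
                "depth": rec.depth,
                "breadth": rec.breadth,
                "mass": rec.mass,
                "fin_ar": rec.fin_aspect_ratio,
                "umax": rec.umax,
                "d_e": der.equivalent_diameter,
                "fineness": der.fineness,
                "reynolds": der.reynolds,
                "logM": np.log(rec.mass),
                "logU": np.log(rec.umax),
            }
        )
    return pd.DataFrame(rows).set_index("species")
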