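"""Arterial wall mechanics.

Two ingredients live here:

* the Langewouters arctangent pressure–area law, which gives every
  segment a bounded lumen area ``A(P)`` and a bell-shaped local area
  compliance ``C_A(P)``;
* the empirical age-resolved inverse relations between pulse wave
  velocity (PWV) and mean lumen diameter that encode how the arterial
  wall stiffens, decade by decade, between 30 and 80 years.

The link between the two is the Bramwell–Hill relation
``PWV^2 = A / (rho * C_A)``: given a target PWV at a reference pressure,
:func:`calibrate_wall` solves for Langewouters parameters that realize it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import MMHG

__all__ = [
    "WallLaw",
    "PwvRelation",
    "PWV_TABLE",
    "pwv_coefficients",
    "pwv_from_diameter",
    "area_of_pressure",
    "pressure_of_area",
    "calibrate_wall",
    "viscoelastic_pressure",
    "RHO_BLOOD",
    "MU_BLOOD",
    "P_REF",
]

RHO_BLOOD = 1050.0  # kg/m^3
MU_BLOOD = 4e-3  # Pa.s
P_REF = 100.0 * MMHG  # wall-law calibration pressure


@dataclass(frozen=True)
class WallLaw:
    """Langewouters arctangent law A(P) = A_m (1/2 + atan((P-P0)/P1)/pi).

    Parameters
    ----------
    A_m : float
        Asymptotic maximal cross-sectional area, m^2.
    P0 : float
        Inflection pressure (compliance maximum), Pa.
    P1 : float
        Width parameter, Pa.
    gamma : float
        Voigt wall-viscosity coefficient, Pa.s/m^2 (0 = purely elastic).
    """

    A_m: float
    P0: float
    P1: float
    gamma: float = 0.0

    def __post_init__(self):
        if self.A_m <= 0:
            raise ValueError("A_m must be positive")
        if self.P1 <= 0:
            raise ValueError("P1 must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass(frozen=True)
class PwvRelation:
    """One decade's PWV(d) = a * (d in mm)^(-b) relation.

    ``r2`` is the goodness of fit of the underlying literature fit and is
    carried as metadata only.
    """

    a: float  # m/s at d = 1 mm
    b: float  # dimensionless exponent
    age: float  # years
    r2: float | None = None

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("a must be positive")
        if not 0 < self.b < 1:
            raise ValueError("b must lie in (0, 1)")


# Decade-resolved inverse-relation coefficients (diameter in mm, PWV in m/s)
# and their fit quality.  The 30 y curve describes a compliant proximal
# aorta (~3 m/s at 29 mm) with a steep stiffness gradient towards the
# periphery; with age the exponent flattens: proximal vessels stiffen far
# more than distal ones.
PWV_TABLE: dict[int, PwvRelation] = {
    30: PwvRelation(15.48, 0.502, 30, 0.95),
    40: PwvRelation(15.59, 0.458, 40, 0.90),
    50: PwvRelation(16.33, 0.447, 50, 0.93),
    60: PwvRelation(16.68, 0.428, 60, 0.93),
    70: PwvRelation(15.91, 0.372, 70, 0.81),
    80: PwvRelation(15.29, 0.345, 80, 0.75),
}

AGE_MIN, AGE_MAX = 30.0, 80.0


def pwv_coefficients(age: float) -> PwvRelation:
    """Return the PWV–diameter relation for a given age.

    Exact decades return the tabulated row; intermediate ages linearly
    interpolate (a, b) between the neighbouring decades.
    """
    if not AGE_MIN <= age <= AGE_MAX:
        raise ValueError(f"age {age} outside supported range [{AGE_MIN:.0f}, {AGE_MAX:.0f}]")
    decade = int(round(age / 10) * 10)
    if age == decade and decade in PWV_TABLE:
        return PWV_TABLE[decade]
    lo = int(math.floor(age / 10) * 10)
    hi = min(lo + 10, int(AGE_MAX))
    w = (age - lo) / 10.0
    rl, rh = PWV_TABLE[lo], PWV_TABLE[hi]
    return PwvRelation((1 - w) * rl.a + w * rh.a, (1 - w) * rl.b + w * rh.b, age, None)


def pwv_from_diameter(d_mean: float, age: float) -> float:
    """Pulse wave velocity (m/s) for mean lumen diameter ``d_mean`` (m)."""
    if d_mean <= 0:
        raise ValueError("diameter must be positive")
    rel = pwv_coefficients(age)
    return rel.a * (d_mean * 1e3) ** (-rel.b)


def area_of_pressure(P, law: WallLaw):
    """Evaluate the arctangent law.

    Returns ``(A, C_A)``: lumen area (m^2) and local area compliance
    dA/dP (m^2/Pa).  Accepts scalars or arrays.
    """
    theta = (np.asarray(P, dtype=float) - law.P0) / law.P1
    A = law.A_m * (0.5 + np.arctan(theta) / np.pi)
    C_A = law.A_m / (np.pi * law.P1 * (1.0 + theta * theta))
    return A, C_A


def pressure_of_area(A, law: WallLaw):
    """Invert the arctangent law: elastic pressure at lumen area ``A``."""
    x = np.asarray(A, dtype=float) / law.A_m - 0.5
    return law.P0 + law.P1 * np.tan(np.pi * x)


def local_pwv(P, law: WallLaw, rho: float = RHO_BLOOD):
    """Bramwell–Hill wave speed sqrt(A / (rho C_A)) at pressure ``P``."""
    A, C_A = area_of_pressure(P, law)
    return np.sqrt(A / (rho * C_A))


def calibrate_wall(A_ref: float, pwv_target: float, P_ref: float = P_REF,
                   rho: float = RHO_BLOOD, gamma: float = 0.0) -> WallLaw:
    """Solve for a Langewouters law matching area and wave speed.

    The returned law satisfies ``A(P_ref) = A_ref`` and, through
    Bramwell–Hill, ``C_A(P_ref) = A_ref / (rho * pwv_target^2)``.  The
    inflection pressure is pinned at the reference pressure (``P0 =
    P_ref``), which closes the two remaining parameters in closed form::

        A_m = 2 A_ref
        P1  = 2 rho pwv_target^2 / pi
    """
    if A_ref <= 0 or pwv_target <= 0 or P_ref <= 0:
        raise ValueError("calibrate_wall arguments must be positive")
    A_m = 2.0 * A_ref
    if A_m <= A_ref:  # pragma: no cover - unreachable under P0=P_ref closure
        raise ValueError("infeasible calibration: A_m <= A_ref")
    P1 = 2.0 * rho * pwv_target ** 2 / np.pi
    return WallLaw(A_m=A_m, P0=P_ref, P1=P1, gamma=gamma)


def viscoelastic_pressure(A, dA_dt, law: WallLaw):
    """Voigt-type viscous wall pressure ``gamma * dA/dt`` (Pa)."""
    del A  # the Voigt term depends on the rate only
    return law.gamma * np.asarray(dA_dt, dtype=float)
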