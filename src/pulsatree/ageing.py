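"""Per-decade ageing parameterization of the tree-and-heart model.

Three mechanisms are aged between 30 and 80 years:

* **arterial stiffening** — every segment's wall is recalibrated so its
  local PWV follows the decade's PWV(diameter) relation; geometry is held
  fixed;
* **peripheral resistance** — total peripheral resistance is set to
  MAP_target / CO with cardiac output fixed at 6.6 L/min, and all terminal
  Windkessel resistances are rescaled by one common factor;
* **cardiac function** — the decade column of the cardiac table (E_es,
  E_ed, P_ven, HR) is installed.

The mitral filling resistance is the single free cardiac closure: it is
calibrated (per decade, against the full 1-D model) so the ejected cardiac
output equals the prescribed 6.6 L/min, and the resulting values are
frozen in :data:`R_MITRAL_TABLE`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .heart import CardiacParams, cardiac_params
from .tree import ArterialTree
from .units import MMHG, lpm_to_m3s
from .wall import MU_BLOOD, P_REF, PwvRelation, calibrate_wall, pwv_coefficients, pwv_from_diameter

__all__ = [
    "AgeingProfile",
    "MAP_TABLE_MMHG",
    "CARDIAC_OUTPUT",
    "total_peripheral_resistance",
    "conduit_resistance",
    "scale_terminal_resistances",
    "ageing_profile",
    "apply_profile",
    "ConfiguredModel",
]

# Decade mean-arterial-pressure targets (mmHg).  These are the expected
# MAP values the peripheral-resistance rule TPR = MAP/CO consumes.
MAP_TABLE_MMHG: dict[int, float] = {
    30: 84.8, 40: 88.8, 50: 91.6, 60: 94.8, 70: 95.8, 80: 95.4,
}

CARDIAC_OUTPUT = lpm_to_m3s(6.6)  # m^3/s, held constant across decades

# Mitral filling resistance (Pa.s/m^3) per decade, calibrated once with the
# packaged reference tree so mean aortic flow equals CARDIAC_OUTPUT.
R_MITRAL_TABLE: dict[int, float] = {
    30: 1.678e6, 40: 1.578e6, 50: 1.741e6, 60: 1.636e6, 70: 1.710e6, 80: 1.951e6,
}

DECADES = (30, 40, 50, 60, 70, 80)


@dataclass(frozen=True)
class AgeingProfile:
    """Complete parameter set for one age."""

    age: float
    pwv_relation: PwvRelation
    MAP_target: float  # Pa
    CO: float  # m^3/s
    TPR: float  # Pa.s/m^3
    cardiac: CardiacParams

    def __post_init__(self):
        if abs(self.TPR - self.MAP_target / self.CO) > 1e-6 * self.TPR:
            raise ValueError("profile violates TPR = MAP_target / CO")


def total_peripheral_resistance(MAP_target: float, CO: float) -> float:
    """TPR = MAP_target / CO (Pa.s/m^3)."""
    if MAP_target <= 0 or CO <= 0:
        raise ValueError("MAP_target and CO must be positive")
    return MAP_target / CO


def _map_target(age: float) -> float:
    decade = int(round(age / 10) * 10)
    if age == decade and decade in MAP_TABLE_MMHG:
        return MAP_TABLE_MMHG[decade] * MMHG
    lo = int(np.floor(age / 10) * 10)
    hi = min(lo + 10, 80)
    w = (age - lo) / 10.0
    return ((1 - w) * MAP_TABLE_MMHG[lo] + w * MAP_TABLE_MMHG[hi]) * MMHG


def _r_mitral(age: float) -> float:
    decade = int(round(age / 10) * 10)
    if age == decade and decade in R_MITRAL_TABLE:
        return R_MITRAL_TABLE[decade]
    lo = int(np.floor(age / 10) * 10)
    hi = min(lo + 10, 80)
    w = (age - lo) / 10.0
    return (1 - w) * R_MITRAL_TABLE[lo] + w * R_MITRAL_TABLE[hi]


def ageing_profile(age: float) -> AgeingProfile:
    """Assemble the full per-age parameter set."""
    if not 30 <= age <= 80:
        raise ValueError(f"age {age} outside supported range [30, 80]")
    map_pa = _map_target(age)
    cardiac = replace(cardiac_params(age), R_mitral=_r_mitral(age))
    return AgeingProfile(
        age=age,
        pwv_relation=pwv_coefficients(age),
        MAP_target=map_pa,
        CO=CARDIAC_OUTPUT,
        TPR=total_peripheral_resistance(map_pa, CARDIAC_OUTPUT),
        cardiac=cardiac,
    )


# --------------------------------------------------------------------------
# peripheral resistance scaling
# --------------------------------------------------------------------------

def _segment_dc_resistance(seg, zeta_v: float, mu: float, n: int = 64) -> float:
    """Steady viscous resistance of one tapered segment at reference area.

    Integrates dR = 2 (zeta_v + 2) pi mu / A(x)^2 dx with A(x) the lumen
    area at the calibration pressure (pi d(x)^2 / 4).
    """
    d = seg.diameters(n)
    A = np.pi * d * d / 4.0
    k = 2.0 * (zeta_v + 2.0) * np.pi * mu
    return float(k * np.trapezoid(1.0 / (A * A), dx=seg.length / (n - 1)))


def _network_resistance(tree: ArterialTree, lam: float, zeta_v: float, mu: float) -> float:
    """DC input resistance of the tree with terminals scaled by ``lam``."""
    seg_r = {sid: _segment_dc_resistance(s, zeta_v, mu) for sid, s in tree.segments.items()}

    def sub(sid: int) -> float:
        kids = tree.children_of(sid)
        if not kids:
            return seg_r[sid] + lam * tree.terminals[sid].total_resistance
        g = sum(1.0 / sub(k) for k in kids)
        return seg_r[sid] + 1.0 / g

    return sub(tree.root_id)


def conduit_resistance(tree: ArterialTree, zeta_v: float = 6.0, mu: float = MU_BLOOD) -> float:
    """DC resistance of the conduit network alone (terminals shorted)."""
    seg_r = {sid: _segment_dc_resistance(s, zeta_v, mu) for sid, s in tree.segments.items()}

    def sub(sid: int) -> float:
        kids = tree.children_of(sid)
        if not kids:
            return seg_r[sid]
        g = sum(1.0 / sub(k) for k in kids)
        return seg_r[sid] + 1.0 / g

    return sub(tree.root_id)


def scale_terminal_resistances(tree: ArterialTree, TPR_target: float, *,
                               conduit: str = "network", zeta_v: float = 6.0,
                               mu: float = MU_BLOOD) -> ArterialTree:
    """Rescale every terminal (R1 + R2) by a common factor lambda.

    With ``conduit='none'`` lambda is the closed-form ratio making the
    parallel combination of all terminal resistances equal TPR_target.
    With ``conduit='network'`` (default) lambda is solved so the *total* DC
    input resistance of the tree — viscous conduit resistances included —
    equals TPR_target; the conduit correction is small but keeps the
    converged mean aortic pressure on target.

    The R1:R2 split and terminal compliances are preserved.
    """
    if TPR_target <= 0:
        raise ValueError("TPR_target must be positive")
    new = tree.copy()
    if conduit == "none":
        lam = TPR_target / tree.parallel_terminal_resistance()
    elif conduit == "network":
        r_min = _network_resistance(tree, 0.0, zeta_v, mu)
        if TPR_target <= r_min:
            raise ValueError(
                f"TPR target {TPR_target:.3e} unachievable: conduit network alone "
                f"contributes {r_min:.3e} Pa.s/m^3")
        lam0 = TPR_target / tree.parallel_terminal_resistance()

        def f(lam):
            return _network_resistance(tree, lam, zeta_v, mu) - TPR_target

        lo, hi = lam0, lam0
        while f(lo) > 0:
            lo *= 0.5
        while f(hi) < 0:
            hi *= 2.0
        lam = lam0 if lo == hi else brentq(f, lo, hi, xtol=1e-12 * lam0)
    else:
        raise ValueError(f"unknown conduit mode '{conduit}'")
    for t in new.terminals.values():
        t.R1 *= lam
        t.R2 *= lam
    return new


# --------------------------------------------------------------------------
# applying a profile
# --------------------------------------------------------------------------

@dataclass
class ConfiguredModel:
    """A tree with age-calibrated walls and terminals plus cardiac params."""

    tree: ArterialTree
    profile: AgeingProfile

    @property
    def age(self) -> float:
        return self.profile.age


def apply_profile(tree: ArterialTree, profile: AgeingProfile, *,
                  P_ref: float = P_REF, zeta_v: float = 6.0) -> ConfiguredModel:
    """Configure a base tree for one age.

    Every segment's wall law is recalibrated at the reference pressure so
    its local PWV (at the segment mean diameter) follows the decade
    relation; terminal resistances are rescaled to the decade TPR;
    geometry is untouched.  Idempotent: applying the same profile twice
    yields the same model.
    """
    aged = tree.copy()
    for s in aged.segments.values():
        d = s.mean_diameter
        A_ref = np.pi * d * d / 4.0
        gamma = s.wall.gamma if s.wall is not None else 0.0
        s.wall = calibrate_wall(A_ref, pwv_from_diameter(d, profile.age),
                                P_ref=P_ref, gamma=gamma)
    aged = scale_terminal_resistances(aged, profile.TPR, conduit="network",
                                      zeta_v=zeta_v)
    return ConfiguredModel(tree=aged, profile=profile)
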