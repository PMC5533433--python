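"""Time-varying-elastance left ventricle and aortic valve.

The ventricle follows the Sagawa elastance concept: ``P_lv = E(t) (V - V0)``
with ``E(t)`` interpolating between end-diastolic (E_ed) and end-systolic
(E_es) elastance through a normalized double-Hill activation curve whose
shape is taken to be invariant across ages and heart rates.

The aortic valve transmits flow with a quadratic (turbulence) and an
inertial pressure loss::

    dp = P_lv - P_a = B Q |Q| + L dQ/dt
    B  = rho / (2 (A_max z)^2),   L = rho l_eff / (A_max z)

where ``z`` is the valve opening fraction with first-order pressure-driven
opening/closing dynamics.  Filling happens through a perfect mitral check
valve with linear resistance from a constant venous pressure P_ven.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CardiacParams",
    "ElastanceShape",
    "ValveState",
    "CARDIAC_TABLE",
    "cardiac_params",
    "normalized_elastance",
    "elastance",
    "ventricular_pressure",
    "valve_coefficients",
    "valve_pressure_drop",
    "valve_state_update",
    "mitral_inflow",
]


@dataclass(frozen=True)
class CardiacParams:
    """Left-ventricle parameter set for one age decade.

    E_es, E_ed in Pa/m^3; P_ven (venous / end-diastolic filling pressure)
    in Pa; HR in beats/min; V0 (unstressed volume) and the mitral filling
    resistance close the filling side of the model.
    """

    E_es: float
    E_ed: float
    P_ven: float
    HR: float
    V0: float = 10e-6  # m^3
    R_mitral: float = 1.5e6  # Pa.s/m^3, calibrated once (see ageing module)

    def __post_init__(self):
        if not self.E_es > self.E_ed > 0:
            raise ValueError("need E_es > E_ed > 0")
        if self.HR <= 0 or self.P_ven <= 0:
            raise ValueError("HR and P_ven must be positive")

    @property
    def period(self) -> float:
        return 60.0 / self.HR


# Ageing cardiac parameter set, one column per decade: the ventricular wall
# thickens and stiffens (E_es up ~47% over 50 y, E_ed proportionally),
# filling pressure rises to defend end-diastolic volume, and heart rate
# drifts down.
CARDIAC_TABLE: dict[int, CardiacParams] = {
    30: CardiacParams(E_es=1.37e8, E_ed=3.43e6, P_ven=861.0, HR=73.3),
    40: CardiacParams(E_es=1.45e8, E_ed=3.63e6, P_ven=895.0, HR=72.1),
    50: CardiacParams(E_es=1.55e8, E_ed=3.67e6, P_ven=937.0, HR=70.9),
    60: CardiacParams(E_es=1.65e8, E_ed=4.13e6, P_ven=987.0, HR=69.7),
    70: CardiacParams(E_es=1.80e8, E_ed=4.50e6, P_ven=1046.0, HR=68.5),
    80: CardiacParams(E_es=2.01e8, E_ed=5.03e6, P_ven=1131.0, HR=67.3),
}


def cardiac_params(age: float) -> CardiacParams:
    """Decade row, or linear interpolation for intermediate ages."""
    if not 30 <= age <= 80:
        raise ValueError(f"age {age} outside supported range [30, 80]")
    decade = int(round(age / 10) * 10)
    if age == decade and decade in CARDIAC_TABLE:
        return CARDIAC_TABLE[decade]
    lo = int(np.floor(age / 10) * 10)
    hi = min(lo + 10, 80)
    w = (age - lo) / 10.0
    a, b = CARDIAC_TABLE[lo], CARDIAC_TABLE[hi]
    return CardiacParams(
        E_es=(1 - w) * a.E_es + w * b.E_es,
        E_ed=(1 - w) * a.E_ed + w * b.E_ed,
        P_ven=(1 - w) * a.P_ven + w * b.P_ven,
        HR=(1 - w) * a.HR + w * b.HR,
        V0=a.V0, R_mitral=a.R_mitral)


@dataclass(frozen=True)
class ElastanceShape:
    """Double-Hill normalized elastance.

    ``E_N(t_N) = k ((t_N/tau1)^m1 / (1+(t_N/tau1)^m1)) (1/(1+(t_N/tau2)^m2))``

    with normalized time t_N = t/T over one cardiac period.  The defaults
    are the widely used activation constants of this model family; ``k``
    rescales the curve so its maximum is exactly 1.
    """

    m1: float = 1.9
    m2: float = 27.4
    tau1: float = 0.30  # fraction of the period
    tau2: float = 0.452  # fraction of the period

    @property
    def k_norm(self) -> float:
        t = np.linspace(1e-9, 1.0, 20001)
        return 1.0 / np.max(self._raw(t))

    def _raw(self, t_N):
        t_N = np.asarray(t_N, dtype=float)
        h1 = (t_N / self.tau1) ** self.m1
        h2 = (t_N / self.tau2) ** self.m2
        return (h1 / (1.0 + h1)) / (1.0 + h2)


DEFAULT_SHAPE = ElastanceShape()
_K_NORM_DEFAULT = DEFAULT_SHAPE.k_norm


def normalized_elastance(t_N, shape: ElastanceShape = DEFAULT_SHAPE):
    """E_N at normalized time t_N in [0, 1]; max over the cycle is 1."""
    t_N = np.asarray(t_N, dtype=float)
    if np.any(t_N < 0) or np.any(t_N > 1):
        raise ValueError("t_N must lie in [0, 1]")
    k = _K_NORM_DEFAULT if shape is DEFAULT_SHAPE else shape.k_norm
    out = k * shape._raw(np.where(t_N <= 0, 1e-12, t_N))
    return float(out) if out.ndim == 0 else out


def elastance(t, params: CardiacParams, shape: ElastanceShape = DEFAULT_SHAPE):
    """Dimensional elastance E(t) over one period, Pa/m^3."""
    T = params.period
    t_N = np.mod(np.asarray(t, dtype=float), T) / T
    return params.E_ed + (params.E_es - params.E_ed) * normalized_elastance(t_N, shape)


def ventricular_pressure(V, t, params: CardiacParams,
                         shape: ElastanceShape = DEFAULT_SHAPE):
    """P_lv = E(t) (V - V0), floored at 0 for (non-physical) V < V0."""
    p = elastance(t, params, shape) * (np.asarray(V, dtype=float) - params.V0)
    return np.maximum(p, 0.0)


@dataclass
class ValveState:
    """Aortic valve opening state and loss coefficients."""

    zeta: float = 0.0  # opening fraction in [0, 1]
    A_max: float = 3.2e-4  # m^2, fully open effective orifice area
    l_eff: float = 0.03  # m, effective inertial length
    K_vo: float = 0.02  # 1/(Pa.s)
    K_vc: float = 0.08  # 1/(Pa.s); the valve closes faster than it opens
    rho: float = 1050.0

    def __post_init__(self):
        self.zeta = float(np.clip(self.zeta, 0.0, 1.0))


def valve_coefficients(state: ValveState) -> tuple[float, float]:
    """Turbulence coefficient B (Pa.s^2/m^6) and inertance L (Pa.s^2/m^3).

    Both diverge as the valve closes (zeta -> 0): a closed valve admits no
    flow.
    """
    z = max(state.zeta, 0.0)
    if z == 0.0:
        return np.inf, np.inf
    Aeff = state.A_max * z
    return state.rho / (2.0 * Aeff * Aeff), state.rho * state.l_eff / Aeff


def valve_pressure_drop(Q: float, dQ_dt: float, state: ValveState) -> float:
    """Transvalvular pressure drop dp = B Q|Q| + L dQ/dt."""
    if state.zeta <= 0.0:
        if Q != 0.0:
            raise ValueError("closed valve cannot carry flow")
        return 0.0
    B, L = valve_coefficients(state)
    return B * Q * abs(Q) + L * dQ_dt


def valve_state_update(state: ValveState, dp: float, dt: float) -> ValveState:
    """One explicit step of the opening dynamics, clipped to [0, 1].

    dzeta/dt = (1 - zeta) K_vo dp   for dp > 0 (opening)
             = zeta K_vc dp         for dp <= 0 (closing; dp < 0)
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = state.zeta
    rate = (1.0 - z) * state.K_vo * dp if dp > 0 else z * state.K_vc * dp
    z_new = float(np.clip(z + dt * rate, 0.0, 1.0))
    return replace(state, zeta=z_new)


def mitral_inflow(P_ven: float, P_lv: float, R_mitral: float) -> float:
    """Perfect mitral check valve: Q = max(0, (P_ven - P_lv) / R_mitral)."""
    if R_mitral <= 0:
        raise ValueError("R_mitral must be positive")
    return max(0.0, (P_ven - P_lv) / R_mitral)
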