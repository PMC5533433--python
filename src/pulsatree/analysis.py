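"""Derived hemodynamic indices.

Implements the full pulse-wave-analysis stack: systolic/diastolic/mean
pressures, input-impedance spectra and characteristic impedance (averaged
over 3–15 Hz), linear forward/backward wave separation
``P_f,b = (P~ +/- Zc Q~)/2``, inflection-point detection with augmentation
pressure and index, pulse-pressure amplification, normalized RMS error,
and the per-decade summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .records import WaveRecord
from .units import MMHG

__all__ = [
    "PulseIndices",
    "ImpedanceSpectrum",
    "WaveSeparation",
    "pulse_indices",
    "input_impedance",
    "separate_waves",
    "inflection_and_augmentation",
    "pp_amplification",
    "nrmse",
    "decade_summary",
    "summarize_record",
]


@dataclass(frozen=True)
class PulseIndices:
    """SBP/DBP/MAP/PP of one cycle, in mmHg."""

    SBP: float
    DBP: float
    MAP: float
    PP: float


def pulse_indices(record: WaveRecord, *, endpoint_tol: float = 5.0 * MMHG) -> PulseIndices:
    """Systolic (max), diastolic (min), mean and pulse pressure in mmHg.

    Warns (via the record's meta) when the endpoints differ by more than
    ``endpoint_tol``, which indicates a non-periodic record.
    """
    P = record.P
    if abs(P[0] - P[-1]) > endpoint_tol:
        import warnings

        warnings.warn(f"record '{record.site}' endpoints differ by "
                      f"{abs(P[0] - P[-1]) / MMHG:.1f} mmHg; not periodic?")
    sbp = float(np.max(P)) / MMHG
    dbp = float(np.min(P)) / MMHG
    mapp = float(np.mean(P)) / MMHG
    return PulseIndices(SBP=sbp, DBP=dbp, MAP=mapp, PP=sbp - dbp)


@dataclass
class ImpedanceSpectrum:
    """Input impedance at the cardiac harmonics."""

    frequencies: np.ndarray  # Hz, k * HR/60 for k >= 1
    Z_modulus: np.ndarray  # Pa.s/m^3
    Z_phase: np.ndarray  # rad
    Zc: float  # characteristic impedance estimate (3-15 Hz average)
    Z0: float  # DC input resistance P_mean/Q_mean
    excluded: list = field(default_factory=list)  # harmonics with ~zero flow


def input_impedance(P: np.ndarray, Q: np.ndarray, T: float, *,
                    f_lo: float = 3.0, f_hi: float = 15.0) -> ImpedanceSpectrum:
    """Harmonic input impedance Z_k = P_k / Q_k and its 3–15 Hz average.

    ``P`` and ``Q`` must sample exactly one period uniformly (exclusive
    right endpoint).  Harmonics whose flow modulus sits at the numerical
    floor are excluded from the spectrum with a note.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    n = len(P)
    Pf = np.fft.rfft(P) / n
    Qf = np.fft.rfft(Q) / n
    f0 = 1.0 / T
    k = np.arange(1, len(Pf))
    floor = max(np.max(np.abs(Qf[1:])), 1e-300) * 1e-10
    keep = np.abs(Qf[1:]) > floor
    excluded = list(k[~keep])
    Z = Pf[1:][keep] / Qf[1:][keep]
    freqs = k[keep] * f0
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    if not np.any(mask):
        raise ValueError(f"no cardiac harmonics inside [{f_lo}, {f_hi}] Hz")
    zc = float(np.mean(np.abs(Z)[mask]))
    q_mean = np.real(Qf[0])
    z0 = float(np.real(Pf[0]) / q_mean) if q_mean != 0 else np.inf
    return ImpedanceSpectrum(frequencies=freqs, Z_modulus=np.abs(Z),
                             Z_phase=np.angle(Z), Zc=zc, Z0=z0, excluded=excluded)


@dataclass
class WaveSeparation:
    """Forward/backward pulsatile pressure components (means removed)."""

    P_forward: np.ndarray
    P_backward: np.ndarray
    PP_forward: float  # Pa
    PP_backward: float  # Pa
    Zc: float


def separate_waves(P: np.ndarray, Q: np.ndarray, Zc: float) -> WaveSeparation:
    """Linear wave separation on the pulsatile components.

    P_f = (P~ + Zc Q~)/2, P_b = (P~ - Zc Q~)/2 with P~ = P - mean(P),
    Q~ = Q - mean(Q); the reconstruction P_f + P_b = P~ is exact.
    """
    if Zc <= 0:
        raise ValueError("Zc must be positive")
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    Pt = P - np.mean(P)
    Qt = Q - np.mean(Q)
    Pfw = 0.5 * (Pt + Zc * Qt)
    Pbw = 0.5 * (Pt - Zc * Qt)
    return WaveSeparation(
        P_forward=Pfw, P_backward=Pbw,
        PP_forward=float(np.max(Pfw) - np.min(Pfw)),
        PP_backward=float(np.max(Pbw) - np.min(Pbw)),
        Zc=Zc)


@dataclass(frozen=True)
class Augmentation:
    t_inflection: float  # ms from the waveform foot
    AP: float  # same units as the input pressure; signed
    AIx: float  # %
    t_foot: float  # ms from the start of the record
    type_a: bool  # inflection before the systolic peak


def inflection_and_augmentation(P: np.ndarray, fs: float = 1000.0, *,
                                window: int = 21, polyorder: int = 3) -> Augmentation:
    """Inflection point, augmentation pressure and augmentation index.

    The waveform is rolled so the foot (pressure minimum) leads, smoothed
    with a Savitzky–Golay filter, and searched for the reflected-wave
    shoulder: the first minimum of dP/dt after the early-systolic slope
    maximum and before the peak (a concave-convex transition of the
    upstroke).  If the shoulder only appears after the peak (young,
    late-inflecting waves) it is located as the dP/dt maximum on the
    falling limb and AP is reported with a negative sign:

        AP  = SBP - P(t_i)  (inflection before peak)
            = P(t_i) - SBP  (inflection after peak)
        AIx = 100 AP / PP
    """
    P = np.asarray(P, dtype=float)
    n = len(P)
    if n < window + 2:
        raise ValueError("record too short for inflection analysis")
    if np.ptp(P) == 0:
        raise ValueError("flat pressure record: no identifiable foot")
    i_foot = int(np.argmin(P))
    Pc = np.roll(P, -i_foot)
    w = min(window if window % 2 == 1 else window + 1, (n // 2) * 2 - 1)
    Ps = savgol_filter(Pc, w, polyorder, mode="wrap")
    d1 = savgol_filter(Pc, w, polyorder, deriv=1, mode="wrap")
    d2 = savgol_filter(Pc, w, polyorder, deriv=2, mode="wrap")

    i_peak = int(np.argmax(Ps))
    sbp = float(np.max(P))
    pp = float(np.ptp(P))

    i_maxslope = int(np.argmax(d1[: max(i_peak, 2)])) if i_peak > 1 else 0
    ti = None
    type_a = True
    # first minus-to-plus crossing of P'' (local minimum of dP/dt) on the
    # upstroke after the slope maximum
    for i in range(i_maxslope + 1, i_peak):
        if d2[i - 1] < 0.0 <= d2[i]:
            ti = i
            break
    if ti is None:
        # falling-limb shoulder: first plus-to-minus crossing of P'' after
        # the peak (local maximum of dP/dt on the decay), searched over the
        # systolic part of the cycle
        type_a = False
        i_hi = min(n - 2, i_peak + int(0.35 * n))
        for i in range(i_peak + 2, i_hi):
            if d2[i - 1] > 0.0 >= d2[i]:
                ti = i
                break
    if ti is None:
        # degenerate fallback: extremum of smoothed dP/dt between slope
        # maximum and peak
        type_a = True
        lo = i_maxslope + 1
        hi = max(i_peak, lo + 1)
        ti = lo + int(np.argmin(d1[lo:hi]))

    p_i = float(Ps[ti])
    ap = (sbp - p_i) if type_a else (p_i - sbp)
    aix = 100.0 * ap / pp
    return Augmentation(t_inflection=ti / fs * 1e3, AP=ap, AIx=aix,
                        t_foot=i_foot / fs * 1e3, type_a=type_a)


def pp_amplification(peripheral: WaveRecord, central: WaveRecord) -> float:
    """Ratio of peripheral (brachial) to central (aortic) pulse pressure."""
    pp_c = float(np.ptp(central.P))
    if pp_c <= 0:
        raise ValueError("central pulse pressure is zero")
    return float(np.ptp(peripheral.P)) / pp_c


def nrmse(predicted, reference) -> float:
    """Normalized RMS error, % of the reference mean."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.size == 0:
        raise ValueError("inputs must be equal-length and non-empty")
    m = np.mean(r)
    if m == 0:
        raise ValueError("zero-mean reference")
    return float(100.0 * np.sqrt(np.mean((p - r) ** 2)) / m)


# --------------------------------------------------------------------------
# decade summary
# --------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "age_y", "SBP_brachial_mmHg", "SBP_aortic_mmHg", "MAP_mmHg", "DBP_mmHg",
    "PP_peripheral_mmHg", "PP_central_mmHg", "PP_amplification",
    "AP_mmHg", "AIx_pct", "inflection_ms",
    "Zc_mmHg_s_per_ml", "PP_forward_mmHg", "PP_backward_mmHg",
    "PP_forward_over_central", "CO_l_min", "converged",
]


def summarize_record(aortic: WaveRecord, brachial: WaveRecord) -> dict:
    """All per-decade indices from the aortic-root and brachial records."""
    ia = pulse_indices(aortic)
    ib = pulse_indices(brachial)
    spec = input_impedance(aortic.P, aortic.Q, aortic.period)
    sep = separate_waves(aortic.P, aortic.Q, spec.Zc)
    aug = inflection_and_augmentation(aortic.P, fs=aortic.fs)
    return {
        "SBP_brachial_mmHg": ib.SBP,
        "SBP_aortic_mmHg": ia.SBP,
        "MAP_mmHg": ia.MAP,
        "DBP_mmHg": ia.DBP,
        "PP_peripheral_mmHg": ib.PP,
        "PP_central_mmHg": ia.PP,
        "PP_amplification": pp_amplification(brachial, aortic),
        "AP_mmHg": aug.AP / MMHG,
        "AIx_pct": aug.AIx,
        "inflection_ms": aug.t_inflection,
        "Zc_mmHg_s_per_ml": spec.Zc / MMHG / 1e6,
        "PP_forward_mmHg": sep.PP_forward / MMHG,
        "PP_backward_mmHg": sep.PP_backward / MMHG,
        "PP_forward_over_central": sep.PP_forward / (ia.PP * MMHG),
    }


def decade_summary(sweep: dict) -> pd.DataFrame:
    """Assemble the per-decade summary table.

    ``sweep`` maps age -> SimulationResult (or any object exposing
    ``records['aortic_root']``, ``records['brachial']``, ``converged`` and
    optionally ``co_mean``).
    """
    rows = []
    for age in sorted(sweep):
        res = sweep[age]
        row = {"age_y": age}
        row.update(summarize_record(res.records["aortic_root"], res.records["brachial"]))
        row["CO_l_min"] = getattr(res, "co_mean", np.nan) * 6e4
        row["converged"] = bool(getattr(res, "converged", True))
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
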