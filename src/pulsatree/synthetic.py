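"""Synthetic pressure/flow waveform generator.

Builds analysis-stack test signals with known ground truth: a forward
Gaussian pressure pulse plus a delayed, scaled echo (the "reflected"
wave), combined through a known characteristic impedance::

    P = P_f + P_b,    Q = (P_f - P_b) / Zc

so wave separation, impedance and inflection detection can be validated
without running the 1-D solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import MMHG

__all__ = ["SyntheticWaves", "synthetic_waveform"]


@dataclass
class SyntheticWaves:
    t: np.ndarray  # s
    P: np.ndarray  # Pa
    Q: np.ndarray  # m^3/s
    P_forward: np.ndarray  # ground truth, Pa (pulsatile)
    P_backward: np.ndarray
    Zc: float  # Pa.s/m^3
    hr: float
    echo_delay: float  # s
    echo_gain: float
    t_pulse: float  # s, forward pulse centre


def synthetic_waveform(*, hr: float = 70.0, amplitude: float = 20.0 * MMHG,
                       t_pulse: float = 0.12, width: float = 0.045,
                       echo_delay: float = 0.12, echo_gain: float = 0.4,
                       Zc: float = 8e6, baseline: float = 80.0 * MMHG,
                       noise_sd: float = 0.0, seed: int | None = None,
                       fs: float = 1000.0) -> SyntheticWaves:
    """One period of a two-wave synthetic pressure/flow pair.

    ``echo_gain`` in [0, 1) scales the reflected copy of the forward
    Gaussian; ``echo_delay`` (< period) shifts it.  Optional white Gaussian
    noise of standard deviation ``noise_sd`` (Pa) is added to both P and
    Zc*Q with a seeded generator.
    """
    if not 0 <= echo_gain < 1:
        raise ValueError("echo_gain must lie in [0, 1)")
    T = 60.0 / hr
    if not 0 <= echo_delay < T:
        raise ValueError("echo_delay must be smaller than the period")
    n = int(round(T * fs))
    t = np.arange(n) / fs
    pf = amplitude * np.exp(-0.5 * ((t - t_pulse) / width) ** 2)
    # periodic echo
    td = np.mod(t - echo_delay, T)
    pb = echo_gain * amplitude * np.exp(-0.5 * ((td - t_pulse) / width) ** 2)
    P = baseline + pf + pb
    Q = (pf - pb) / Zc
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        P = P + rng.normal(0.0, noise_sd, n)
        Q = Q + rng.normal(0.0, noise_sd, n) / Zc
    return SyntheticWaves(t=t, P=P, Q=Q, P_forward=pf, P_backward=pb, Zc=Zc,
                          hr=hr, echo_delay=echo_delay, echo_gain=echo_gain,
                          t_pulse=t_pulse)
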