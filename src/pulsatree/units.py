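"""Unit conversions.

Everything inside the package is SI (m, Pa, m^3/s).  Clinical I/O uses
mmHg, cm, mL/s; conversions are centralized here so the factors appear
exactly once.
"""

MMHG = 133.322  # Pa per mmHg

ML_PER_M3 = 1e6
ML_S_PER_M3_S = 1e6

# peripheral resistance: mmHg.s/mL <-> Pa.s/m^3
R_CLINICAL = MMHG * 1e6
# compliance: mL/mmHg <-> m^3/Pa
C_CLINICAL = 1e-6 / MMHG


def pa_to_mmhg(p):
    return p / MMHG


def mmhg_to_pa(p):
    return p * MMHG


def lpm_to_m3s(q):
    """Litres per minute to m^3/s."""
    return q * 1e-3 / 60.0


def m3s_to_lpm(q):
    return q * 60.0 * 1e3
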