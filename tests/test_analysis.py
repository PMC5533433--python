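"""Pulse-wave analysis: impedance, separation, augmentation, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pulsatree.analysis import (inflection_and_augmentation, input_impedance, nrmse,
                                pp_amplification, pulse_indices, separate_waves,
                                summarize_record)
from pulsatree.records import WaveRecord
from pulsatree.synthetic import synthetic_waveform
from pulsatree.units import MMHG


def _record(P, Q=None, T=1.0, site="x"):
    n = len(P)
    t = np.arange(n) * (T / n)
    if Q is None:
        Q = np.zeros(n)
    return WaveRecord(site=site, t=t, P=np.asarray(P, float), Q=np.asarray(Q, float))


class TestPulseIndices:
    def test_constant_record(self):
        r = _record(np.full(1000, 100.0 * MMHG))
        idx = pulse_indices(r)
        assert (idx.SBP, idx.DBP, idx.PP) == (100.0, 100.0, 0.0)
        assert idx.MAP == pytest.approx(100.0, rel=1e-12)

    def test_sinusoid_closed_form(self):
        t = np.arange(1000) / 1000.0
        r = _record((100 + 20 * np.sin(2 * np.pi * t)) * MMHG)
        idx = pulse_indices(r)
        assert idx.SBP == pytest.approx(120, abs=0.01)
        assert idx.DBP == pytest.approx(80, abs=0.01)
        assert idx.MAP == pytest.approx(100, abs=0.01)
        assert idx.PP == pytest.approx(40, abs=0.02)

    def test_non_periodic_record_warns(self):
        P = np.linspace(80, 120, 500) * MMHG
        with pytest.warns(UserWarning, match="periodic"):
            pulse_indices(_record(P))


class TestInputImpedance:
    def test_pure_resistor(self):
        t = np.arange(2048) / 2048.0
        P = 1e4 + 2e3 * np.sin(2 * np.pi * 5 * t) + 1e3 * np.cos(2 * np.pi * 9 * t)
        R = 1.25e8
        spec = input_impedance(P, P / R, T=1.0)
        np.testing.assert_allclose(spec.Z_modulus, R, rtol=1e-9)
        assert spec.Zc == pytest.approx(R, rel=1e-9)
        assert spec.Z0 == pytest.approx(R, rel=1e-9)

    def test_recovers_windkessel_impedance_from_ode_solution(self):
        # independent route: integrate the RCR ODE in time, then check the
        # frequency-domain estimator against the analytic impedance
        R1, R2, C, T = 6e6, 1.1e8, 1.2e-8, 0.85
        n = 4096
        t = np.arange(n) * T / n
        rng = np.random.default_rng(7)
        amps = rng.uniform(0.3, 1.0, 6)
        phases = rng.uniform(0, 2 * np.pi, 6)

        def q(tt):
            s = 9e-5
            for k, (a, ph) in enumerate(zip(amps, phases), start=1):
                s = s + 2e-5 * a * np.cos(2 * np.pi * k * tt / T + ph)
            return s

        def rhs(tt, y):
            return [(q(tt) - y[0] / R2) / C]

        sol = solve_ivp(rhs, (0, 14 * T), [q(0) * R2], t_eval=13 * T + t,
                        max_step=T / 2000, rtol=1e-10, atol=1e-8)
        P = sol.y[0] + R1 * q(13 * T + t)
        spec = input_impedance(P, q(13 * T + t), T)
        w = 2 * np.pi * spec.frequencies
        z_true = R1 + R2 / (1 + 1j * w * R2 * C)
        np.testing.assert_allclose(spec.Z_modulus[:6], np.abs(z_true)[:6], rtol=0.01)

    def test_averaging_band_harmonics(self):
        # HR 70 -> f0 = 7/6 Hz: harmonics 3..12 lie inside [3, 15] Hz
        f0 = 70 / 60.0
        k = np.arange(1, 40)
        inside = k[(k * f0 >= 3) & (k * f0 <= 15)]
        assert inside[0] == 3 and inside[-1] == 12

    def test_zero_flow_harmonics_excluded(self):
        t = np.arange(1024) / 1024.0
        P = 1e4 + 1e3 * np.sin(2 * np.pi * 4 * t)
        Q = 8e-5 + 1e-5 * np.sin(2 * np.pi * 4 * t)  # single harmonic only
        spec = input_impedance(P, Q, T=1.0)
        assert len(spec.excluded) > 0
        assert 4 * 1.0 in spec.frequencies * 1.0


class TestWaveSeparation:
    def test_matched_wave_has_no_backward_component(self):
        w = synthetic_waveform(echo_gain=0.0)
        sep = separate_waves(w.P, w.Q, w.Zc)
        assert np.max(np.abs(sep.P_backward)) < 1e-9 * np.max(np.abs(sep.P_forward))
        assert sep.PP_forward == pytest.approx(np.ptp(w.P), rel=1e-12)

    def test_standing_wave_splits_evenly(self):
        t = np.arange(1000) / 1000.0
        P = 1e4 + 2e3 * np.sin(2 * np.pi * t)
        sep = separate_waves(P, np.zeros_like(P), 8e6)
        Pt = P - P.mean()
        np.testing.assert_allclose(sep.P_forward, Pt / 2, atol=1e-9)
        np.testing.assert_allclose(sep.P_backward, Pt / 2, atol=1e-9)

    def test_reconstruction_is_exact(self):
        w = synthetic_waveform(echo_gain=0.45, noise_sd=30.0, seed=3)
        sep = separate_waves(w.P, w.Q, w.Zc)
        np.testing.assert_allclose(sep.P_forward + sep.P_backward,
                                   w.P - np.mean(w.P), atol=1e-9)

    def test_constructed_echo_ratio_recovered(self):
        w = synthetic_waveform(echo_gain=0.4, echo_delay=0.12)
        sep = separate_waves(w.P, w.Q, w.Zc)
        assert sep.PP_backward / sep.PP_forward == pytest.approx(0.4, rel=0.01)

    @given(st.floats(min_value=0.0, max_value=0.8),
           st.floats(min_value=0.02, max_value=0.5),
           st.integers(min_value=0, max_value=2 ** 16))
    @settings(max_examples=30, deadline=None)
    def test_triangle_bound_on_pulse_pressures(self, gain, delay, seed):
        w = synthetic_waveform(echo_gain=gain, echo_delay=delay,
                               noise_sd=20.0, seed=seed)
        sep = separate_waves(w.P, w.Q, w.Zc)
        pp = np.ptp(w.P)
        assert abs(sep.PP_forward - sep.PP_backward) <= pp + 1e-9
        assert pp <= sep.PP_forward + sep.PP_backward + 1e-9

    def test_requires_positive_zc(self):
        with pytest.raises(ValueError):
            separate_waves(np.ones(4), np.ones(4), 0.0)


class TestAugmentation:
    @staticmethod
    def _two_wave(fs=1000.0, gain=1.3, delay=0.12):
        # augmented (type A) morphology: the late "reflected" hump exceeds
        # the early systolic shoulder, with a clear inflection between
        t = np.arange(int(0.85 * fs)) / fs
        p1 = np.exp(-0.5 * ((t - 0.10) / 0.03) ** 2)
        p2 = gain * np.exp(-0.5 * ((t - 0.10 - delay) / 0.04) ** 2)
        return t, 80 * MMHG + 20 * MMHG * (p1 + p2)

    def test_detects_constructed_inflection(self):
        t, P = self._two_wave()
        # independent oracle: dP/dt minimum between the slope maximum and
        # the peak on a 100 kHz analytic evaluation of the same curve
        tf = np.arange(0, 0.85, 1e-5)
        Pf = 20 * (np.exp(-0.5 * ((tf - 0.10) / 0.03) ** 2)
                   + 1.3 * np.exp(-0.5 * ((tf - 0.22) / 0.04) ** 2))
        d1 = np.gradient(Pf, tf)
        i_pk = int(np.argmax(Pf))
        i_ms = int(np.argmax(d1[:i_pk]))
        ti_true = tf[i_ms + int(np.argmin(d1[i_ms:i_pk]))]
        assert d1[i_ms:i_pk].min() < 0 < d1[i_pk - 1]  # a genuine shoulder exists
        aug = inflection_and_augmentation(P, fs=1000.0)
        # times are reported from the waveform foot; map back to absolute
        ti_abs = ((aug.t_foot + aug.t_inflection) % (len(P))) / 1e3
        assert ti_abs == pytest.approx(ti_true, abs=2e-3)
        assert aug.type_a
        # AP equals the analytic peak-minus-shoulder height
        ap_true = (Pf[i_pk] - Pf[i_ms + int(np.argmin(d1[i_ms:i_pk]))]) * MMHG
        assert aug.AP == pytest.approx(ap_true, rel=0.15)

    def test_scale_and_offset_invariance_of_aix(self):
        t, P = self._two_wave()
        a1 = inflection_and_augmentation(P)
        a2 = inflection_and_augmentation(3.7 * P)
        assert a2.AIx == pytest.approx(a1.AIx, abs=0.2)
        assert a2.t_inflection == a1.t_inflection

    def test_resampling_invariance(self):
        t, P = self._two_wave()
        a1 = inflection_and_augmentation(P, fs=1000.0)
        P2 = np.interp(np.arange(2 * len(P)) / 2000.0, t, P, period=t[-1] + 1e-3)
        a2 = inflection_and_augmentation(P2, fs=2000.0)
        assert a2.t_inflection == pytest.approx(a1.t_inflection, abs=2.0)

    def test_flat_record_rejected(self):
        with pytest.raises(ValueError):
            inflection_and_augmentation(np.full(800, 1e4))


class TestScalarMetrics:
    def test_nrmse_cases(self):
        ref = np.full(10, 100.0)
        assert nrmse(ref, ref) == 0.0
        assert nrmse(ref * 1.01, ref) == pytest.approx(1.0, rel=1e-9)
        assert nrmse([110.0, 90.0], [100.0, 100.0]) == pytest.approx(10.0, rel=1e-12)

    def test_nrmse_rejects_zero_mean_reference(self):
        with pytest.raises(ValueError):
            nrmse([1.0, -1.0], [1.0, -1.0])

    def test_pp_amplification(self):
        t = np.arange(1000) / 1000.0
        r = _record((100 + 20 * np.sin(2 * np.pi * t)) * MMHG)
        assert pp_amplification(r, r) == 1.0
        flat = _record(np.full(1000, 100.0 * MMHG))
        with pytest.raises(ValueError):
            pp_amplification(r, flat)


class TestSynthetic:
    def test_seed_reproducibility(self):
        a = synthetic_waveform(noise_sd=40.0, seed=11)
        b = synthetic_waveform(noise_sd=40.0, seed=11)
        np.testing.assert_array_equal(a.P, b.P)
        np.testing.assert_array_equal(a.Q, b.Q)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            synthetic_waveform(echo_gain=1.2)
        with pytest.raises(ValueError):
            synthetic_waveform(echo_delay=5.0, hr=70)


class TestModelSummary:
    def test_internal_identities_per_decade(self, decade_sweep):
        for age, res in decade_sweep.items():
            row = summarize_record(res.records["aortic_root"], res.records["brachial"])
            assert row["PP_central_mmHg"] == pytest.approx(
                row["SBP_aortic_mmHg"] - row["DBP_mmHg"], abs=1e-9)
            assert row["AIx_pct"] == pytest.approx(
                100 * row["AP_mmHg"] / row["PP_central_mmHg"], abs=1e-6)
            assert row["DBP_mmHg"] < row["MAP_mmHg"] < row["SBP_aortic_mmHg"]

    def test_zc_on_matched_tube_matches_theory(self):
        # a single uniform tube with matched termination presents its own
        # characteristic impedance rho c / A to the 3-15 Hz average
        import sys
        sys.path.insert(0, "tests")
        from conftest import make_tube
        from pulsatree.solver import SolverConfig, run_prescribed_inflow
        from pulsatree.wall import P_REF, RHO_BLOOD

        d, pwv = 0.012, 7.0
        A = np.pi * d * d / 4
        zc = RHO_BLOOD * pwv / A
        tree = make_tube(pwv=pwv, diameter=d, length=0.6, R1=zc, R2=4e9, C=2e-8)
        T = 0.8

        def q(t):
            return 4e-6 * (1 + np.cos(2 * np.pi * (t / T - 0.5)) ** 3)

        cfg = SolverConfig(p_init=P_REF, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(tree, q, T, n_cycles=6, config=cfg)
        spec = input_impedance(rec["in"].P, rec["in"].Q, T)
        assert spec.Zc == pytest.approx(zc, rel=0.05)
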