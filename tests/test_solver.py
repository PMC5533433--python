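"""Raw 1-D solver physics against analytic oracles, plus the coupled run."""

import numpy as np
import pytest

from pulsatree.solver import (CFLError, SolverConfig, run_prescribed_inflow,
                              run_to_periodic)
from pulsatree.units import MMHG
from pulsatree.wall import P_REF, RHO_BLOOD

from conftest import gaussian_pulse, make_bifurcation, make_tube


def _foot_time(t, y, frac=0.1):
    """Time at which y first crosses frac of its peak (linear interpolation)."""
    y = y - y[: max(3, len(y) // 50)].mean()
    thr = frac * np.max(y)
    i = int(np.argmax(y > thr))
    if i == 0:
        return t[0]
    f = (thr - y[i - 1]) / (y[i] - y[i - 1])
    return t[i - 1] + f * (t[i] - t[i - 1])


class TestInterior:
    def test_constant_state_is_steady(self):
        tree = make_tube(pwv=8.0)
        cfg = SolverConfig(p_init=P_REF, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(tree, lambda t: 0.0, 0.5, config=cfg)
        # zero flow, uniform pressure at the wall-law reference: nothing moves
        assert np.max(np.abs(rec["mid"].P - P_REF)) < 1e-6 * P_REF
        assert np.max(np.abs(rec["mid"].Q)) < 1e-12

    def test_poiseuille_limit(self):
        # steady flow, profile coefficient 2, near-rigid wall at the
        # operating pressure: dP = 8 mu l Q / (pi r^4)
        d, L, Q = 0.01, 0.2, 5e-6
        tree = make_tube(pwv=30.0, diameter=d, length=L,
                         R1=0.0, R2=1e7, C=5e-8)
        cfg = SolverConfig(p_init=P_REF, zeta_v=2.0, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(tree, lambda t: Q, 8.0, config=cfg)
        dp = rec["in"].P[-1] - rec["out"].P[-1]
        mu = cfg.mu
        expected = 8 * mu * L * Q / (np.pi * (d / 2) ** 4)
        assert dp == pytest.approx(expected, rel=0.02)

    def test_pulse_speed_matches_bramwell_hill(self):
        pwv = 8.0
        tree = make_tube(pwv=pwv, diameter=0.012, length=1.2, R1=2e8, R2=2e9, C=1e-10)
        cfg = SolverConfig(p_init=P_REF, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(
            tree, gaussian_pulse(q_peak=2e-6, t0=0.03, width=0.006), 0.35,
            config=cfg, extra_sites={"x1": (1, 0.2), "x2": (1, 0.8)})
        t = rec["x1"].t
        dt_foot = _foot_time(t, rec["x2"].P) - _foot_time(t, rec["x1"].P)
        c_meas = 0.6 * 1.2 / dt_foot
        assert c_meas == pytest.approx(pwv, rel=0.02)


class TestJunctions:
    def test_symmetric_bifurcation_splits_flow_evenly(self):
        tree = make_bifurcation()
        cfg = SolverConfig(p_init=P_REF, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(
            tree, gaussian_pulse(q_peak=3e-6, t0=0.03, width=0.008), 0.25, config=cfg)
        np.testing.assert_allclose(rec["a_mid"].Q, rec["b_mid"].Q, atol=1e-18 + 1e-10)

    def test_matched_continuation_transmits_without_reflection(self):
        # one child with identical calibre and wall: no impedance step
        from pulsatree.tree import ArterialSegment, ArterialTree, WindkesselTerminal
        from pulsatree.wall import calibrate_wall

        d, pwv = 0.01, 8.0
        A = np.pi * d * d / 4
        law = calibrate_wall(A, pwv)
        segs = {
            1: ArterialSegment(1, "up", 0.4, d, d, None, wall=law),
            2: ArterialSegment(2, "down", 0.4, d, d, 1, wall=law),
        }
        zc = RHO_BLOOD * pwv / A
        tree = ArterialTree(segs, {2: WindkesselTerminal(zc, 5e9, 1e-11, P_REF)},
                            {"up_mid": (1, 0.5), "down_mid": (2, 0.5)})
        cfg = SolverConfig(p_init=P_REF, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(
            tree, gaussian_pulse(q_peak=2e-6, t0=0.025, width=0.006), 0.16, config=cfg)
        up, down = rec["up_mid"].P - P_REF, rec["down_mid"].P - P_REF
        # reference: the same pulse in one uninterrupted 0.8 m tube, probed
        # at the same stations, isolates the frictional decay
        ref = make_tube(pwv=pwv, diameter=d, length=0.8, R1=zc, R2=5e9, C=1e-11)
        rec0, _ = run_prescribed_inflow(
            ref, gaussian_pulse(q_peak=2e-6, t0=0.025, width=0.006), 0.16,
            config=cfg, extra_sites={"x1": (1, 0.25), "x2": (1, 0.75)})
        decay_ref = np.max(rec0["x2"].P - P_REF) / np.max(rec0["x1"].P - P_REF)
        # crossing the junction transmits like plain tube travel within 1 %
        assert np.max(down) / np.max(up) == pytest.approx(decay_ref, rel=0.01)
        # after the pulse has passed, the junction echo over the upstream
        # site is below 2 % of the incident amplitude
        t = rec["up_mid"].t
        tail = up[(t > 0.085) & (t < 0.135)]
        assert np.max(np.abs(tail)) < 0.02 * np.max(up)

    def test_reflection_coefficient_matches_linear_theory(self):
        # large calibre step parent -> single child
        from pulsatree.tree import ArterialSegment, ArterialTree, WindkesselTerminal
        from pulsatree.wall import calibrate_wall

        d1, d2, pwv = 0.012, 0.007, 8.0
        A1, A2 = np.pi * d1 ** 2 / 4, np.pi * d2 ** 2 / 4
        segs = {
            1: ArterialSegment(1, "p", 0.5, d1, d1, None, wall=calibrate_wall(A1, pwv)),
            2: ArterialSegment(2, "c", 0.5, d2, d2, 1, wall=calibrate_wall(A2, pwv)),
        }
        z2 = RHO_BLOOD * pwv / A2
        tree = ArterialTree(segs, {2: WindkesselTerminal(z2, 5e9, 1e-11, P_REF)},
                            {"probe": (1, 0.4)})
        cfg = SolverConfig(p_init=P_REF, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(
            tree, gaussian_pulse(q_peak=1e-6, t0=0.025, width=0.005), 0.2, config=cfg)
        t, P = rec["probe"].t, rec["probe"].P - P_REF
        # incident peak passes the probe at ~0.05 s; the junction echo
        # (0.3 m away, 75 ms round trip) arrives at ~0.125 s
        inc = np.max(P[(t > 0.02) & (t < 0.08)])
        refl = np.max(P[(t > 0.10) & (t < 0.155)])
        z1 = RHO_BLOOD * pwv / A1
        gamma = (1 / z1 - 1 / z2) / (1 / z1 + 1 / z2)
        assert refl / inc == pytest.approx(gamma, abs=0.05 * gamma)


class TestTerminals:
    def test_windkessel_dc_limit(self):
        Q = 1e-5
        R1, R2 = 2e8, 8e8
        tree = make_tube(pwv=20.0, R1=R1, R2=R2, C=2e-9)
        cfg = SolverConfig(p_init=P_REF, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(tree, lambda t: Q, 15.0, config=cfg)
        # the viscous tube drop is excluded by reading the outlet pressure
        assert rec["out"].P[-1] == pytest.approx(P_REF + (R1 + R2) * Q, rel=0.02)

    def test_windkessel_rc_decay(self):
        R1, R2, C = 2e8, 8e8, 2e-9
        # very stiff tube so the tube's own compliance is negligible
        tree = make_tube(pwv=60.0, R1=R1, R2=R2, C=C)
        cfg = SolverConfig(p_init=160 * MMHG, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(tree, lambda t: 0.0, 3.5, config=cfg)
        t, P = rec["out"].t, rec["out"].P - P_REF  # stored charge relaxes to P_out
        sel = (t > 0.3) & (t < 2.8)
        k = np.polyfit(t[sel], np.log(P[sel]), 1)
        assert -1.0 / k[0] == pytest.approx(R2 * C, rel=0.02)

    def test_matched_terminal_absorbs_early_systolic_wave(self):
        d, pwv = 0.01, 8.0
        A = np.pi * d * d / 4
        zc = RHO_BLOOD * pwv / A
        tree = make_tube(pwv=pwv, diameter=d, length=0.5, R1=zc, R2=5e9, C=1e-8)
        cfg = SolverConfig(p_init=P_REF, wall_visc_tau=0.0)
        rec, st = run_prescribed_inflow(
            tree, gaussian_pulse(q_peak=2e-6, t0=0.025, width=0.005), 0.2,
            config=cfg, extra_sites={"probe": (1, 0.4)})
        t, P = rec["probe"].t, rec["probe"].P - P_REF
        inc = np.max(P[(t > 0.02) & (t < 0.08)])
        echo = np.max(np.abs(P[(t > 0.10) & (t < 0.16)]))
        assert echo < 0.02 * inc


class TestCoupledRun:
    def test_age30_converges_quickly(self, age30):
        assert age30.converged
        assert age30.n_cycles <= 15

    def test_relaxing_the_tolerance_never_needs_more_cycles(self, age30):
        tol = 0.5 * MMHG
        n1 = age30.cycles_to_converge(tol)
        n2 = age30.cycles_to_converge(2 * tol)
        assert n1 is not None and n2 is not None and n2 <= n1

    def test_cardiac_output_hits_prescribed_value(self, age30):
        assert age30.co_mean * 6e4 == pytest.approx(6.6, rel=0.03)

    def test_mean_aortic_pressure_tracks_map_target(self, age30):
        assert age30.map_aortic / MMHG == pytest.approx(84.8, rel=0.03)

    def test_mass_conservation_over_final_cycle(self, age30):
        assert age30.mass_error < 0.005

    def test_record_layout(self, age30):
        rec = age30.records["aortic_root"]
        assert rec.t[0] == 0.0
        assert rec.fs == pytest.approx(1000.0)
        assert rec.period == pytest.approx(60.0 / 73.3, abs=1e-3)
        assert len(rec.P) == len(rec.Q) == len(rec.A)

    def test_periodic_state_is_initialization_independent(self):
        # same tube + heartless prescribed flow from two initial pressures
        from pulsatree.ageing import ageing_profile, apply_profile
        from dataclasses import replace

        tree = make_tube(pwv=6.0, diameter=0.02, length=0.3, R1=2e7, R2=8e7, C=8e-9)
        # run the full heart-coupled model on the toy tube from two inits
        prof = ageing_profile(30)
        out = []
        for p0 in (60.0, 95.0):
            cfg = SolverConfig(p_init=p0 * MMHG, n_cycles_max=40,
                               periodicity_tol=0.1 * MMHG)
            model = apply_profile(tree, prof)
            res = run_to_periodic(model, config=cfg)
            assert res.converged
            out.append(res.records["mid"].P)
        assert np.max(np.abs(out[0] - out[1])) < 0.5 * MMHG

    def test_cfl_violation_aborts_with_diagnostic(self):
        tree = make_tube(pwv=8.0)
        cfg = SolverConfig(p_init=P_REF, c_headroom_pressure=P_REF,
                           u_headroom=-7.0, wall_visc_tau=0.0)
        with pytest.raises(CFLError):
            run_prescribed_inflow(tree, gaussian_pulse(q_peak=2e-5), 0.3, config=cfg)
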