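"""Shared fixtures.

The decade simulations are expensive (seconds each), so converged runs are
computed once per session and shared; all other fixtures are cheap tube
setups for the raw-physics checks.
"""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("repro", derandomize=True)
hyp_settings.load_profile("repro")

from pulsatree import build_reference_tree, simulate_decade
from pulsatree.tree import ArterialSegment, ArterialTree, WindkesselTerminal
from pulsatree.wall import calibrate_wall

DECADES = (30, 40, 50, 60, 70, 80)


@pytest.fixture(scope="session")
def ref_tree():
    return build_reference_tree()


@pytest.fixture(scope="session")
def age30(ref_tree):
    """Converged reference run at age 30 (shared, read-only)."""
    return simulate_decade(30, ref_tree)


@pytest.fixture(scope="session")
def decade_sweep(ref_tree, age30):
    """Converged reference runs for all six decades (shared, read-only)."""
    out = {30: age30}
    out.update({age: simulate_decade(age, ref_tree) for age in DECADES if age != 30})
    return out


def make_tube(pwv=8.0, diameter=0.01, length=0.2, R1=2e8, R2=8e8, C=2e-9,
              P_out=None, gamma=0.0, seg_id=1):
    """Single uniform elastic tube with a 3-element Windkessel terminal."""
    from pulsatree.wall import P_REF
    if P_out is None:
        P_out = P_REF  # equilibrium at the wall-law reference pressure
    A = np.pi * diameter * diameter / 4.0
    law = calibrate_wall(A, pwv, gamma=gamma)
    seg = ArterialSegment(seg_id, "tube", length, diameter, diameter, None, wall=law)
    return ArterialTree(
        segments={seg_id: seg},
        terminals={seg_id: WindkesselTerminal(R1, R2, C, P_out)},
        named_sites={"in": (seg_id, 0.0), "mid": (seg_id, 0.5), "out": (seg_id, 1.0)},
    )


def make_bifurcation(d_parent=0.012, d_child=0.008, pwv_parent=8.0, pwv_child=8.0,
                     L_parent=0.25, L_child=0.25, R=1e9, C=5e-10):
    """Parent tube splitting into two identical children."""
    Ap = np.pi * d_parent ** 2 / 4
    Ac = np.pi * d_child ** 2 / 4
    segs = {
        1: ArterialSegment(1, "parent", L_parent, d_parent, d_parent, None,
                           wall=calibrate_wall(Ap, pwv_parent)),
        2: ArterialSegment(2, "child_a", L_child, d_child, d_child, 1,
                           wall=calibrate_wall(Ac, pwv_child)),
        3: ArterialSegment(3, "child_b", L_child, d_child, d_child, 1,
                           wall=calibrate_wall(Ac, pwv_child)),
    }
    from pulsatree.wall import P_REF
    terms = {i: WindkesselTerminal(0.2 * R, 0.8 * R, C, P_REF) for i in (2, 3)}
    sites = {"p_in": (1, 0.0), "p_mid": (1, 0.5), "p_end": (1, 0.95),
             "a_in": (2, 0.05), "a_mid": (2, 0.5), "b_mid": (3, 0.5)}
    return ArterialTree(segments=segs, terminals=terms, named_sites=sites)


def gaussian_pulse(q_peak=5e-6, t0=0.05, width=0.01):
    def q(t):
        return q_peak * np.exp(-0.5 * ((t - t0) / width) ** 2)
    return q
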