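"""Packaged 55-segment human systemic arterial tree.

Topology and branch dimensions follow the classic 55-segment systemic
tables of the 1-D modelling literature (aorta from root to bifurcation,
arch vessels, arms, head, visceral and leg branches, linear taper within
each segment).  Aortic and carotid-branch diameters are revised to
contemporary young-adult MRI reference anatomy, and the whole fixture is
calibrated once at the young-adult (age 30) operating point of the decade
study; see docs/methods.md for the calibration rationale.  The table is
frozen here so the model is fully self-contained.

Terminal Windkessels are sized at construction time:

* total terminal resistance — the parallel combination of all (R1 + R2)
  equals the age-30 total peripheral resistance exactly; individual
  terminals share the load according to physiological resting regional
  flow fractions (:data:`TERMINAL_FLOW_SHARES`);
* R1 — matched to the terminal segment's characteristic impedance at the
  calibration pressure (capped at half the terminal total) to limit
  spurious terminal reflections;
* compliance — distributed in proportion to terminal conductance, with the
  peripheral total chosen so that conduit plus peripheral compliance at
  age 30 equals :data:`C_TOTAL_30`.
"""

from __future__ import annotations

import numpy as np

from .ageing import CARDIAC_OUTPUT, MAP_TABLE_MMHG, total_peripheral_resistance
from .tree import ArterialSegment, ArterialTree, WindkesselTerminal, validate_tree
from .units import MMHG
from .wall import RHO_BLOOD, P_REF, area_of_pressure, calibrate_wall, pwv_from_diameter

__all__ = ["build_reference_tree", "SEGMENT_ROWS"]

# id, name, length (cm), proximal radius (cm), distal radius (cm), parent id
SEGMENT_ROWS = [
    (1, "ascending_aorta", 4.0, 1.575, 1.525, None),
    (2, "aortic_arch_a", 2.0, 1.425, 1.375, 1),
    (3, "brachiocephalic", 3.4, 0.620, 0.620, 1),
    (4, "r_subclavian_a", 3.4, 0.423, 0.423, 3),
    (5, "r_common_carotid", 17.7, 0.370, 0.370, 3),
    (6, "r_vertebral", 14.8, 0.188, 0.183, 4),
    (7, "r_subclavian_brachial", 42.2, 0.403, 0.236, 4),
    (8, "r_radial", 23.5, 0.174, 0.142, 7),
    (9, "r_ulnar_a", 6.7, 0.215, 0.215, 7),
    (10, "r_interosseous", 7.9, 0.091, 0.091, 9),
    (11, "r_ulnar_b", 17.1, 0.203, 0.183, 9),
    (12, "r_internal_carotid", 17.6, 0.177, 0.160, 5),
    (13, "r_external_carotid", 17.7, 0.177, 0.130, 5),
    (14, "aortic_arch_b", 3.9, 1.325, 1.275, 2),
    (15, "l_common_carotid", 20.8, 0.370, 0.370, 2),
    (16, "l_internal_carotid", 17.6, 0.177, 0.160, 15),
    (17, "l_external_carotid", 17.7, 0.177, 0.130, 15),
    (18, "l_subclavian_a", 3.4, 0.423, 0.423, 14),
    (19, "thoracic_aorta_a", 5.2, 1.175, 1.125, 14),
    (20, "l_vertebral", 14.8, 0.188, 0.183, 18),
    (21, "l_subclavian_brachial", 42.2, 0.403, 0.236, 18),
    (22, "l_radial", 23.5, 0.174, 0.142, 21),
    (23, "l_ulnar_a", 6.7, 0.215, 0.215, 21),
    (24, "l_interosseous", 7.9, 0.091, 0.091, 23),
    (25, "l_ulnar_b", 17.1, 0.203, 0.183, 23),
    (26, "intercostals", 8.0, 0.200, 0.150, 19),
    (27, "thoracic_aorta_b", 10.4, 1.025, 0.910, 19),
    (28, "abdominal_aorta_a", 5.3, 0.660, 0.650, 27),
    (29, "celiac_a", 1.0, 0.390, 0.390, 27),
    (30, "celiac_b", 1.0, 0.200, 0.200, 29),
    (31, "hepatic", 6.6, 0.220, 0.220, 30),
    (32, "gastric", 7.1, 0.180, 0.180, 30),
    (33, "splenic", 6.3, 0.275, 0.275, 29),
    (34, "superior_mesenteric", 5.9, 0.435, 0.435, 28),
    (35, "abdominal_aorta_b", 1.0, 0.640, 0.635, 28),
    (36, "l_renal", 3.2, 0.260, 0.260, 35),
    (37, "abdominal_aorta_c", 1.0, 0.630, 0.625, 35),
    (38, "r_renal", 3.2, 0.260, 0.260, 37),
    (39, "abdominal_aorta_d", 10.6, 0.620, 0.560, 37),
    (40, "inferior_mesenteric", 5.0, 0.160, 0.160, 39),
    (41, "abdominal_aorta_e", 1.0, 0.540, 0.525, 39),
    (42, "l_common_iliac", 5.8, 0.380, 0.350, 41),
    (43, "r_common_iliac", 5.8, 0.380, 0.350, 41),
    (44, "l_external_iliac", 14.4, 0.320, 0.290, 42),
    (45, "l_internal_iliac", 5.0, 0.200, 0.200, 42),
    (46, "l_femoral", 44.3, 0.259, 0.190, 44),
    (47, "l_deep_femoral", 12.6, 0.255, 0.186, 44),
    (48, "l_posterior_tibial", 32.1, 0.247, 0.141, 46),
    (49, "l_anterior_tibial", 34.3, 0.130, 0.130, 46),
    (50, "r_external_iliac", 14.4, 0.320, 0.290, 43),
    (51, "r_internal_iliac", 5.0, 0.200, 0.200, 43),
    (52, "r_femoral", 44.3, 0.259, 0.190, 50),
    (53, "r_deep_femoral", 12.6, 0.255, 0.186, 50),
    (54, "r_posterior_tibial", 32.1, 0.247, 0.141, 52),
    (55, "r_anterior_tibial", 34.3, 0.130, 0.130, 52),
]

NAMED_SITES = {
    "aortic_root": (1, 0.0),
    "brachial": (7, 0.5),
    "carotid": (5, 0.5),
    "thoracic_aorta": (27, 0.5),
    "abdominal_aorta": (39, 0.5),
    "femoral": (52, 0.5),
}

# Young-adult total arterial compliance target (conduit + peripheral).
C_TOTAL_30 = 4.5e-6 / MMHG  # m^3/Pa  (4.5 mL/mmHg)
R1_CAP_FRACTION = 0.5

# Resting regional flow shares (fraction of cardiac output) assigned to the
# terminal vascular beds: brain ~12% (3/4 via the internal carotids), each
# arm ~4%, kidneys ~18%, splanchnic ~22%, pelvis and legs ~23%.  Values are
# normalized at build time.
TERMINAL_FLOW_SHARES = {
    "r_vertebral": 1.5, "l_vertebral": 1.5,
    "r_internal_carotid": 4.5, "l_internal_carotid": 4.5,
    "r_external_carotid": 2.5, "l_external_carotid": 2.5,
    "r_radial": 1.6, "l_radial": 1.6,
    "r_ulnar_b": 1.6, "l_ulnar_b": 1.6,
    "r_interosseous": 0.4, "l_interosseous": 0.4,
    "intercostals": 3.5,
    "hepatic": 4.5, "gastric": 1.5, "splenic": 4.5,
    "superior_mesenteric": 10.0,
    "l_renal": 9.0, "r_renal": 9.0,
    "inferior_mesenteric": 2.0,
    "l_internal_iliac": 3.0, "r_internal_iliac": 3.0,
    "l_deep_femoral": 2.5, "r_deep_femoral": 2.5,
    "l_posterior_tibial": 3.5, "r_posterior_tibial": 3.5,
    "l_anterior_tibial": 2.5, "r_anterior_tibial": 2.5,
}


def _conduit_compliance_at_30(tree: ArterialTree, n: int = 64) -> float:
    """Integrated area compliance of all segments at P_ref, age-30 walls."""
    total = 0.0
    for s in tree.segments.values():
        d = s.diameters(n)
        ca = np.empty_like(d)
        for i, di in enumerate(d):
            law = calibrate_wall(np.pi * di * di / 4.0, pwv_from_diameter(di, 30.0))
            ca[i] = area_of_pressure(P_REF, law)[1]
        total += np.trapezoid(ca, dx=s.length / (n - 1))
    return float(total)


def build_reference_tree() -> ArterialTree:
    """Build and validate the packaged 55-segment systemic tree."""
    segments = {
        sid: ArterialSegment(id=sid, name=name, length=L * 1e-2,
                             diameter_prox=2 * rp * 1e-2, diameter_dist=2 * rd * 1e-2,
                             parent=parent)
        for sid, name, L, rp, rd, parent in SEGMENT_ROWS
    }
    tree = ArterialTree(segments=segments, terminals={}, named_sites=dict(NAMED_SITES))

    tpr30 = total_peripheral_resistance(MAP_TABLE_MMHG[30] * MMHG, CARDIAC_OUTPUT)
    leaves = tree.leaves()
    weights = np.array([TERMINAL_FLOW_SHARES[segments[l].name] for l in leaves])
    weights = weights / weights.sum()

    # (R1+R2)_i = TPR30 / w_i  ->  parallel combination == TPR30 exactly
    totals = {l: tpr30 / w for l, w in zip(leaves, weights)}

    # characteristic impedance of each terminal segment at its distal end
    for l in leaves:
        s = segments[l]
        d = s.diameter_dist
        A = np.pi * d * d / 4.0
        c = pwv_from_diameter(d, 30.0)
        zc = RHO_BLOOD * c / A
        r1 = min(zc, R1_CAP_FRACTION * totals[l])
        tree.terminals[l] = WindkesselTerminal(R1=r1, R2=totals[l] - r1, C=0.0, P_out=0.0)

    # distribute peripheral compliance ~ conductance
    c_conduit = _conduit_compliance_at_30(tree)
    c_periph = max(C_TOTAL_30 - c_conduit, 0.15 * C_TOTAL_30)
    g = np.array([1.0 / totals[l] for l in leaves])
    g = g / g.sum()
    for l, gi in zip(leaves, g):
        tree.terminals[l].C = c_periph * gi

    diags = validate_tree(tree)
    if diags:  # pragma: no cover - fixture is static
        raise AssertionError("reference tree failed validation: " +
                             "; ".join(str(d) for d in diags))
    return tree
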