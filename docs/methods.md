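# Methods

This note documents the model equations, the parameter choices that matter,
the calibration of the packaged arterial tree, and what the tests do and do
not demonstrate.

## Governing equations and numerics

Each arterial segment carries the 1-D mass and momentum balance

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂(Q²/A)/∂x + (A/ρ) ∂P/∂x = −2(ζ_v+2) π μ Q / (ρ A)

with blood density ρ = 1050 kg/m³ and viscosity μ = 4 mPa·s. The friction
term is the constant-velocity-profile approximation of pulsatile
(Womersley-type) wall shear; the profile coefficient defaults to ζ_v = 6,
inside the admissible range (2 = Poiseuille, ~9–11 = flat profile). It was
fixed during fixture calibration: larger values over-damp the brachial path
and suppress the peripheral amplification the model is meant to exhibit.
Frequency-dependent friction is out of scope.

The wall is Langewouters' arctangent law. Per grid node, with local diameter
d(x) from the linear taper, the two free parameters are closed from
(i) A(P_ref) = π d²/4 and (ii) Bramwell–Hill compliance matching
C_A(P_ref) = A/(ρ·PWV²) with PWV = a·(d in mm)^(−b) from the decade table,
under the convention P0 = P_ref = 100 mmHg (giving A_m = 2 A_ref and
P1 = 2ρ·PWV²/π). P0 = P_ref is not merely convenient: for the very compliant
young aorta of this parameterization no arctangent law with a physiological
low P0 (~40 mmHg) can reach the required compliance at 100 mmHg, so the
inflection is pinned at the reference point.

Wall viscoelasticity is a Voigt term P_visc = Γ ∂A/∂t. Substituting mass
conservation turns it into a diffusion of Q, which the solver integrates
implicitly (a tridiagonal solve per segment per step) — an explicit
treatment is unconditionally unstable at realistic Γ. The default relaxation
time Γ·C_A = 2 ms corresponds to a wall loss tangent of ≈0.1 at 8 Hz,
typical of arterial wall viscosity; it damps the 3–15 Hz standing-wave
resonances that would otherwise corrupt the characteristic-impedance
estimate. Setting `SolverConfig.wall_visc_tau = 0` recovers purely elastic
walls. Recorded pressures include the viscous wall stress.

Interior nodes advance with an explicit MacCormack predictor–corrector
(forward/backward differencing); Δx ≤ 2.5 mm, CFL = 0.9 with the time step
sized at a 170 mmHg / +2.5 m/s headroom state. Boundary nodes are closed
with linearized characteristic invariants P ± ZQ (Z = ρc/A frozen at the
local state, foot of the characteristic found by interpolation):

* junctions: flow conservation and static pressure continuity, solved in
  closed form (the linearized system is linear, so the junction residual is
  machine zero);
* terminals: implicit-Euler 3-element Windkessel;
* root: the elastance ventricle through the valve law, with the transvalvular
  relation solved semi-implicitly each step.

Runs start from a uniform 75 mmHg, zero flow, and advance whole cycles until
the monitored-site pressure change between consecutive cycles falls below
0.5 mmHg (default; at most 20 cycles). Analysis uses the final cycle
resampled to 1 kHz. Verified invariants: Poiseuille steady state within 2 %,
pulse transit at the calibrated wave speed within 2 %, Windkessel DC and RC
limits within 2 %, global mass closure < 0.5 % of stroke volume, grid
halving moves aortic SBP by < 1 mmHg.

## Heart and valve

E(t) interpolates E_ed → E_es through the double-Hill activation
E_N(t/T) with exponents m1, m2 and time constants τ1, τ2 expressed as
fractions of the cardiac period T. m2 = 27.4 and τ2 = 0.452 are the
standard constants of this family. The early-contraction pair was set to
m1 = 1.9, τ1 = 0.30 (from the commonly used 1.32/0.269): with the
steeper-rising default the ventricle ejects too impulsively against this
tree (peak aortic flow ≳650 mL/s), and the period-fraction normalization is
used because a systolic-time normalization of the same constants collapses
systole to ~0.16 s. Peak activation then falls at 0.40 T.

The aortic valve has opening fraction ζ with pressure-driven dynamics
(K_vo = 0.02, K_vc = 0.08 (Pa·s)⁻¹; closure faster than opening, otherwise
the model produces a −340 mL/s backflow spike at end-systole where ≈−60 mL/s
is physiological), effective orifice A_max = 3.2 cm² and inertial length
l_eff = 3 cm. Filling is a perfect mitral check valve with resistance
R_mitral from a constant venous pressure P_ven.

R_mitral is the one free cardiac parameter. It is calibrated per decade,
against the full 1-D model, so the ejected cardiac output equals the
prescribed 6.6 L/min (frozen values in `ageing.R_MITRAL_TABLE`;
`solver.calibrate_filling` re-derives them). This enforces the same closure
the study design assumes when it sets TPR = MAP/CO with an age-constant CO.
The printed decade values of P_ven are taken as given; the resulting
end-diastolic volume is then only approximately age-constant (≈190–200 mL),
consistent with the known ~10 % internal drift of that parameter set.

## The packaged tree and its calibration

Topology and branch dimensions follow the classic 55-segment systemic
table; aortic and carotid-branch calibres were revised to contemporary
young-adult MRI reference anatomy (ascending aorta 3.15 cm, arch 2.85–2.55,
descending 2.35→1.82, abdominal 1.32→1.05 cm, internal carotid ending at
3.2 mm). Terminal Windkessels are sized at build time: total terminal
resistance splits the age-30 TPR according to physiological resting regional
flow shares (brain 12 %, kidneys 18 %, splanchnic 22 %, legs 23 %, …); R1
matches the terminal segment's characteristic impedance (capped at half the
total); peripheral compliance is distributed proportional to conductance.

Two fixture constants were calibrated once against the young-adult operating
point of the decade study and then frozen: the total arterial compliance at
age 30 (4.5 mL/mmHg nominal at the reference pressure — 2.1 conduit + 2.4
peripheral; the pressure-dependence of the arctangent law and the R1 shield
make the *effective* buffering ≈2.5–3 mL/mmHg) and the distal-thoracic taper
that sets the dominant reflection site. These are stand-in choices for the
original study's unpublished tree; they, not the physics, dominate the
residual disagreement discussed below.

## What the decade sweep reproduces — and what it does not

With the frozen model, the six-decade sweep reproduces: brachial SBP within
2.5 mmHg at every decade (107.6→138.9 vs 109.7→141.3), aortic SBP within
5.5 mmHg (99.6→129.5 vs 97.7→129.8), MAP within 1.2 mmHg, cardiac output
within 0.3 %, central PP widening (28→59 vs 24→57), amplification falling to
1.19 (vs 1.21), late-life augmentation pressure ≈9 mmHg (vs 7.1), and the
age-30 forward-wave ratio 0.82 (vs 0.78).

Four indices sit outside their tolerance bands, all traceable to the
reflection phenotype of the stand-in tree rather than to the ageing rules:
the age-30 amplification (1.36 vs 1.57 — our central pulse is ~3 mmHg too
wide relative to the brachial one), the age-60 augmentation index (13.6 vs
18.1±4), the age-30 inflection time (123 vs 154 ms — young reflections
return ~30 ms early), and the forward-wave ratio at 80 (0.68 vs 0.83, i.e.
the ratio does not rise with age here although the absolute forward-wave
pulse pressure does grow from 23 to 40 mmHg). Extensive geometry and
terminal experiments could shift each of these individually but not jointly
with the pressure targets; the corresponding acceptance tests are left
failing rather than loosened.

## Analysis conventions

* Zc is the mean input-impedance modulus over cardiac harmonics in 3–15 Hz;
  harmonics with flow amplitude at the numerical floor are excluded.
* Wave separation acts on the pulsatile components (means removed), so the
  forward/backward pulse pressures are offset-independent and the
  reconstruction P_f + P_b = P̃ is exact by construction.
* The inflection point is found on a Savitzky–Golay-smoothed waveform
  (21 samples at 1 kHz, order 3): the first minimum of dP/dt between the
  early-systolic slope maximum and the peak; for late-inflecting (young,
  type C) waves the shoulder is sought on the falling limb instead and AP is
  reported with a negative sign. AP and AIx = 100·AP/PP are signed.
* n-RMSE normalizes the root-mean-square error by the mean of the reference
  series.
* All analysis runs at a uniform 1 kHz over exactly one period (exclusive
  right endpoint), so time averages are plain means and FFTs see one period.

## Problem sizes and determinism

The default discretization (Δx ≤ 2.5 mm) yields ≈3100 nodes and ≈5300 time
steps per cardiac cycle; a decade run converges in 8–11 cycles (seconds on
one CPU once the kernel is compiled). The solver path contains no random
numbers; repeated runs are bit-identical. The only stochastic component in
the package is the synthetic-waveform generator's optional measurement
noise, which is seeded.

## Known limitations

* The tree is a calibrated stand-in: per-site indices that depend on the
  detailed reflection pattern (AIx, inflection time, forward-wave ratio)
  carry the disagreements listed above.
* Constant-profile friction and Voigt viscoelasticity are first-order
  stand-ins for Womersley friction and the full viscoelastic kernel of the
  cited model family.
* No coronary, cerebral (beyond the extracranial vessels) or pulmonary
  circulations; no baroreflex; no gender-specific parameterization; geometry
  is age-invariant by design.
* The synthetic waveform generator produces two-component Gaussian waves for
  analysis-stack validation; it does not emulate measured waveform
  morphology, calibration drift, or movement artefacts, so passing those
  tests validates the algebra of the analysis chain, not its robustness to
  clinical data quality.
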