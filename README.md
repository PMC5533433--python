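# pulsatree

1-D pulse-wave propagation in an ageing human systemic arterial tree, with a
time-varying-elastance left ventricle coupled through an aortic valve, and the
pulse-wave-analysis stack used in clinical vascular-ageing studies.

## The problem

With age the proximal aorta stiffens, peripheral resistance rises, and the
left ventricle thickens. Central systolic and pulse pressure increase, pulse
pressure amplification to the arm is lost, and the augmentation index first
rises and then falls. Whether the reflected wave or the growing *forward*
wave drives this is a long-standing question in hemodynamics. This package
simulates that process mechanistically: one model of the systemic
circulation, re-parameterized per age decade (30–80 y), produces full
pressure/flow waveforms at named arterial sites, from which all the clinical
indices are computed.

## The model

* **Arterial tree** — 55 tapered elastic segments (aorta, arch vessels, arms,
  head, viscera, legs) with 3-element Windkessel terminals (R1–C‖R2). The
  packaged tree is frozen in `pulsatree.reference_tree`.
* **Wall law** — Langewouters arctangent pressure–area relation,
  `A(P) = A_m (1/2 + arctan((P−P0)/P1)/π)`, calibrated per node so the local
  pulse wave velocity obeys the decade's empirical inverse relation
  `PWV = a · d̄^(−b)` (d̄ in mm) through Bramwell–Hill
  `PWV² = A/(ρ C_A)`. An optional Voigt term `Γ ∂A/∂t` models wall
  viscosity.
* **Blood flow** — 1-D mass and momentum equations, integrated with an
  explicit MacCormack predictor–corrector; junctions and terminals are closed
  with linearized characteristics (mass conservation and static pressure
  continuity); constant-profile friction `f = −2(ζ_v+2)πμ Q/(ρA)`.
* **Heart** — Sagawa elastance ventricle `P_lv = E(t)(V−V0)` with a
  double-Hill normalized activation shape, mitral check-valve filling from a
  venous pressure, and an aortic valve with turbulence and inertance losses
  `Δp = B Q|Q| + L dQ/dt`, `B = ρ/(2(A_max ζ)²)`, `L = ρ l_eff/(A_max ζ)`.
* **Ageing** — per decade: Table of PWV coefficients (a, b), total peripheral
  resistance `TPR = MAP_target/CO` with CO fixed at 6.6 L/min, and the
  cardiac table (E_es, E_ed, P_ven, HR). Geometry never changes with age.
* **Analysis** — SBP/DBP/MAP/PP, input impedance `Z_k = P̂_k/Q̂_k` with
  characteristic impedance `Zc = mean |Z| over 3–15 Hz`, wave separation
  `P_f,b = (P̃ ± Zc Q̃)/2`, augmentation pressure/index and inflection time,
  pulse-pressure amplification, n-RMSE.

See `docs/methods.md` for assumptions, parameter choices and limitations.

## Worked example

```python
import pulsatree as pt

res = pt.simulate_decade(30)           # packaged tree, age-30 parameter set
ao  = res.records["aortic_root"]       # WaveRecord: t, P, Q, A over one cycle
br  = res.records["brachial"]

print(pt.pulse_indices(ao))
# PulseIndices(SBP=99.63, DBP=71.44, MAP=86.01, PP=28.19)
print(round(pt.pp_amplification(br, ao), 2), round(res.co_mean * 6e4, 2))
# 1.36 6.61
```

The run converges to a periodic state in ~10 cardiac cycles (a few seconds
after JIT warm-up). SBP/DBP/MAP are in mmHg at the aortic root; the second
line prints brachial-to-aortic pulse-pressure amplification and the emergent
cardiac output in L/min (the prescribed value is 6.6). The same sweep over
all six decades, with every derived index, is one call:

```python
sweep = {age: pt.simulate_decade(age) for age in (30, 40, 50, 60, 70, 80)}
table = pt.decade_summary(sweep)       # one row per decade, Table-style
```

or from the shell:

```sh
pulsatree age-sweep --out sweep_out            # writes decade_summary.csv
pulsatree simulate --age 60 --out run60        # one decade, per-site CSVs
pulsatree analyze --pressure p.csv --flow q.csv --hr 70
```

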