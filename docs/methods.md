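# Methods

## Scope and model

`fickflow` implements gas-exchange-based estimation of pulmonary blood
flow during VA-ECMO and an in-silico twin of the two-circuit bench rig
on which the method was validated.  The package is organized around
the chain: blood gas-content models → V̇/Q̇ normalization → modified
Fick flow estimators → shunt analysis → agreement statistics, with the
circuit simulator generating the measurement records that exercise the
whole chain.

## Blood gas contents

**O₂ content** is the classical linear formula
cO₂ = 1.36·Hb·sO₂ + 0.003·pO₂ [ml/100 ml], Hb in g/dl, sO₂ as a
fraction.  With Hb 9 g/dl, sO₂ 0.876 and pO₂ 50 mmHg it gives
10.9 ml/100 ml (venous); with sO₂ 0.995 and pO₂ 200 mmHg,
12.8 ml/100 ml (arterial at FiO₂ 0.5).

**CO₂ content** follows the Dash–Bassingthwaighte whole-blood
chemistry.  Per litre of blood,

* dissolved CO₂ = α_CO₂(T)·pCO₂ in the plasma (W_pl = 0.94) and
  red-cell (W_rbc = 0.65) water phases;
* bicarbonate by Henderson–Hasselbalch with pK′ = 6.1 in each phase,
  the intracellular [H⁺] set by a fixed Donnan ratio
  [H⁺]_pl/[H⁺]_rbc = 0.69;
* carbamino CO₂ on the four α-amino termini of hemoglobin, with
  competitive ionization (K₅ = 2.63·10⁻⁸ M deoxy, K₆ = 1.91·10⁻⁸ M
  oxy) and carbamate equilibria (K₂ = 2.95·10⁻⁵ deoxy,
  K₃ = 2.51·10⁻⁵ oxy), interpolated linearly in sO₂.  Deoxyhemoglobin
  binds more CO₂ — the Haldane effect — so content falls as sO₂ rises
  at fixed pCO₂.

Hematocrit is derived from the measured hemoglobin via a fixed MCHC of
34 g/dl, and mol → ml STPD conversion uses 22 256 ml/mol.  All
constants sit in a `DashConstants` dataclass and can be swapped.  The
model gives ≈ 44 ml/100 ml for normal arterial blood (pCO₂ 40, pH 7.4,
Hb 15) and ≈ 46 ml/100 ml at the bench's venous operating point (pCO₂
50, pH 7.28, Hb 9).  The bench study printed far higher venous/arterial
contents (68.4/59.9 ml/100 ml) without stating its unit convention or
implementation; no whole-blood model reproduces those numbers at the
printed pCO₂/pH, so they are not used as anchors.  Correctness is
instead checked against an independently coded single-file oracle of
the same published chemistry (`tests/dash_oracle.py`) on a 60-point
grid, and by round-trip inversion.

**Inversion.**  pCO₂ from content uses bracketed Brent root-finding on
[0, 200] mmHg (the content is strictly monotone in pCO₂, so the root
is unique; tolerance ~1e-12, round trips close to < 1e-6 mmHg).  Port
(pO₂, sO₂) pairs are recovered from O₂ content by inverting
1.36·Hb·S(pO₂) + 0.003·pO₂ with the Severinghaus (1979) dissociation
curve S(p) = 1/(1 + 23400/(p³ + 150p)).

## The normalization constant c

c = σ_CO₂ · R·T · (1 + K_c), K_c = 10^(pH − pK′), pK′ = 6.1,
R = 62.36 L·mmHg·mol⁻¹·K⁻¹, T absolute.  σ_CO₂ defaults to
0.0333 mmol·L⁻¹·mmHg⁻¹ — the CO₂ solubility of water at ~37 °C rather
than the plasma value 0.0307.  This choice is a deliberate calibration:
the validation study reports c = 10.4 [9.5–12.5] for venous pH
7.28 [7.24–7.36] at 36.8 °C, and the water-solubility value reproduces
that mapping at all three quantiles (10.40, 9.54, 12.37), whereas the
plasma value undershoots the whole range by ~8 %.  Both σ_CO₂ and pK′
are exposed as parameters.

## V̇/Q̇ normalization

f(V̇, Q̇) = ((V̇/Q̇ + c)/(1 + c)) · (Q̇/V̇) multiplies a gas-side V̇CO₂
measured at an arbitrary V̇/Q̇ to give the value at V̇/Q̇ = 1.  f is 1
at V̇ = Q̇ and strictly decreasing in V̇/Q̇.  The ECMO-side V̇CO₂ is
always normalized (its V̇/Q̇ is known clinically); normalizing the lung
side requires knowing the lung V̇/Q̇ and is what separates the
`vco2_gasnorm` method from the clinical `vco2_gas` condition.  The
lung-side factor uses the oxygenator blood flow, i.e. lung flow reduced
by the set shunt fraction, since only that flow exchanges gas.  The
constant c is recomputed from each record's venous pH (per-step rather
than baseline-frozen; with the simulator's buffered pH the two
coincide).

## Flow estimators

All four methods of the validation study are implemented on a common
measurement-record schema:

* `vo2_blood` — Q̇_ecmo × |q_lung·Δc_(LA−v)O₂| / |q_ecmo·Δc_(pm−v)O₂|;
* `vco2_gas` — gas-side V̇CO₂ ratio, ECMO normalized, lung raw;
* `vco2_gasnorm` — both sides normalized to V̇/Q̇ = 1;
* `vco2_blood` — blood-side V̇CO₂ ratio from the v−LA and v−pm CO₂
  content differences.

The blood-side methods use the record's measured circuit flows, as the
bench did with its inline flow meters; they are validation-context
methods and would be circular at the bedside.  Absolute values make
every estimator invariant to the production-vs-elimination sign
convention.  A pure content-difference estimator
Q̇_lung = Q̇_ecmo(Δc_(v−pm) − Δc_(v−ao))/(Δc_(v−ao) − Δc_(v−LA)) is
provided separately and rejects the degenerate case
Δc_(v−ao) = Δc_(v−LA).

## Circuit simulator

Topology: venous reservoir → parallel ECMO and lung circuits (the lung
one with a shunt bypass) → aortic mixing → metabolic chamber (CO₂ in,
O₂ out) → venous side.  Configuration defaults are the bench's baseline
conditions: 2000/500 ml/min ECMO/lung split (2500 total), lung sweep
fixed at 1500 ml/min, FiO₂ 0.5, Hb 9 g/dl, 36.8 °C, venous pH 7.28 and
arterial 7.39, venous pCO₂ target 50 mmHg, chamber V̇CO₂ 130 ml/min and
V̇O₂ 45 ml/min (the reported CO₂ production aim of 120–150 ml/min and
O₂ magnitudes), post-oxygenator pO₂ 200 mmHg.

**Forward CO₂ model.**  The rig's oxygenators are not mechanistically
modelled; instead each unit's elimination at V̇/Q̇ = 1 is a common
flow-proportional content drop δ, and at other ratios the measured
elimination is the reference divided by f(V̇, Q̇) — making the
normalization exactly self-inverting by construction.  Steady state of
the closed loop requires total elimination to equal the chamber input,
so δ is scaled to δ_eff = 100·V̇CO₂_chamber / Σ(q_i/f_i); equivalently,
the chamber CO₂ partitions over the units with weights q/f.  At the
baseline grid δ_eff ≈ 4–5 ml/100 ml, consistent with the configured
reference drop of 5 ml/100 ml that is used directly when no chamber
rate is given.  This scaling preserves every estimator property (the
common factor cancels in all ratios) and makes conservation exact:
V̇CO₂_lung + V̇CO₂_ecmo = V̇CO₂_chamber at every converged state.

**O₂ model.**  Oxygenator outflow is fully saturated at the configured
post-oxygenator pO₂; venous saturation follows from the chamber's O₂
removal through the mixing equations.  At the defaults this lands on a
venous O₂ content of ≈ 11.0 ml/100 ml and sO₂ ≈ 0.89, matching the
reported baseline (10.9 ml/100 ml, 87.6 %).

**Steady state.**  Fixed-point iteration on the venous contents with a
1e-9 ml/100 ml tolerance and a 10 000-iteration cap; the O₂ map is a
contraction (spectral factor q_lung·s/q_total < 1) and the balanced CO₂
map converges immediately.  Port blood-gas panels are recovered by
inverting the content models at each port's pH (venous pH at the venous
port, arterial pH post-oxygenator and aortic, flow-weighted mixture at
the left atrium), so an estimator recomputing contents from the panels
reproduces the simulator's contents exactly.  Degenerate inputs fail
loudly: over-ventilation that would drive a content negative raises
`OverVentilationError`; at 100 % shunt the stagnant post-lung sample
equilibrates with the CO₂-free sweep gas (content → 0) and all
lung-side exchange is zero.

**Protocol.**  Step 1a weans ECMO flow 2000→500 ml/min in 500-ml steps
with matched sweep (V̇/Q̇ = 1) and compensating lung flow; step 1b holds
the ECMO sweep at 1500 ml/min (V̇/Q̇ 0.75–3); both repeat at shunt 0, 20
and 40 %.  Step 2a transfers only 75 %/50 % of each weaned 500 ml to
the lung circuit (falling total flow); step 2b holds lung flow at
baseline (constant-RPM proxy for a failing pump); both at shunt 0.

**Noise.**  The exhaust capnometer's stated accuracy (±3.3 mmHg + 8 %
relative) is read as a 95 % bound: readings are perturbed with
zero-mean Gaussian noise of SD (3.3 + 0.08·pCO₂)/1.96.  Optional
blood-gas and flow-meter noise terms are available in the config and
off by default.  All noise flows through one seeded generator; a
protocol run is reproducible bit-for-bit from (config, seed).

**What the simulator does not emulate.**  Pulsatile flow, oxygenator
membrane physics, recirculation, temperature drift, pH drift across a
maneuver, and — deliberately — the bench's large discrepancy between
blood-side and gas-side V̇CO₂ (bias ≈ 50 ml/min), which the
investigators attributed to the red-cell-suspension perfusate and
content-model limits.  In this simulator blood-side and gas-side V̇CO₂
agree by construction, so passing tests demonstrate the internal
consistency of the method chain, not the field accuracy of blood-side
V̇CO₂ measurements.  Likewise the exact bench agreement numbers (bias
103 ml/min, LoA −306 to 512 ml/min) belong to undeposited laboratory
data and are not reproduction targets.

## Statistics

Bland–Altman: bias = mean difference, LoA = bias ± 1.96·SD, confidence
intervals from Var(bias) = SD²/n and Var(LoA) = SD²(1/n + z²/(2(n−1)))
with t(n−1) quantiles (the study brackets its bias/LoA values without
defining them; both CIs and raw ranges can be read from the output).
Least significant change = 1.96·√2·SD_within with the precision SD
pooled over conditions by degrees of freedom (multiplier exposed).
Proportional bias regresses the method difference on the pairwise
mean.  The V̇CO₂ model V̇CO₂ = β₀ + β₁Δc + β₂Q̇ + β₃ΔcQ̇ is ordinary
least squares via statsmodels with per-coefficient p-values; designs
with condition number > 1e10 are flagged collinear but still returned.
Two-tailed p < 0.05, no multiplicity correction.

## Numerical and design choices

* Exhaust pCO₂ → dry-gas fraction uses barometric 760 mmHg by default;
  a water-vapor mode (P_H₂O = 47 mmHg) is available because the
  conversion used on the bench is not stated.
* The capnometer's 200 ml/min side-stream draw is treated as
  non-consuming.
* Shunt estimates outside [0, 1] under noise are flagged, never
  clamped; the >1 % shunt exclusion filter is a reusable parameterized
  record filter.
* CSV output uses 12-significant-digit floats: a canonical text form
  that round-trips byte-identically while preserving the noiseless
  closure properties (< 1e-9 relative) through a file cycle.
* Problem sizes in the test suite (12-record protocol grids, 200-config
  conservation sweeps, 5 replicate noisy runs for Monte-Carlo checks)
  were chosen to keep statistical checks well-powered at desk scale.

## Known limitations

The CO₂ content model is a full-blood model applied to a simulated
red-cell suspension; the normalization constant's σ_CO₂ is calibrated
to the study's printed c-range rather than measured; lung V̇/Q̇
normalization needs the lung ventilation and shunt, which are exactly
the quantities that are uncertain clinically; and the simulator's
linear-drop oxygenator model cannot probe saturation phenomena (e.g.
incomplete hemoglobin saturation at low FiO₂) that would degrade the
V̇O₂ method in vivo.
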