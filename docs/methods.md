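# Methods

## Model structure

The system is a fixed five-species scaffold: two parallel cascades
`G1 → A → B → O` and `G2 → C → D → O` sharing the output `O`, with four
backbone activations (A→B, B→O, C→D, D→O) present in every module.
Nine registered topologies differ only in crosstalk:

| module | crosstalk | module | crosstalk |
|---|---|---|---|
| M0 | none (baseline) | M5 | B→C and D→A (mutual activation) |
| M1 | A→D | M6 | B⊣C (half strength) and D⊣A (mutual inhibition) |
| M2 | A⊣D | M7 | B⊣C and D→A |
| M3 | B→C | M8 | B→C and D⊣A |
| M4 | B⊣C | |

Arrows are activation (V = +0.4), bars inhibition (V = −1); all edges use
Michaelis constant K = 0.8. M6's mutual inhibition is deliberately
asymmetric — the downstream link D⊣A at full strength, the upstream link
B⊣C at half (V = −0.5) — so that one pathway dominates; the 0.5 ratio is a
package choice (only the ordering is constrained by the biology being
emulated) and is encoded in the registry, where it can be changed.

States are activation fractions: concentrations are non-dimensional with
total concentration normalized to 1, so `X_i ∈ [0, 1]`, and time is
non-dimensional. All simulations start from `X = 0`.

## Kinetics and the inhibition convention

Activating edges consume the inactive fraction `(1 − X_i)` with saturating
kinetics. For inhibiting edges the package's default is the
*deactivation* convention: the inhibitor acts enzymatically on the
*active* fraction, `V_ji·X_i/(g_i·K_ji + X_i)·X_j`. Writing the
inhibition term with `(1 − X_i)` saturation instead (the *literal* form,
available via `inhibition="literal"`) makes an inhibited species at
`X_i = 0` acquire a negative derivative, which has no meaning for an
activation fraction. Under the deactivation convention the derivative of
any species at 0 is nonnegative and at 1 is negative (the maximal input
`V_A/(K_A+1) ≈ 0.133` stays below the degradation rate `d = 0.2`), so
trajectories remain in `[0, 1]` without clipping; tests assert this
rather than enforce it.

## Drug action

A drug is a competitive inhibitor of its target's activation: dose `D` on
species *i* multiplies the Michaelis constants of *all* activation routes
into *i* — edge constants `K_ji` and, when the target is a receptor
species (A or C), the input constant `K_A`/`K_C` — by
`g_i = 1 + D/K_D` with `K_D = 0.1`. Including the receptor input in the
drug's reach is a deliberate choice: without it a drug on A or C would be
inert in every module lacking crosstalk into that species, which
contradicts the screen design where every species is a meaningful target.
Doses of multiple regimen entries sharing a target add inside `g_i`, so
"B combined with B" doubles the effective dose and a zero-dose entry is
exactly inert. The default regimen applies dose 1.0 from `t = 0` for the
whole horizon; dose, onset and target are configurable per entry.

## Stimuli

Stimulus profiles are piecewise-constant in time with amplitudes in
[0, 1]. The basic profile S0 is a unit pulse on `t ∈ [0, 30)` applied to
both channels. The variant library S1–S6 (sustained step, short pulse,
double pulse, staircase ramp, half-amplitude pulse, delayed pulse) is a
package-designed set for probing robustness of the resistance
classification to input shape; the staircase ramp stands in for a
continuous ramp because profiles are piecewise-constant by contract.
Only qualitative conclusions (which modules resist under a majority of
input shapes) should be drawn from the variant library.

## Numerics

Integration is classical fixed-step RK4, default `h = 0.01` over
`T = 100`. Because stimuli and drug schedules are piecewise constant,
their values are sampled once per step (at the step midpoint) and held
fixed across the four stages: each step then integrates a smooth system,
input breakpoints that coincide with grid points are handled exactly, and
the integrator keeps its fourth-order convergence across pulse edges
(stage-wise sampling of the discontinuity would degrade it to second
order and shift integrated outputs by ~1e−3). Consequences of the
midpoint convention: an input edge at time `t*` lying strictly inside a
step is smeared by at most one step, and a drug with `t_on` on a grid
point becomes active on the following step. The integrated output
`IO = ∫₀ᵀ O dt` uses the composite trapezoidal rule on the RK4 grid.
Halving `h` from the default changes states and IO by well under 1e−6.

## Indices and classification

RDE follows the definition in the README; it is exactly 0 for module 0
(self-comparison) and undefined when the untreated output integral is 0
(rejected rather than patched). For combinations, the module-0 baseline
term uses the *same combined regimen*, so the combination RDE is the
crosstalk-attributable part of the combination effect.

Bliss fractional reductions are taken positive,
`R = (IO_untreated − IO_treated)/IO_untreated`, which makes CI vanish
exactly at Bliss independence (remaining fractions multiply). The signed
variant (treated-minus-untreated ratio) is kept behind `signed_r=True`
for comparison; it scores two independent half-effective drugs at
CI = +0.5 and should not be used for classification. Labels use a
symmetric tolerance band of ±0.05 around 0 — synergy above, antagonism
below, additivity inside — absorbing ~5% perturbations; `tol=0` recovers
the pure sign rule. Increase/decrease calls between a combination and the
single anchor drug treat |ΔRDE| < 1e−9 as a tie.

## Screens and default conditions

* **Single-drug screen**: anchor drug on B, dose 1.0, S0 stimulus; RDE
  per module. Modules 1, 4, 6, 7, 8 come out resistant (RDE < 0) under
  the defaults; 2, 3, 5 respond better than baseline.
* **Combination screen**: anchor B paired with each of A, B, C, D (four
  arms per cell: untreated, anchor, partner, both). `partner_dose` may
  be set to 0 to verify the inert-partner degenerate case.
* **Strength scan**: the single-drug screen repeated over a crosstalk
  magnitude multiplier (default: 8 geometric points from 1 to 10; the
  multiplier scales crosstalk edges only). Under the defaults modules 4
  and 7 switch resistant→sensitive, module 5 sensitive→resistant,
  modules 1, 6, 8 deepen their resistance, module 2 strengthens its
  response and module 3 barely moves.
* **Stimulus scan**: the single-drug screen across the stimulus library,
  each variant applied to G1 alone, G2 alone, and both; a module is
  flagged "prone to resistance" when RDE < 0 in more than half the
  conditions (majority rule — a package choice). Under the defaults the
  flagged set is {1, 4, 6, 7, 8}, matching the single-drug screen.

All screens are deterministic: identical configs give bit-identical
result tables, which the manifest (config echo + hash + package version)
makes checkable after the fact.

## Known limitations

* The combination screen's synergy/antagonism labels are sensitive to
  the drug dose, which the default protocol fixes at 1.0 (`g = 11`). At
  this strong dose, cross-pathway pairs (B with C or D) are strongly
  super-multiplicative (CI up to ≈ +0.4) and same-pathway pairs
  redundant (CI down to ≈ −0.25), so few cells land in the additivity
  band; at smaller doses CI magnitudes shrink toward additivity while
  the increase/decrease directions are stable over a wide dose range.
  Dose–response surfaces are out of scope.
* The scaffold is fixed at five species and two pathways; arbitrary
  networks, SBML exchange, stochastic (Langevin) dynamics and delay
  terms are out of scope.
* Passing the stimulus-scan robustness check shows insensitivity to the
  shapes in the package's variant library, not to arbitrary physiological
  inputs.
* The tests exercise the default conditions at full resolution
  (`h = 0.01`) for the quantitative protocols and a coarser `h = 0.05`
  for qualitative sweeps, where the two grids agree to ≪ 1e−6.
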