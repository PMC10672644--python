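# Methods

## Model

A material point of bone is described by the bone volume fraction `v_b`
(porosity `p = 1 − v_b`) and the composition of the tissue itself: a fixed
organic fraction `v_o = 3/7`, a mineral fraction `v_m` that grows at the
expense of water (`v_m + v_o + v_w = 1`), and the ash fraction
`α = ρ_m v_m / (ρ_m v_m + ρ_o v_o)` as the scalar measure of tissue
mineralization.  Derived quantities: stiffness
`E = 84370 v_b^2.58 α^2.74` MPa, volumetric mineral density
`BMD = ρ_m v_m v_b`, material density `ρ_mat = ρ_m v_m + ρ_o v_o + ρ_w v_w`
and apparent density `ρ_app = ρ_mat v_b`.

Remodeling is driven by BMU population kinetics.  BMUs originate on the
free surface at rate `Ṅ = f_or · S_v(p)`, where `S_v` is Martin's quintic
`32.3p − 93.9p² + 134p³ − 101p⁴ + 28.8p⁵` (1/mm) and
`f_or = f_bio · ζ_ref/(ζ + ζ_ref)` is the biologically capped,
mechanically inhibited activation frequency.  The daily stimulus
`ζ = (Σ N_i ε_i^4)^{1/4}` uses uniaxial strains `ε = σ/E` of the habitual
load cases; the reference stimulus accommodates at rate φ
(`dζ_ref/dt = φ(ζ − ζ_ref)`).  The focal balance `f_bb(ζ − ζ_ref)` is the
mechanostat curve: `f_bb_min` in disuse, 1 inside the ±w dead zone,
`f_bb_max` in overload, linear in between, all scaled by κ_fbb(t).

**Window integrals.**  `N_BMU(τ)` in the formation/resorption integrals is
taken as the density of BMUs *active* at τ, i.e. the origination rate
integrated over the BMU lifespan `T_R + T_I + T_F` (the origination rate is
defined as a derivative, `dN_BMU/dt = f_or S_v`, so `N_BMU` is its running
integral over living units).  Daily rates are then

    v̇_r(t) = (A_BMU v_BMU / T_R) Σ_{τ ∈ [t−T_R, t)}              N_BMU(τ)
    v̇_f(t) = (A_BMU v_BMU / T_F) Σ_{τ ∈ [t−T_R−T_I−T_F, t−T_R−T_I)} N_BMU(τ) f_bb(τ)

with f_bb evaluated at the historical day τ (formation closes the packet
that was being refilled then).  This reading makes baseline turnover
`A_BMU·v_BMU·N ≈ 7×10⁻⁴/day` (≈ 25%/yr at transition-zone porosity) —
consistent with measured peri/postmenopausal porosity-change rates and
with the alternative reading (integrating the origination rate itself)
ruled out, since it yields ~0.25%/yr turnover, two orders of magnitude too
slow to produce any clinically relevant BMD trajectory.  The formation
window trails the resorption window by ≈ 62 days, which reproduces the
remodeling-space transient: any sustained rise in activation frequency
transiently removes bone before formation catches up.

**Layered mineralization.**  Tissue is a LIFO stack of layers; formation
pushes fresh osteoid (ash `α_0`) on top, resorption strips volume
youngest-first, digging into old, fully mineralized tissue only when
cumulative resorption exceeds the young surface volume.  Each layer
matures as `α(age) = α_max − (α_max − α_0) e^{−age/τ_sec}`.  Aggregation
is thickness-weighted, with `v_m` converted per layer so mineral volume is
conserved.  Adjacent layers closer than 30 days in age are merged
(thickness-weighted age), bounding the stack at a few hundred layers over
multi-decade runs; the merge error is second-order in (30 d/τ_sec)².

**Menopause and ageing.**  Both κ(t) channels are 1 before t₁ = −4 y,
ramp linearly to κ_perm at t₂ = +4 y, then drift at a constant per-day
slope, floored at 0.  The per-day slope convention is deliberate: per-year
slopes would make the postmenopausal drift negligible and the sustained
late decline of relative BMD would vanish.  The linear ramp is the
simplest monotone continuous shape consistent with purely permanent
changes.  Scenario tags (`none`, `fbio_only`, `fbb_only`, `combined`) mask
the non-varying channel to identity.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| ρ_m, ρ_o, ρ_w | 3.2, 1.1, 1.0 | g/cm³ | constituent densities |
| v_o | 3/7 | – | organic fraction of tissue |
| T_R, T_I, T_F | 24, 18, 64 | days | BMU phase durations |
| A_BMU | 2.84e-2 | mm² | BMU cross-section (model lineage; only the product A·v·N matters and calibration absorbs it) |
| v_BMU | 0.04 | mm/day | BMU progression speed |
| f_bio | 5.0e-3 | 1/(mm²·day) | max activation frequency |
| f_bb_min/max | 0.85 / 1.15 | – | focal-balance bounds |
| w, v | 1.5e-3 each | ζ units | dead-zone half-width, linear-zone width |
| m | 4 | – | cycle-weighting exponent |
| φ | 1.0e-4 | 1/day | accommodation rate (τ ≈ 27 y) |
| α_0, α_max, τ_sec | 0.45, 0.72, 1500 d | – | mineralization law (lineage values; normalized outputs are insensitive to the exact constants) |
| κ presets | fbio 1.489/3.654e-4 · fbb 0.793/−7.085e-5 · combined 1.230/1.610e-4 & 0.903/−4.452e-5 | –, 1/day | fitted κ_perm and ageing slopes per scenario |

Time base: Δt = 1 day, 365 days/year.  Explicit Euler for accommodation
(φ·Δt = 10⁻⁴, contraction factor 1−φΔt; matches the exponential to 0.05%
at t = 1/φ).

## Site-ensemble surrogate

The organ-scale strain field is replaced by five independent material
sites — v_b = 0.95, 0.85 (cortical), 0.60 (transition), 0.35, 0.20
(trabecular) with mass weights 0.35/0.25/0.15/0.15/0.10 — each loaded by
habitual stress amplitudes solved at initialization so the site is in
stimulus equilibrium (ζ = ζ_ref) at its starting composition.  The free
scale is the habitual strain level, set from locomotion physiology:
walking 1500 µε peak (5000 cycles/day) and stair-climbing 1800 µε
(500 cycles/day), giving ζ_ref ≈ 0.0132 so the dead zone spans ±11% of
the habitual stimulus.  Initial tissue age is 30 years (α within 3×10⁻⁴
of α_max), so the premenopausal state is a genuine fixed point: with both
κ ≡ 1 the 19-year femur-average BMD̄ drifts by under 0.1%.

Because every site keeps its own stress history, there is **no load
redistribution between sites**: when a weak site loses stiffness no other
site picks up its share.  Relative to a full organ-level solve this makes
the late postmenopausal decline steeper (the κ_fbb drift eventually drops
the balance curve's ceiling below break-even at every site
simultaneously), which compresses the spacing between threshold-crossing
times of different load scenarios.  Scenario comparisons should therefore
be read as orderings and approximate gaps, not calendar predictions.

Scenario analysis applies a load-factor step (0.7 / 1.0 / 1.3) at the time
of load change, default ToLC = 0 (the last menses), matching the framing
of activity change once menopause is reached; threshold-crossing runs
extend to +25 y so that slow branches are not censored at the default
+15 y horizon.

## Calibration

`fit_parameters` minimizes the mean squared error between femur-averaged
BMD̄ (interpolated to the observation times) and a relative-BMD series
normalized to its first value (making the fit invariant to overall
rescaling).  The search is deterministic: a coarse grid (κ_perm axes
linear; slope axes geometric from zero, since the drift's effect spans
orders of magnitude), two local grid refinements, then multi-start
Nelder–Mead from the refined incumbent and the best mutually distant
coarse basins, with a final restarted polish.  Bounds: κ_perm ∈ [1, 2]
(activation), [0.5, 1] (balance), |slope| ≤ 10⁻³/day with channel-fixed
signs.  On noiseless self-generated data the generating parameters are
recovered to numerical precision; under 0.5% observation noise the balance
channel is sharply identified while the activation channel — whose BMD̄
signature (remodeling space plus mineral dilution, a few percent) is
closest to the noise scale — carries the widest spread, especially in the
four-parameter combined fit.

## Synthetic observations

The generator runs the forward model under a known κ schedule, samples
femur BMD̄ every 0.5 y over [−4, 15] y (39 points, emulating
annual-to-biennial densitometry follow-up), adds i.i.d. Gaussian noise
(default SD 0.005 relative units), and renormalizes so the first
observation is 1.  It emulates the *shape* of longitudinal relative-BMD
curves — premenopausal plateau, accelerated transition, sustained
postmenopausal decline — but not real measurement physics: no
heteroscedastic DXA precision, no between-subject variance, no site
mismatch between forearm/spine/femur measurements, and the noise on the
renormalized first point induces a small common-scale shift that real
cohort averaging would not.  Passing recovery tests therefore demonstrate
estimator correctness under the stated noise model, not field performance
on clinical series.

## Numerical and degenerate-case choices

- The daily loop is a compiled (numba) kernel; a pure-Python step path
  built from the module-surface functions implements identical semantics
  and the two are cross-checked in the tests.  Runs are bit-reproducible.
- Histories are pre-filled with the equilibrium origination rate and
  f_bb = 1 (warm start), so simulations begin at steady state.
- Over-resorption beyond the available volume clamps the stack to empty
  with a warning; a site with no tissue is frozen at zero (disuse
  collapse) and keeps contributing zero to the femur average.
- Martin's published S_v coefficients leave a 0.2/mm residue at p = 1
  (coefficient rounding); the curve is used as published, the residue is
  under 5% of the peak.
- The osteoporosis threshold is reported at 3 decimals.  On the published
  rounded reference statistics the Mexican-American population computes to
  0.726 (the reference table prints 0.727, reachable only from unrounded
  source statistics); the non-Hispanic white and black rows compute to
  0.720 and 0.698 exactly.
- Annualized stage summaries of porosity use percentage points per year,
  (p(b) − p(a))·100/(b − a), over the stages [−4,0], [0,4], [4,15] y.

## Known limitations

- No inter-site load redistribution (see above) and no spatial geometry:
  density maps, trabecular connectivity and cortical thinning are out of
  scope.
- Exactly balanced turnover churns only the youngest surface layer of the
  LIFO stack, so turnover-driven demineralization is weaker than in models
  that mix resorption depth; the effect appears here through remodeling
  transients rather than at steady state.
- Only permanent (irreversible) κ changes are modeled; transient drug
  effects and microdamage are not.
- The isotropic stiffness law ignores anisotropy and Poisson effects.
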