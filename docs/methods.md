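# Methods

## Constitutive model

Uniaxial tissue response is described by Kilian's van der Waals network
model, a phenomenological rubber-elasticity model with finite chain
extensibility (limiting stretch λ_m) and weak global chain interactions
(parameter a). With stretch λ (λ = 1 undeformed), deformation function
D(λ) = λ − λ⁻², conformation measure Φ(λ) = ½(λ² + 2/λ − 3),
Φ_m = Φ(λ_m) and η = (Φ/Φ_m)^½, the nominal (first Piola) stress is

    f(λ) = G·D(λ)·(1/(1−η) − a·Φ^½)

and the strain-energy density W(λ) = −G{2Φ_m[ln(1−η)+η] + ⅔aΦ^{3/2}}
satisfies dW/dλ = f exactly (the implementation verifies this numerically
to ≤1e−5 relative error over randomized valid parameters). As a → 0 and
λ_m → ∞ the model reduces to the neo-Hookean stress G·D(λ); its
infinitesimal modulus is 3G, consistent with E = 2G(1+ν) at ν = 0.5.

Assumptions: incompressibility (ν = 0.5, fixed, not fitted — the standard
assumption for hydrated biological tissue), homogeneity and isotropy of the
punched sample, quasi-static loading, and uniaxial kinematics with
λ = 1 + ε in tension and λ = 1 − ε in compression (ε = engineering strain,
displacement over machine-measured initial height). All public stresses are
nominal (force over undeformed cross-section); whether a given commercial
fitting tool uses nominal or true stress internally for this model is
generally not documented, so this package states its convention explicitly
and uses it consistently for both generation and fitting.

Evaluation at η ≥ 1 raises `BeyondExtensibilityError` rather than returning
infinity: silently clamped or infinite residuals corrupt least squares, so
the fitting layer instead constrains λ_m away from the observed stretches.

## Test preprocessing

* Strain ε_i = |d_i − d_0| / h with h the initial sample height; stress
  σ_i = F_i / (π(d/2)²) with d the punch diameter (4 mm fetal, 8 mm adult;
  default heights 2.0 / 4.2 mm). Stress is sign-normalized positive in the
  loading direction.
* Start-of-contact: the machine establishes contact (≈1 mN threshold)
  while measuring sample height, so a recorded test is taken to begin at
  contact and `to_stress_strain` applies no trimming by default. For files
  that do include an approach phase, `contact_force_N=1e-3` trims to the
  first sample exceeding the threshold and re-zeroes displacement there;
  this truncates the sub-threshold toe (≲2.5 % strain at fetal stiffness),
  which is the unavoidable cost of threshold-based contact detection.
* Linear-regime bounds default to ε ≤ 0.15 in compression and ε ≤ 0.10 in
  tension (the regimes over which lung tissue responds linearly in the two
  modes); both are configurable. The OLS intercept is free — forcing a zero
  intercept would bias the slope whenever a small contact offset remains.
  At the default fetal parameters the secant OLS slope over ε ≤ 0.15 sits
  below 3G because the a-term softens the model's compression response
  before stiffening takes over; the slope-equals-3G identity holds in the
  ε → 0 limit.
* Rupture events are detected as interior local stress maxima with
  prominence above 50 Pa (default, chosen below the 100–200 Pa amplitude of
  observed local-failure drops so those are caught); raising the prominence
  can only reduce the count.

## Fitting procedure

`VanDerWaalsModel.fit` minimizes unweighted least squares on nominal stress
with scipy's trust-region-reflective solver:

* starting values G₀ = (linear-regime slope)/3, a₀ = 2,
  λ_m₀ = 1.05·λ_eq, where λ_eq is the tension-equivalent of the largest
  observed conformation measure (for compression data the constraint on λ_m
  acts through Φ, not λ itself);
* bounds G ∈ (0, 10⁶] Pa, a ∈ [0, 20] (nonnegative, as measured for lung
  tissue), λ_m ∈ [1.01·λ_eq, 10] — the lower bound guarantees η < 1 on
  every data point throughout the search;
* up to 5 seeded random restarts; the best solution by cost is kept, and a
  constant (zero-variance) curve raises `FitError` instead of a fit;
* standard errors from the Gauss–Newton covariance s²(JᵀJ)⁻¹; weighted
  losses are deliberately not the default (no defensible heteroscedasticity
  model for a single curve) — noise handling belongs to replication across
  samples.

Fits are per-sample; group values are means of per-sample fits (fitting a
mean curve instead is possible by averaging curves upstream, but per-sample
fitting keeps the between-sample variance available to the statistics).

## Ventilation physiology

ΔV/V = V_T/FRC; linear strain of a homogeneous sphere
ε = (1+ΔV/V)^{1/3} − 1; deformation velocity v = ε·L/t_insp. All
intermediates are carried unrounded, with rounding only at report
formatting (percent to one decimal, velocity to integer) — the standard
clinical figures only reproduce from the unrounded chain. Defaults: FRC
21.4 ml/kg, V_T 4–6 ml/kg, t_insp 0.20–0.27 s, L = 2 mm; the slow end of
the velocity range pairs the smallest strain with the longest inspiration
time and vice versa. For adult parameters (FRC 30 ml/kg, V_T 6 ml/kg,
t_insp 1–2 s) the same arithmetic gives ≈3.8–7.5 mm/min, slightly wider
than the conventionally quoted 3–7 mm/min; the package reports the
unrounded values and leaves the rounding convention to the caller.

## Ussing-chamber analysis

Units are fixed throughout: mV, Ω·cm², µA/cm², cmH2O. I_sc = V_te/R_te
(Ohm's law) converts with a factor 1000 from mV/(Ω·cm²) to µA/cm².

* QC: baseline R_te (pre-event mean) must strictly exceed 300 Ω·cm².
* Plateau: a sliding window (default 6 samples = 2 min at the 20 s
  current-clamp cadence) is stable when its OLS slope normalized by the
  window mean is below 0.01 per sample. "Stable plateau" has no canonical
  instrument definition, so both knobs are explicit parameters.
* Inhibitor deltas use plateau means, not single samples (noise
  robustness): delta = (last stable window before the event) − (last stable
  window after it), positive when the inhibitor reduces transport. The
  decomposition V_base = V_amil + ΔV_amil then holds identically, because
  both terms derive from the same two plateau means. Whether the
  amiloride-insensitive level should be a post-event plateau or a
  time-matched single value is an open convention; the plateau mean is used
  here and satisfies the additive relation either way.
* amil_max = (peak I_sc between basolateral amphotericin and basolateral
  amiloride) − (post-amiloride plateau), on voltage-clamp traces (5 s
  cadence).

## Statistics

Shapiro–Wilk per group, Bartlett across groups; two groups → Student's t
(Welch-corrected when Bartlett rejects at α = 0.05); more → ANOVA + Tukey
HSD under homogeneity, else Welch's ANOVA + Games–Howell. Stars: * p<0.05,
** p<0.01, *** p<0.001, strict. Groups with n < 3 or zero variance flag the
comparison as skipped. A Shapiro–Wilk rejection flags the result but does
not reroute to a nonparametric test — the protocol defines no such
fallback, and inventing one would change the analysis; the flag leaves the
judgement to the analyst. Welch's ANOVA and Games–Howell are implemented
in-package (Welch–Satterthwaite degrees of freedom, studentized-range
reference distribution) and are cross-checked against pingouin in the test
suite.

## Synthetic data

The mechanical generator emits force-distance records at the 2 ms machine
cadence for a constant crosshead velocity up to 50 % strain, whose
noiseless stress is exactly the van der Waals stress at the configured
parameters. It emulates: velocity-dependent compression stiffness
(shear-modulus multipliers per velocity, default ratios 1 : 1.678 : 2.879
for 1/7/70 mm·min⁻¹, the measured fetal-compression modulus ratios
2646 : 4441 : 7617 Pa), velocity-independent tension, multiplicative
Gaussian stress noise (default 5 %, heteroscedastic like the visually
growing spread of experimental curves; additive noise available), Poisson
rupture events as persistent 100–200 Pa step drops, and an optional
pre-contact approach phase. The electrophysiology generator produces
piecewise plateaus approached exponentially (τ = 60 s) and held exactly
once settled, additive Gaussian noise, per-clamp-mode cadence, and
configurable R_te per pressure group; cohorts add between-trace variability
in the plateau levels.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: viscoelastic creep/relaxation within a single
curve (rate dependence enters only across curves), slippage and detachment
artifacts, drift or spikes in electrode recordings, poroelastic fluid
redistribution, and between-animal covariance structure. Parameter-recovery
results therefore demonstrate estimator correctness, not robustness to
every laboratory artifact.

## Problem sizes and seeds

The test suite and the acceptance script use desk-scale problem sizes
chosen to keep Monte-Carlo error well inside the asserted tolerances:
200-point curves for recovery oracles, 20 noisy replicates for mean-G
recovery, cohorts of 5 curves per velocity, 30-trace Ussing cohorts, and
1000 replicates for the null calibration of the Tukey path (family-wise
starred rate asserted within a 3σ binomial band of 0.05). All randomness is
seeded explicitly; hypothesis property tests run derandomized.

## Known limitations

* Uniaxial, incompressible, isotropic idealization; no 3-D tensor
  formulation, no Mooney–Rivlin/Ogden alternatives, no true-stress variant.
* Rate dependence is represented phenomenologically (per-velocity modulus
  scaling), not by a viscoelastic constitutive law.
* The Games–Howell p-value relies on the studentized-range asymptotics;
  very small groups (n < 6) give conservative results.
* Plateau detection assumes monotone settling between events; oscillating
  traces may flag spurious plateaus at the tolerance boundary.
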