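# Methods

## Scope

`erythrosim` studies one question: how does the life span of circulating
red blood cells (RBCs) shape the total erythropoietin (Epo) concentration a
hemodialysis patient must sustain to hold hemoglobin at a target? It does so
entirely *in silico*, over a synthetic ("virtual") patient population whose
parameter distributions emulate published cohort statistics. No real patient
records enter the computation; nothing here fits the model to data. Iron
kinetics are deliberately absent — their effects are implicitly folded into
the effective marrow parameters.

## Virtual population

Each virtual patient is a parameter set: RBC life span L (days), endogenous
Epo (U/L), ESA half-life (hours), the half-effect Epo concentration θ for
apoptosis suppression (U/L), and a dimensionless maturation-velocity factor.
Patients are sampled independently; joint correlations in a real cohort are
unknown and are not modeled, which is the main caveat when reading
population-level spreads.

- **RBC life span** — truncated normal on [33, 137] d. The published
  statistics (mean 76, SD 21) describe the *post-truncation* sample, and
  because the range is asymmetric around the mean, naive truncation of
  N(76, 21) would bias the realized mean upward. The parent location/scale
  are therefore solved numerically (2-D Powell-hybrid root find on the
  truncated moments; accepted at 1e-6 relative accuracy; fitted parent
  ≈ N(74.2, 23.3²)). Sampling is by inverse CDF, so no draw can leave the
  range.
- **Endogenous Epo** — lognormal. The log-median is matched exactly
  (ln 15); the printed quartiles (10.2, 21.1 U/L) are slightly inconsistent
  with any single lognormal, so the log-SD is the least-squares compromise
  between the two quartile equations, σ = [ln(15/10.2) + ln(21.1/15)]/(2·z₀.₇₅)
  ≈ 0.539.
- **Unreported parameters** — no distributions are published for the
  remaining three, so configurable lognormal defaults supply plausible
  heterogeneity: ESA half-life median 20 h (log-SD 0.3, appropriate for
  long-acting agents), θ median 30 U/L (log-SD 0.4), maturation factor
  median 0.5 (log-SD 0.4). This heterogeneity is what produces the within-bin
  spread of required Epo; it is a modeling choice, not an estimate.

Every parameter draws from its own RNG substream spawned from the root seed
(fields in declaration order), so adding a parameter never perturbs the
draws of existing ones, and identical (n, specs, seed) reproduce a
population bit-for-bit.

## Mechanistic model

The erythroid hierarchy is reduced to the minimal structure that preserves
the biology that matters for the requirement question:

- stem influx S₀ (arbitrary cells/day) feeds a proliferating compartment
  amplified by exp(β·τ_p) over a fixed window (β = 0.7 /d, τ_p = 5 d);
- the CFU-E stage prunes the cohort by apoptosis over its residence
  τ_CFU = 6 d at the Epo-dependent rate α(E) = α_max·θ^h/(θ^h + E^h)
  (α_max = 0.35 /d, h = 2) — Epo's canonical role as a survival factor;
- circulating cells live exactly L days (rectangular survival), giving the
  closed-form steady state Hb(E) = κ·P(E)·L with
  P(E) = S₀·exp(β·τ_p − α(E)·τ_CFU).

Consequences relied on throughout: Hb is strictly increasing in E and in L,
so the requirement solver can bracket safely, and the steady state is exact,
so it serves as an oracle for the dynamic simulator. S₀ and κ enter only
through their product; κ is calibrated so a healthy-physiology reference
(L = 120 d, θ = 30 U/L) is normo-hemic (14 g/dl) at the cohort's median Epo
(15 U/L), and rescaling S₀ with recalibration changes nothing downstream.
Hematocrit is reported by the fixed rule-of-three conversion 3 %/(g/dl) —
an approximation, stated as such.

The dynamic simulator does explicit cohort bookkeeping on a uniform age
grid: each step a cohort of size P(E(t − τ_d)) · dt enters circulation,
where the marrow transit delay τ_d = τ_d0 / (1 + m·E/(E + θ)) (τ_d0 = 3 d)
shrinks with Epo via the patient's maturation factor m; cohorts age in
lock-step and exit at age L. The hemoglobin readout weights the oldest
(partial) age bin by its overlap with [0, L), so the standing total equals
P·L exactly at constant Epo regardless of whether dt divides L; raw
entering/removed/total counts are exposed on the trajectory so cell
conservation can be audited to round-off. Optional neocytolysis removes
cohorts younger than a cutoff (10 d) at an extra rate (0.05 /d) whenever
total Epo falls below a threshold (10 U/L); it is off by default and in the
headline analysis, which holds Epo constant at need.

"Required total Epo" is interpreted as a *constant total serum
concentration* held to steady state — consistent with expressing the
requirement and its increase over endogenous Epo in concentration units —
not as a reconstruction of any particular ESA dosing schedule. ESA
pharmacokinetics (superposed one-compartment decays with the patient's
half-life) are provided for dynamic experiments but do not enter the
headline computation.

## Requirement solver and summaries

The solver targets the midpoint (10.50 g/dl) of the window [10.49, 10.51]
and declares convergence on window membership. The root is bracketed by
doubling the upper endpoint from 1 U/L until the target is straddled or the
concentration cap (10,000 U/L) is reached, then polished with Brent's method
(xtol 1e-9 U/L). Patients who cannot reach the window below the cap are
non-achievers (`converged=False`, requirement reported as the cap) and are
excluded from summaries; the symmetric corner — hemoglobin above the window
already at zero Epo — returns a zero requirement and `converged=False`.
Under the default calibration neither corner occurs: all 6,659 default
patients converge.

Negative increases (endogenous Epo exceeding requirement, common at long
life spans) are clamped to zero for the density grid but retained raw in
the results table, since both readings are defensible. Life-span bins are
half-open [lo, lo + 10) aligned to multiples of 10 d; endogenous-Epo bins
start at 5 U/L with width 10. Box statistics use linear-interpolation
quartiles with the 1.5·IQR outlier fence; whiskers span the most extreme
non-outlier values. Grid cells are flagged included only at ≥ 25 patients.

## Phenomenological model

A deliberately abstract alternative with hematocrit as the only variable:
H(t) = ∫ p(C(s))·S(t − s) ds, with production linear above a concentration
threshold, p(C) = p₀ + η·max(0, C − θ_c), and a logistic survival kernel
S(a) = 1/(1 + e^{(a−L)/s_L}) encoding life span and its variability
(rectangular at s_L = 0, where the unstimulated steady state is p₀·L). The
convolution is evaluated by the trapezoid rule; with the rectangular kernel
the quadrature error is O(dt/L), so dt = 0.05 d keeps the closed-form check
within 0.1 %. The "duration of the response" property is measured as the
time for the dose-induced excursion to fall back within 5 % of its own
peak excess — peak-relative rather than baseline-relative, because the
baseline itself scales with L.

## Numerical choices and problem sizes

Steady-state quantities are closed-form, so the full 6,659-patient solve
takes ~2 s on one CPU. Simulator checks use dt = 0.25 d over 5 life spans
(transients vanish exactly after L + τ_d at constant Epo); the tolerance
against the analytic steady state is 1e-3 g/dl. The brute-force oracle for
the solver is a 2,000-point grid over [0, cap], agreement required within
one grid step. Population-trend checks use n = 2,000; generator moment
checks use the cohort size n = 6,659 with 3-standard-error bands.

## Limitations

- The mechanistic model is a minimal reconstruction, not a reproduction of
  any published multi-compartment erythropoiesis model; absolute Epo
  requirements depend on the chosen Hill parameters and calibration anchor,
  so only the *structure* of the results (monotonicity, trends, spreads) —
  not their absolute placement — should be compared across models.
- Parameters are sampled independently; real cohorts likely correlate life
  span with marrow responsiveness, which would reshape within-bin spreads.
- Rectangular RBC survival ignores life-span variability within a patient
  (the phenomenological module's logistic kernel gestures at it).
- Hemoglobin per cell is fixed; hematocrit is a fixed multiple of
  hemoglobin.
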