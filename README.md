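# erythrosim

Biomathematical analysis of how red-blood-cell (RBC) life span drives
erythropoietin (Epo) requirements in hemodialysis patients.

Anemia management in dialysis usually centers on Epo deficiency, but the
life span of circulating RBCs — dramatically shortened in uremia — is an
equally direct driver of the erythropoiesis-stimulating agent (ESA) dose a
patient needs. `erythrosim` quantifies that relationship over a *virtual
patient population*: thousands of simulated patients, each represented by an
erythropoiesis-related parameter set (an "anemia avatar"), whose parameter
distributions emulate those estimated for a large US hemodialysis cohort
(RBC life span 76 ± 21 d, range 33–137 d; endogenous Epo median 15 U/L,
quartiles 10.2/21.1 U/L; n = 6,659).

## The model

Epo suppresses apoptosis of the colony-forming unit–erythroid (CFU-E)
progenitors through a decreasing Hill function,

    α(E) = α_max · θ^h / (θ^h + E^h),

so the flux of new RBCs entering circulation after amplification over the
proliferative window τ_p and CFU-E residence τ_CFU is

    P(E) = S₀ · exp(β·τ_p − α(E)·τ_CFU),

strictly increasing in the total serum Epo concentration E. Circulating
cells survive to the patient-specific life span L and are removed abruptly,
giving the closed-form steady state

    Hb(E) = κ · P(E) · L        (κ calibrated so Hb = 14 g/dl at L = 120 d, E = 15 U/L).

For each virtual patient the package finds, by bracketing plus Brent root
finding, the **required total Epo** E\*: the constant concentration at which
steady-state hemoglobin lies in the target window 10.49–10.51 g/dl. The
population is then summarized as box-plot statistics of E\* per 10-day
life-span bin and as the mean required *increase* over endogenous Epo on a
(life span × endogenous Epo) grid, keeping only cells with ≥ 25 patients.

An age-structured dynamic simulator (maturation delay, optional
neocytolysis — removal of young RBCs at low Epo) verifies the analytic
steady state, and a separate phenomenological single-variable hematocrit
model reproduces the qualitative claim that a shorter life span yields a
lower hematocrit at equal ESA dose.

## Worked example

```python
import erythrosim as es

model = es.calibrate_kappa(es.ModelParams())
for L in (50.0, 100.0):
    p = es.PatientParams(patient_id=1, rbc_life_span=L, endogenous_epo=12.0,
                         esa_half_life=20.0, apoptosis_sensitivity=30.0,
                         maturation_factor=0.5)
    r = es.required_total_epo(p, model)
    print(f"L={L:.0f} d: required Epo {r.required_total_epo:.1f} U/L, "
          f"achieved Hb {r.achieved_hb:.3f} g/dl")
```

prints

```
L=50 d: required Epo 28.8 U/L, achieved Hb 10.500 g/dl
L=100 d: required Epo 12.6 U/L, achieved Hb 10.500 g/dl
```

— halving the RBC life span from 100 to 50 days more than doubles the Epo
concentration this patient must sustain to hold hemoglobin at target.

The full population analysis runs from the command line:

```sh
erythrosim all --n 6659 --seed 1 --out out/
```

which writes `population.csv`, per-patient `results.csv`, the per-bin
box-plot statistics `bin_summary.csv`, the density grid
`lifespan_epo_grid.csv`, and the effective config. On the default
population every patient converges, and the bin medians of required Epo
fall monotonically from ≈ 38 U/L in the 30–40 d life-span bin to ≈ 3 U/L in
the 130–140 d bin, with the spread within bins produced by inter-patient
heterogeneity in the other physiological parameters.

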