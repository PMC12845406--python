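# cyclopk

Population pharmacokinetics of cyclosporin A (CsA) in children and young
adults after renal transplantation, with a focus on how haemoglobin (HGB)
shapes drug exposure.

CsA is a narrow-therapeutic-index immunosuppressant dosed by therapeutic
drug monitoring (TDM): whole-blood troughs (C0, pre-dose) and 2-h
post-dose samples (C2) are titrated into period-specific target windows.
This package implements, end to end, the analysis such TDM data supports:

- **Structural model** — one-compartment disposition with first-order oral
  absorption (Ka fixed at 1.15 h⁻¹) and first-order elimination, evaluated
  in closed form at steady state.  Apparent clearance and volume follow

  CL/F = 15 · (WT/40)^0.89 · (1 − 0.00279·(HGB − 120)) · e^(η_CL + κ)  [L/h]
  V/F  = 71.1 · (WT/40)^1 · e^(η_V)  [L]

  with body weight WT in kg, HGB in g/L, log-normal inter-individual
  effects (η) correlated between CL and V, an inter-occasion effect (κ)
  on CL per sampling day, and proportional residual error.  Clearance
  falls as haemoglobin rises — plausibly erythrocyte binding: less
  haemoglobin, less cell-bound drug, faster apparent clearance.
- **FOCE-I estimation** (`cyclopk.fit`) — first-order conditional
  estimation with interaction: per-subject conditional modes by a damped
  Newton iteration (all subjects solved simultaneously on padded arrays),
  extended-least-squares objective from the first-order expansion around
  the modes, quasi-Newton outer optimisation on transformed parameters.
- **Stepwise covariate modelling** (`cyclopk.run_scm`) — forward inclusion
  p < 0.05, backward elimination p < 0.01, χ²-referenced ΔOFV, covariate
  correlation screening, and the 20%-over-the-range clinical-relevance
  convention.
- **Diagnostics** — CWRES, prediction-corrected VPC, nonparametric
  (subject-resampling) bootstrap, GOF plot set.
- **Exposure simulation** (`cyclopk.simulate_scenario`) — steady-state
  AUC/Cmin/Cmax for virtual cohorts under fixed-HGB scenarios, plus a
  target-range classifier for the TDM protocol.
- **Synthetic cohort generator** (`cyclopk.generate_cohort`) — the
  clinical dataset is not redistributable, so the generator emulates the
  study design (58 subjects, ~974 paired C0/C2 steady-state samples, one
  occasion per sampling day, covariate distributions to scale) and makes
  every stage testable.

## Worked example

```python
import cyclopk as c

fe, re = c.FixedEffects(), c.RandomEffectsSpec()       # final-model values
ds = c.generate_cohort(c.CohortConfig(seed=1), fe, re) # 58 subjects, 899 obs

res = c.fit(ds, c.FixedEffects(theta_cl=10, theta_v=50, theta_all=0.75,
                               theta_hgb=0.0),
            c.RandomEffectsSpec(omega2_cl=0.1, omega2_v=0.1, omega_clv=0.05,
                                pi2_iov=0.02, sigma_prop=0.2))
print(round(res.fixed.theta_cl, 2), round(res.fixed.theta_v, 1),
      round(res.fixed.theta_hgb, 5))
```

prints `14.48 68.4 -0.00289`: refitting the synthetic cohort from neutral
starting values recovers the generating typical clearance (15 L/h at
40 kg) and volume (71.1 L) within a few percent, and the haemoglobin
coefficient (−0.00279 per g/L) within 3% — sampling noise at 58 subjects,
not bias.  The same pipeline as numbered scripts:

```sh
python analysis/01_simulate_cohort.py --seed 1   # dataset -> results/cohort.csv
python analysis/02_fit_model.py                  # FOCE-I recovery table
python analysis/03_covariate_scm.py              # correlation screen + SCM
python analysis/04_diagnostics.py --n-boot 200   # CWRES, pcVPC, bootstrap
python analysis/05_hgb_scenarios.py --seed 1     # exposure scenarios
```

`03` retains HGB-on-CL alone (creatinine enters in the forward pass at
p ≈ 0.014 but falls in backward elimination at the 0.01 bar), and `05`
prints the scenario table: at matched weights and doses, a cohort at
HGB 120 g/L has a ~35–46% higher median trough than one at HGB 73 g/L,
while AUC and Cmax move far less — the trough, the quantity TDM actually
targets, is the exposure metric most sensitive to anaemia.

A `cyclopk` console command exposes the same steps
(`simulate-cohort`, `fit`, `scm`, `vpc`, `bootstrap`, `gof`, `scenario`,
`recover`); every stochastic subcommand requires `--seed`.

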