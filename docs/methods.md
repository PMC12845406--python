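# Methods

## Model

One-compartment disposition, first-order oral absorption, first-order
elimination, evaluated only at steady state: every observation in the TDM
design was drawn after at least three days of unchanged dosing, so the
closed-form steady-state superposition limit

C(t) = 1000·D·Ka / (V·(Ka−k)) · [e^(−k·t)/(1−e^(−k·τ)) − e^(−Ka·t)/(1−e^(−Ka·τ))],  k = CL/V,

replaces any dose-history bookkeeping (t is time within the dosing
interval, τ = 12 h under twice-daily dosing, D in mg, concentrations in
ng/mL — the ×1000 unit conversion lives in this one expression).  The
profile is τ-periodic, so the pre-dose trough is C(0).  When |Ka−k|/k
< 1e−8 the removable singularity is replaced by its analytic limit.
Maturation functions and multi-compartment disposition are out of scope:
the population is mostly past the age where CsA metabolic capacity
matures, and sparse C0/C2 sampling cannot inform peripheral compartments.

Individual parameters:

- CL/F = θ_CL·(WT/40)^θ_ALL·(1 + θ_HGB·(HGB−120))·exp(η_CL + κ_occ)
- V/F  = θ_V·(WT/40)^1·exp(η_V)

θ_CL = 15 L/h, θ_V = 71.1 L, θ_ALL = 0.89 (estimated; the V/F exponent is
fixed at 1), θ_HGB = −0.00279 per g/L, Ka = 1.15 h⁻¹ fixed (sparse
absorption-phase data cannot identify it; `ka_sensitivity` refits over a
user grid to show the primary estimates are insensitive).  The linear HGB
factor is validated at construction to stay positive over the supported
73–164 g/L range.  Written with its estimated sign, the factor is
(1 − 0.00279·(HGB−120)) — clearance decreases with haemoglobin — and over
the observed HGB range it spans a 22.45% relative change in CL/F
(denominator: the larger, low-HGB clearance).

Random effects: (η_CL, η_V) ~ N(0, Ω) with ω²_CL = 0.3491², ω²_V =
0.4305², covariance 0.136 (reported "%" variabilities are CV% =
100·√ω²; the proportional residual SD is 0.258).  The 0.136 is read as a
*covariance*, per its label; the implied CL–V correlation is ≈ 0.905 —
high, but biologically coherent (both parameters share bioavailability
F).  Inter-occasion variability: one κ ~ N(0, 0.1225²) per occasion on
CL, where an occasion is a sampling day (a C0/C2 pair, or a lone sample).

## Estimation (FOCE-I)

Per subject i with observations y, predictions f(η), η = (η_CL, η_V,
κ_1..κ_K) ~ N(0, Ω_i) (block-diagonal IIV ⊕ π²I):

1. Inner step — conditional modes η̂ minimise
   Σ_j [ln(σ²f_j²) + (y_j−f_j)²/(σ²f_j²)] + η'Ω_i⁻¹η.
   Damped Newton with analytic first derivatives of f and a floored
   second-derivative weight; all subjects iterate in lockstep on padded
   arrays (one numpy batch per iteration), which is what makes bootstrap
   and operating-characteristic replicates affordable.  Kappas for
   occasions without observations are never allocated.
2. OFV — with G = ∂f/∂η at η̂ and R = diag(σ²f(η̂)²) (residual variance at
   *individual* predictions — the interaction term),
   OFV_i = ln det(C) + e'C⁻¹e + n·ln 2π,  C = GΩG' + R,  e = y − f(η̂) + Gη̂.
   This is exact when f is linear in η.  The n·ln 2π constant is kept so
   the OFV is directly comparable to an exact −2 log-likelihood
   (quadrature oracle tests); ΔOFV between nested models is unaffected.
   Per-subject contributions are sorted before summing, making the OFV
   bit-identical under subject reordering.
3. Outer step — L-BFGS-B with finite-difference gradients on transformed
   parameters (log for θ_CL, θ_V, the IIV Cholesky diagonal, the IOV and
   residual SDs; identity for exponents and covariate slopes), in two
   stages: a fast stage with the inner gradient floored at 5e−7, then a
   restart with fully polished modes so the finite differences are clean
   near the optimum.  Ka and the V/F exponent are always fixed; any other
   parameter can be fixed by name (the no-HGB base model fixes θ_HGB = 0).
   Conditional modes are warm-started across outer iterations; `fit` is
   deterministic given data and initial values and never returns a point
   worse than its start.

%RSEs from a finite-difference Hessian of the OFV are available but
flagged approximate; the bootstrap is the primary uncertainty surface.

## Covariate search

Forward inclusion adds, one at a time, the candidate (linear, power or
categorical multiplier on CL or V; 1 df each) with the largest ΔOFV
significant at p < 0.05 (χ²₁); backward elimination then deletes any
included covariate whose removal worsens the OFV at p ≥ 0.01.  Candidate
fits warm-start from their parent model.  Subjects entirely missing a
candidate's covariate are excluded from that candidate's test only.
Collinear covariates (the correlation screen flags |r| ≥ 0.8 on
per-subject baselines; undefined for constants) are not auto-excluded —
competing candidates are compared in separate runs, as the analysis
scripts demonstrate with creatinine vs derived creatinine clearance.
Clinical relevance of an effect is 100·|f(lo)−f(hi)|/max(f(lo), f(hi))
over the covariate's observed range, with 20% as the conventional bar;
the max-denominator convention is what yields 22.45% for the HGB effect.

## Diagnostics

- **CWRES**: C^(−1/2)·e with the same per-subject C and e as the
  objective; on data simulated from the generating model they are
  standard-normal-like (mean ≈ 0, SD ≈ 1), which the suite asserts.
- **pcVPC**: observations and simulations are scaled by (bin-median
  population prediction / own population prediction); observed 5th/50th/
  95th percentiles are overlaid on 95% simulation bands (default 1000
  simulated replicates, fully vectorised).  Default bins are sample type
  (C0/C2) × post-transplant period (≤30, 31–90, >90 days) — the natural
  strata of a two-timepoint TDM design; continuous time bins are
  available via `time_bins`.  No correction beyond prediction correction
  is applied to either side.
- **Bootstrap**: whole subjects resampled with replacement (unstratified),
  each replicate refit from the original estimates; non-converged
  replicates are excluded and counted, >20% failures flags the result.

## Synthetic cohort

The generator emulates the study design so the pipeline is testable
without the clinical data (not redistributable): 58 subjects; weight
log-normal (median 39.65 kg, σ_log 0.5, truncated 9.8–103 kg — σ_log
chosen to match the reported dispersion after truncation); height tied
to log-weight (r ≈ 0.9) with the reported marginal moments; creatinine
log-normal (median 87 µmol/L, σ_log 0.55); creatinine clearance by the
bedside Schwartz formula 0.413·HT/(CREAT/88.4) (the 88.4 converts µmol/L
to the mg/dL the formula expects — without it the values are ~60-fold
off the reported scale); haemoglobin normal (118.33 ± 14.99 g/L,
truncated 73–164) evolving within subject as a stationary AR(1) across
occasions (ρ = 0.8 — labs drawn weeks apart are correlated but not
frozen; no within-subject covariate model is reported, so this is a
design choice).  Dosing is 5 mg/kg/day divided BID, rounded to 5 mg.
Sampling days per subject are Poisson (mean 9.3, clipped 3–33) allocated
across the three post-transplant periods in the reported 132:229:611
observation proportions; each day yields a C0/C2 pair with probability
0.8, else a single sample (C2 with probability 0.6), landing near the
974 observations and 471:501 C0:C2 split of the study; per-day sample
counts are not published, so these are calibrated choices.  Observations
are model predictions times (1 + ε).  The generator emulates design
only: no dose titration toward targets (the TDM feedback loop), no assay
censoring (values below the assay's 30 ng/mL quantification limit are
retained — the reported concentration minima imply the study did not
censor), no dropout, no genotype covariates.  Passing tests therefore
demonstrate correctness of the machinery under the study's design and
the model's own assumptions, not robustness to real-data pathologies
(model misspecification, adaptive dosing, censoring).

## Exposure scenarios

Virtual cohorts of 100 patients, WT ~ Normal(43.03, 9.89) kg truncated
above 5 kg (a 12-year-old cohort to scale), fixed HGB per scenario (73
vs 120 g/L), two occasions differing only by fresh κ draws, η sampled
once per subject.  Each subject receives 5 mg/kg *per administration*
every 12 h: the package dosed the scenarios at the level that reproduces
the observed simulated concentration scale — the within-interval peak at
2.5 mg/kg is bounded near 1.5 µg/mL for these volumes, below the
reported scenario peaks, so the full 5 mg/kg per dose is the only
consistent reading (`mgkg_per_dose` restores the divided-dose protocol
if wanted).  Per subject-occasion: AUC over one interval = 1000·D/CL
(exact identity), Cmin = C(0) (the periodic trough), Cmax = C(t*) with
the closed-form interior maximiser t* = ln[Ka(1−e^(−kτ))/(k(1−e^(−Kaτ)))]
/(Ka−k).  Summaries are medians with 5th–95th centiles.  Target-range
classification uses the TDM protocol windows (C0 150–200 / C2 1200–1400
in month 1; 100–150 / 800–1200 in months 2–3; 100–130 / 800–1000 after),
endpoints inclusive.

## Numerical choices and problem sizes

- Inner Newton: gradient tolerance 1e−9·(1+|obj|) with a 5e−7 absolute
  floor during optimisation and a full polish for reported values; ≤60
  iterations, Armijo backtracking, per-subject Levenberg damping and
  stall detection.
- Outer: L-BFGS-B, FD step 1e−5, default ftol 1e−9 (two-stage); SCM and
  bootstrap replicates use documented looser/tighter settings per use.
- Acceptance-scale experiments: parameter recovery at the study's own
  design (58 subjects, ~900 observations); SCM power at 58 subjects ×
  20 replicates; type-I calibration at 16 subjects × 200 replicates with
  a reduced random-effects model (IIV only) — the false-inclusion rate
  is a property of the test, not of the cohort size, and the small
  design keeps 400 refits affordable; bootstrap demonstrations at 12–58
  subjects with 10–200 replicates (1000 is the publication-scale
  default).
- Degenerate inputs: zero dose predicts zero; Ka→k handled by the
  analytic limit; variances → 0 shrink EBEs to zero smoothly; constant
  covariates yield undefined (not zero) correlations.

## Known limitations

- FOCE-I is an approximation; its OFV tracks the exact −2 log-likelihood
  to ~1–2% on this model (verified against adaptive Gauss–Hermite
  quadrature on small cases), but no SAEM/importance-sampling check is
  provided.
- The LRT χ² reference is asymptotic: at very small designs the
  forward-step false-inclusion rate runs slightly above nominal (≈7% at
  α = 5% in the 16-subject calibration), consistent with the usual
  small-sample behaviour of FOCE-based ΔOFV tests.
- The scenario AUC column follows analytically from the dose (AUC =
  1000·D/CL); under the 5 mg/kg-per-administration regimen it is
  therefore twice what the divided-dose protocol would give, and the two
  conventions cannot be reconciled within one regimen.
- Bootstrap and VPC treat the design as fixed; no stratification or
  adaptive-design correction.
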