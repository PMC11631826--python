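# Methods

## Scope

`petliv` implements, end to end, a local-instrumental-variable (LIV)
analysis of treatment-effect heterogeneity for an emulated target trial:
synthetic cohort generation with a preference-based instrument, trial
construction, marginal/personalised effect estimation, aggregation with
bootstrap inference, and selection-on-observables / linear-IV
comparators.  Everything is validated on synthetic data because the
motivating application (UK primary-care records) is licensed; the
generator is therefore a first-class, tested component whose ground
truth has closed form.

## Identification model

Potential outcomes `Y1, Y0`; treatment `D`; observed covariates `X_O`;
instrument `Z`.  Selection follows the latent-index model
`D = 1{P(X_O, Z) > V}` with `V ~ Uniform[0,1]` independent of
`(X_O, Z)`.  The usual IV conditions are assumed: instrument
unconfoundedness given `X_O`, exclusion, relevance, monotonicity (built
into the index by a strictly positive instrument coefficient) and SUTVA.
Under these, `MTE(x, v) = E[Y1 − Y0 | X_O = x, V = v]` equals
`∂E[Y | X_O = x, P = p]/∂p` at `p = v`, and personalised (PeT) effects
are conditional averages of the MTE over resistance values compatible
with each patient's covariates, instrument level and observed treatment.

## Synthetic data generator

One row per patient with cluster, region, index date, instrument,
treatment, nine baseline covariates, and an HbA1c-change outcome at week
52.  Key mechanisms:

- **Covariates.** Independent draws with marginals close to the
  published target population (age 61±12, baseline HbA1c 73±17
  mmol/mol, BMI 32.5±6.3, 40% female, ethnicity 87.5/9/3.5%); clipped
  normals.  Joint correlation structure is not emulated (not reported
  for the source population).
- **Instrument.** Each cluster gets a preference shift
  `α_c ~ N(0, spread)` on the probit scale.  The patient-level
  instrument is the cluster's realised tendency-to-prescribe: the
  fraction of second-line initiations choosing DPP4i in the 365 days
  strictly before the patient's own day zero (own prescription never
  counted; each cluster starts from a burn-in history so the window is
  never empty; windows with fewer than 5 events are flagged).  Because
  prescriptions feed back into later windows, the default instrument
  coefficient (2.0) is chosen so the feedback gain stays below one and
  cluster tendencies are stable; at the study scale (13,240 patients,
  160 clusters) the first-stage cluster-robust F is ≈1100–1600,
  matching the strong-instrument regime the method requires (benchmark
  F > 100).
- **Selection.** `D = 1{Φ(μ_D(x, z)) > V}` with `μ_D` linear in the
  instrument and standardised covariates (higher HbA1c → SU, higher
  BMI → DPP4i, consistent with the published case mix).
- **Effects.** `Y1 − Y0 = τ0 + τ_x·(x − x̄) + η` with
  `η = ρ_ess σ_gain Φ⁻¹(V) + √(1−ρ_ess²) σ_gain ξ`.  This is the
  minimal coupling that creates essential heterogeneity while keeping
  `Var(η) = σ_gain²` and a closed-form oracle
  `MTE(x, v) = τ0 + τ_x·(x − x̄) + ρ_ess σ_gain Φ⁻¹(v)`.
- **Confounding.** Baseline noise
  `ε0 = ρ_conf σ_y (−Φ⁻¹(V)) + √(1−ρ_conf²) σ_y ϑ`: correlating the
  untreated outcome with the pro-treatment selection shock biases naive
  OLS while leaving the instrument valid.
- **Missingness.** Follow-up HbA1c missing completely at random
  (default 31.8%, the published outcome-missingness rate) plus a
  measurement-date jitter that pushes a few follow-ups outside the
  ±90-day window; complete-case analysis is then unbiased by
  construction, matching the analysis strategy.
- **Determinism.** A single seed feeds named child streams (assignment,
  covariates, selection, prescribing, outcomes, missingness); repeated
  runs are byte-identical.

Defaults (`DGPConfig`): τ0 = −1.3 mmol/mol (the published headline ATE
scale), τ_x = {HbA1c: −0.08 per mmol/mol}, ρ_ess = 0.3, σ_gain = 4,
ρ_conf = 0.3, σ_y = 10.

**Oracle configuration** (`oracle_dgp`): for estimator validation the
instrument dominates selection (coefficient 4, cluster spread 1.0, so
the propensity traverses nearly all of (0,1)), there is no overt effect
modification, ρ_ess = 0.5 and σ_gain = 4 (true MTE `−1 + 2Φ⁻¹(v)`),
missingness and jitter are off, and σ_y = 3.  The low noise scale is a
deliberate oracle-design choice: the derivative of a cubic fitted to
50,000 points has a sampling SE roughly proportional to the residual SD,
and the validation tolerances target the estimator's systematic
behaviour, not its (well-understood) sampling noise.

## Estimation choices

- **Term sets.** Mains: age, sex, ethnicity (2 dummies), HbA1c, BMI,
  eGFR, SBP, DBP, diabetes duration.  Candidates: age², HbA1c²,
  HbA1c×{age, sex, BMI}, and instrument/propensity interactions with
  {HbA1c, eGFR, BMI, SBP, age}.  Selection uses a plugin-penalty LASSO
  (`λ = 2c√n Φ⁻¹(1−γ/2p)`, c = 1.1, γ = 0.1/log n,
  heteroscedasticity-robust loadings iterated from post-selection
  residuals) per stage on the standardised, forced-terms-partialled
  design; the final specification is the union of terms selected in
  either stage and is used identically in both stages.  Stage 1 uses a
  linear probability model for selection (the standard device for a
  binary left-hand side); estimation itself is probit.  Selection runs
  once on the full sample; bootstrap refits reuse the frozen term set.
- **Propensity.** Probit MLE via Fisher scoring (a lean implementation
  validated against statsmodels to 10⁻⁶; it exists because bootstrap
  and coverage studies need tens of thousands of fits).  Fitted values
  clipped to [10⁻³, 1−10⁻³]; separation raises an explicit error.
- **Outcome.** Gaussian identity-link least squares on covariate terms,
  an orthogonalised power basis in `p̂` of degree 3 (QR on the centred
  Vandermonde; the triangular transform maps derivative evaluations
  into the same basis, so the MTE is analytic, not numeric), and the
  selected `p̂ × x` interactions.  Degree 3 balances curvature against
  derivative variance; it is configurable.
- **PeT integration.** One shared vector of 1000 draws
  `u ~ Uniform(min p̂, max p̂)` for all patients.  The latent rule
  `D* = Φ⁻¹(p̂) + Φ⁻¹(1−u) > 0` is algebraically `u < p̂`; the
  implementation uses the sorted-draw prefix-sum form and a test pins
  the equivalence.  Sharing draws makes two identities exact to machine
  precision: per patient, the draw-weighted mixture of the two branch
  means equals the all-draw mean MTE; across patients, the mean of
  those mixtures equals the support-truncated ATE implied by the fitted
  curve.  A patient at the support edge with no qualifying draw falls
  back to the nearest draw (counted and reported).
- **Aggregation and inference.** ATE/CATEs are unweighted means of PeT
  effects over populations (target, trial-eligible, trial-ineligible)
  and subgroup strata (age, HbA1c, BMI, ethnicity, sex bands); strata
  under 10 patients are flagged.  Bootstrap: patients resampled with
  replacement within region × treatment strata, preserving stratum
  sizes; both stages and the integration re-run per replicate;
  intervals are `point ± t_{1−α/2,B−1}·SD` centred at the full-sample
  estimate (percentile intervals behind a flag); replicate failures are
  skipped up to 5%, then the run aborts.  Benchmark agreement uses a
  closed interval at the endpoints.
- **Comparators.** IPTW-RA: probit treatment model on covariates only
  (instrument deliberately excluded — it is not a confounder, and
  conditioning on an instrument amplifies bias), stabilised weights
  capped at 50 (truncations counted), fully treatment-interacted
  weighted outcome regression, recycled predictions; equals weighted
  g-computation exactly, which a test verifies by an independent route.
  2SLS: projection algebra with CR1 region-clustered errors and a
  first-stage F gate (< 10 flags weak).  Wald-LATE: two-group ratio
  with a delta-method SE.

## Target-trial conventions

- Week 52 anchored at day 364; follow-up accepted within ±90 days,
  otherwise the outcome is missing.  (The ±90-day window is anchored at
  day 364; anchoring at 365 would change almost nothing and the anchor
  is configurable.)
- Baseline HbA1c must be measured within 180 days before day zero;
  blood-pressure/renal measures within 540 days.
- Benchmark-trial eligibility: age and baseline HbA1c inside [18, 78]
  and [44, 87], bounds inclusive (the reference trial excluded "over
  78" and "> 87"); rows with missing age/HbA1c are indeterminate and
  belong to neither stratum.
- Subgroup bands are lower-inclusive/upper-exclusive except terminal
  bands; values outside all bands (BMI < 15) get an explicit
  out-of-range label.
- Intention-to-treat: `D` is the day-zero prescription; switching is
  out of scope.

## Validation studies and their scale

The test suite recomputes, per run: closed-form MTE recovery (one
n=50,000 oracle cohort, tolerance ±0.5 mmol/mol at v ∈ {0.2, 0.5,
0.8}); ATE recovery (50 replicates at n=10,000, mean within 0.3 of
truth); the homogeneous limit (8 replicates at n=20,000 per estimator);
the LIV-versus-2SLS sign test under ρ_ess = 0.6 (50 paired replicates);
bootstrap coverage (150 simulated datasets, B=149, n=5,000, coverage
within [90%, 99%]); and the exact identities.  Replicate counts are the
package's chosen simulation scale: large enough that binomial/Monte
Carlo error is small against each tolerance, small enough that the
whole suite runs in minutes on one CPU.

## What passing tests do and do not show

The generator produces independent covariates, a correctly specified
probit index, linear outcome models and MCAR missingness.  Passing
recovery tests therefore demonstrates internal correctness of the
estimator chain under the identification assumptions — not robustness
to misspecified functional form, informative missingness, instrument
invalidity (exclusion violations are untestable and not simulated), or
correlated case mix.  LIV estimates target the support-truncated ATE;
with the oracle instrument the propensity support is nearly (0,1) and
the truncation gap is ≲0.05 mmol/mol, but with weaker instruments it
grows and is a genuine feature of the method, not a bug.

## Known limitations

- Two drug classes only; multi-arm marginal effects are out of scope.
- No repeated outcome measures, adherence modelling or drug-code
  dictionaries; the cohort schema is an analysis-ready abstraction.
- The rigorous-LASSO tuning constants follow the standard plugin
  recipe; they are exposed but not data-driven.
- Bootstrap replicates refit both stages but not the LASSO selection,
  so the intervals condition on the selected specification.
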