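# Methods

This note documents the models, numerical choices and limitations of
`cipropk`, a population-pharmacokinetic (popPK) pipeline for intravenous
ciprofloxacin in critically ill adults.

## Structural and statistical model

Drug disposition is a mammillary two-compartment model with zero-order
(constant-rate) infusion input into the central compartment, parameterised by
clearance CL (L/h), central volume Vc (L), peripheral volume Vp (L) and
inter-compartmental clearance Q (L/h).  All concentration–time curves are
closed form: the bolus macro-coefficients follow from the disposition
exponents α > β (the negated eigenvalues of the 2×2 rate matrix), the
infusion solution from integrating them over the infusion window, multi-dose
profiles from superposition, and steady state from the geometric
accumulation factor.  The closed forms are verified in the tests against
stiff ODE integration to 1e-6 relative accuracy.

Between-subject variability is log-normal: for subject *j*,
`P_j = P_pop · Π_k m_k(cov_jk) · exp(η_Pj)` with `η ~ N(0, Ω)`.  The default
("reference") model places a full 2×2 Ω block on (CL, Vc).  Variability is
reported as `CV% = 100·√ω²`, the common pharmacometric approximation — under
this convention the reference CV values 67.8% and 51.0% map directly to
ω = 0.678 and 0.510.  The CL–Vc covariance of the reference model is not
published; the package defaults to correlation 0.5 (configurable), which
affects only the realism of simulated cohorts, not any recovery target.
An optional diagonal η on Q (default CV 30%) reflects an ambiguity in the
source analysis, which described IIV on Q during model building but reported
final variability only for CL and Vc.

Residual error is combined proportional + additive on the concentration
scale: `y = f·(1+ε_p) + ε_a`, `ε_p ~ N(0, σ_p²)`, `ε_a ~ N(0, σ_a²)`;
reference values σ_p = 0.153 (15.3%) and σ_a = 0.143 mg/L.

Covariate effects are multiplicative and composable: continuous covariates
enter as powers normalised to the population median,
`(cov/cov_m)^θ_cov`, binary covariates as multipliers `θ_cov^cov`.

## Estimation (FOCE-I-style Laplace)

The marginal likelihood integrates the residual model over each subject's
η.  The package approximates it with a Laplace expansion at the
empirical-Bayes mode η*, with the residual variance evaluated at the
individual predictions (the "interaction"):

```
-2 log L_i ≈ g(η*) − d·log 2π + log det H(η*)
g(η)  = Σ_j [log 2π v_j + (y_j − f_j)²/v_j] + η'Ω⁻¹η + log det 2πΩ
v_j   = (σ_p f_j)² + σ_a²
```

H is the Gauss–Newton (expected-information) curvature of g/2, which is
positive definite by construction.  With Ω = 0 the expression reduces to the
exact Gaussian −2 log-likelihood (extended least squares); this exact case,
and dense 2-D Gauss–Hermite quadrature of the true marginal on a small
cohort, serve as independent oracles in the test suite (the quadrature
agrees within 0.5 OFV units on a two-subject dataset).

Numerical choices:

* **Inner problem.** Per-subject Newton iteration from η = 0 with
  finite-difference Jacobians of f (step 1e-4), step-halving line search,
  and a step-norm cap of 3.  Cold starts are deliberate: the joint density
  can be multimodal in η, so warm-starting across outer iterations makes
  the objective path-dependent; from a cold start it is a pure function of
  the parameters, which keeps finite-difference outer gradients consistent.
  During the outer search the inner solve uses forward differences and a
  relaxed convergence gain (3e-6); reported OFV, EBEs and curvatures are
  recomputed at full precision (gain 1e-9, central differences).  The
  per-subject iteration is JIT-compiled (numba) with a pure-numpy fallback.
* **Outer problem.** Fixed effects and residual SDs on the log scale, Ω via
  its Cholesky factor (log diagonal).  Default optimiser: Nelder–Mead
  followed by an L-BFGS-B polish (finite-difference gradients, step 3e-4);
  a warm-start-friendly `method="bfgs"` is used inside bootstrap and
  replicate studies.  An abnormal L-BFGS line-search exit at the numerical
  noise floor is treated as convergence.
* **Standard errors.** Inverse observed information from a central-difference
  Hessian of the OFV in the transformed parameters, delta-method-propagated
  to the reported scales; RSE% = 100·SE/estimate.
* **Shrinkage.** η-shrinkage `100·(1 − SD(η*)/ω)` per dimension;
  ε-shrinkage `100·(1 − SD(IWRES))`.
* **BLQ.** Observations below the assay limit of 0.04 mg/L are discarded
  with a logged count (M1).  Fitting always conditions on the recorded dose
  history; steady-state shortcuts are used only in exposure/PTA computations.

## Covariate search

Greedy forward inclusion (the best candidate per round is added when it
drops the OFV by ≥ 3.84, the χ²₁ 95% quantile) followed by one-at-a-time
backward elimination (an effect is retained only if its removal raises the
OFV by > 10.83, the χ²₁ 99.9% quantile).  Ties go to the earlier candidate;
non-converged candidate fits are skipped with a warning.

Calibration, measured by simulation under the null: the realised type-I
error of the forward step is ≈ 6.5% for cohorts of the default size
(42 subjects, 200 replicates) but inflates for very small cohorts (≈ 7.5%
at 24 subjects, ≈ 12% at 12) — the familiar anti-conservatism of
approximate-likelihood ratio tests in sparse nonlinear mixed models.  Users
running covariate searches on substantially smaller cohorts should expect
more false inclusions than the nominal 5%.

## Model evaluation

* **Bootstrap.** Subjects resampled with replacement (optionally stratified
  by dosing interval), each resample refitted from the point estimates;
  failures counted and excluded, the result flagged if more than half fail.
  Percentile 95% intervals.
* **VPC.** Replicate datasets simulated with the original design; per
  time-after-dose bin, the observed median/5th/95th percentiles are overlaid
  on the simulated 95% confidence intervals of those percentiles.  Default
  bins follow the sparse template (peak just after end of infusion, two
  mid-interval bins, troughs), anchored at the median infusion duration; no
  prediction correction by default.  Under the generating model the observed
  median falls inside its simulated interval in 95.0% of bins (30 replicate
  cohorts × 4 bins).
* **NPDE.** Standard decorrelation algorithm: per subject, simulated vectors
  are mean-centred and whitened with the inverse Cholesky factor of their
  empirical covariance (ridge-regularised with a warning if singular); each
  whitened observation's percentile among its whitened simulations — with
  midpoint tie handling, so an observation at the simulated median maps to
  exactly 0.5 — is transformed by Φ⁻¹, after clipping to
  (1/2K, 1−1/2K).  A D'Agostino normality test summarises the result.
* **GOF.** PRED (η = 0), IPRED (η = η*), IWRES, and CWRES from a first-order
  linearisation around η*: `CWRES = L⁻¹(y − f(η*) + Gη*)` with
  `LL' = GΩG' + diag(v)`.

## Target attainment

Exposure metrics are free-drug quantities using an unbound fraction
f_u = 0.7 (average plasma protein binding 30% in this population):
`fAUC₀₋₂₄ = f_u·(24/τ)·D/CL` exactly under linear kinetics, fCmax the
steady-state concentration at end of infusion (the profile maximum for an
IV infusion, verified by brute-force grid search), fCmin the end-of-interval
trough.  Targets: fAUC₀₋₂₄/MIC ≥ 100 (efficacy) and fCmax/MIC ≥ 8
(resistance suppression), compared inclusively.

`simulate_pta` draws n virtual individuals (default 5000) from the
population model, computes their exposure closed-form, and reports the
attained fraction on a doubling-dilution MIC grid (0.0312–8 mg/L).
Confidence bands are normal-approximation intervals of 20 batch means; the
published simulation platform's band construction is not described, so this
is the package's own choice.  Because fAUC depends on CL alone, the
fAUC-target PTA has the exact form `Φ(log(f_u·D₂₄/(100·MIC)/CL_pop)/ω_CL)`,
used as the oracle for the Monte Carlo engine (agreement within 2 SE across
the grid at n = 5000).  `typical_attainment` additionally reports whether
the typical-value exposure curve meets the target — some simulation
platforms describe dose requirements "on average", which corresponds to this
curve rather than to a population percentile, and the two can differ
markedly when variability is high (ω_CL ≈ 0.68 here).

## Synthetic cohorts

The generator emulates the study design end to end: 42 subjects split
3/25/14 across 400 mg q24h/q12h/q8h, 0.5-h infusions (the source protocol
allowed 30–60 min; no assignment rule was given), full dose history from
treatment start, and five samples in the day-2 interval — pre-dose trough,
a peak drawn uniformly 0.25–0.5 h after the end of infusion, 1 h and 3 h
post-infusion, and the next trough.  Continuous covariates are log-normal
matched to the published medians and IQRs (BMI's published spread reads as
a min–max range and is fitted as a wide log-normal spanning ±1.96 SD); sex
is 25:17 male:female and renal replacement therapy 10/42.  An optional flag
re-centres eGFR per dose group (28/52/82.5) to reproduce the study's
dose-by-renal-function confounding; it is off by default.  Observations get
combined residual error and are censored below 0.04 mg/L (M1), so the
default 210 samples typically shrink by a handful, matching the scale of
the published 204.

What the generator does **not** emulate: assay drift, time-varying renal
function or covariates, informative dropout, inter-occasion variability,
and real-data model misspecification (the fitted model family is the
generating family).  Passing recovery tests therefore demonstrate that the
estimator recovers the truth under the study design — not that the model is
correct for any particular clinical dataset.

## Problem sizes used in the shipped checks

Parameter recovery fits one default 42-subject cohort; diagnostics use 500
simulation replicates; PTA oracle comparisons use 5000 virtual subjects;
bootstrap examples use 20–200 resamples; LRT calibration uses 200 null
replicates at the study size and 20 powered replicates at 100 subjects.
These sizes give each check enough resolution to detect the failures it is
aimed at while keeping the full suite quick to run.

## Known limitations

* The Laplace/FOCE-I objective differs from other implementations by
  additive constants and approximation details; OFVs are comparable within
  this package only (all acceptance is via parameter recovery, never OFV
  matching).
* Under the sparse 5-sample design at n = 42, Vc (and to a lesser degree
  Vp, Q) carries large sampling variance (log-scale SD ≈ 0.24 for Vc) and a
  small upward finite-sample bias; CL is recovered tightly.
* M1 discarding of BLQ troughs slightly biases the terminal phase for the
  once-daily group.
* The terminal half-life implied by the reference typical values is 7.8 h;
  cohort-average individual half-lives (a different summary) will differ.
* No inter-occasion variability, mixture models, or SAEM-type estimation.
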