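# cipropk

Population pharmacokinetics and target attainment of **intravenous
ciprofloxacin in critically ill (ICU) patients**, as a tested, reusable
Python pipeline.

ICU patients handle antibiotics very differently from healthy adults —
shifted volumes of distribution, altered clearance, and large unexplained
between-patient variability — so fixed "one-dose-fits-all" ciprofloxacin
regimens often miss the pharmacodynamic targets that predict cure
(ƒAUC₀–₂₄/MIC ≥ 100) and resistance suppression (ƒC_max/MIC ≥ 8).  This
package implements the full workflow used to quantify that problem:

* **Two-compartment IV-infusion kinetics**, fully closed form (superposition
  over the dose history and steady state via the accumulation factor), with
  free-drug exposure metrics (ƒAUC₀–₂₄ = 0.7 · D₂₄ / CL, ƒC_max, ƒC_min).
* **Nonlinear mixed-effects estimation** (FOCE-I-style Laplace
  approximation): log-normal between-subject variability
  `CL_j = CL_pop·exp(η_CL)`, `η ~ N(0, Ω)` with a CL–Vc covariance block,
  combined proportional + additive residual error, OFV = −2 log-likelihood,
  relative standard errors, empirical-Bayes etas and shrinkage.
* **Stepwise covariate modelling**: forward inclusion at ΔOFV ≥ 3.84
  (χ²₁, p < 0.05), backward elimination retaining only ΔOFV > 10.83
  (p < 0.001), with power-law continuous effects normalised to the
  population median and binary multipliers.
* **Model qualification**: nonparametric bootstrap, visual predictive
  checks, normalised prediction distribution errors (NPDE), and
  goodness-of-fit residuals (PRED/IPRED/IWRES/CWRES).
* **Monte Carlo probability of target attainment (PTA)** over a
  doubling-dilution MIC grid (0.0312–8 mg/L) with 95%/99% confidence bands,
  plus a closed-form log-normal oracle for the ƒAUC target.
* **A synthetic ICU-cohort generator** that emulates the study design —
  42 subjects split 3/25/14 across 400 mg q24h/q12h/q8h, five samples in a
  day-2 dosing interval, covariates drawn from the published cohort
  marginals — so the entire pipeline is testable end to end without any
  patient data.

The packaged reference model carries the published final estimates
(CL 25.4 L/h, Vc 91.1 L, Vp 164 L, Q 91.9 L/h; IIV 67.8%/51.0% on CL/Vc;
proportional error 15.3%, additive 0.143 mg/L).

## Worked example

Simulate a cohort at the reference truth, fit it, and compute PTA for
400 mg q8h (1200 mg/day):

```bash
$ cipropk generate --seed 1 --out cohort.csv
wrote 42 subjects, 206 observations -> cohort.csv

$ cipropk fit --data cohort.csv --out fit.json
OFV 205.24 converged=True
  CL  =   26.645
  Vc  =  120.174
  Vp  =  189.411
  Q   =   92.324
  IIV CL = 62.6%
  IIV Vc = 48.0%

$ cipropk pta --dose 400 --interval 8 --n 5000 --seed 1 --out pta.csv
   MIC    PTA     lo95     hi95     lo99     hi99
0.0312 0.9996 0.999060 1.000000 0.998891 1.000000
0.0625 0.9914 0.988777 0.994023 0.987952 0.994848
0.1250 0.9262 0.918928 0.933472 0.916643 0.935757
0.2500 0.6566 0.638984 0.674216 0.633449 0.679751
0.5000 0.2698 0.255440 0.284160 0.250927 0.288673
1.0000 0.0442 0.039494 0.048906 0.038015 0.050385
2.0000 0.0042 0.002191 0.006209 0.001560 0.006840
4.0000 0.0002 0.000000 0.000592 0.000000 0.000715
8.0000 0.0000 0.000000 0.000000 0.000000 0.000000
```

Reading the output: the 42-subject cohort (210 nominal samples, a few
censored below the 0.04 mg/L assay limit) was generated with the reference
model as truth; the fit recovers the typical clearance (26.6 vs 25.4 L/h
generating value) and the variability structure from sparse five-sample
profiles.  The PTA table says that even at 1200 mg/day only ~66% of virtual
ICU patients reach ƒAUC₀–₂₄/MIC ≥ 100 at an MIC of 0.25 mg/L, and ~27% at
the 0.5 mg/L clinical breakpoint — the high between-patient variability
(ω_CL ≈ 0.68) spreads exposure so widely that no fixed regimen covers the
breakpoint reliably, which is the quantitative argument for therapeutic
drug monitoring in this population.

Other subcommands: `covsearch` (stepwise covariate search over eGFR,
creatinine, albumin, BMI, weight, age, sex, RRT), `bootstrap`, `vpc`,
`npde`, `report`; `cipropk --config run.yaml <cmd>` supplies shared
defaults (seed, replicate counts, MIC grid, BLQ policy).  Every artifact
gets a `.manifest.json` recording the options and seed.

The same operations are available as a library:

```python
import cipropk as c

dataset, truth = c.generate_cohort(seed=1)
fit = c.fit(dataset, c.reference_model())
pta = c.simulate_pta(c.reference_model(),
                     c.DosingRegimen(dose=400, interval=8), n=5000, seed=1)
```

See `docs/methods.md` for the model equations, the estimation algorithm and
its numerics, and known limitations.

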