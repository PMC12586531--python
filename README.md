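# morbsim

Dynamic discrete-time microsimulation of the burden of **major illness** —
a Cambridge Multimorbidity Score (CMS) above 1.5 — in an adult population
(ages 30–100) under counterfactual risk-factor scenarios.

The package is aimed at epidemiological modellers who want a fully testable,
self-contained engine of the kind used to project multimorbidity in England:
synthetic individuals ("simulants") carry sociodemographics, correlated
risk-factor exposures (BMI, SBP, total cholesterol, fruit, vegetables,
physical activity, smoking history, environmental tobacco smoke), acquired
diseases, and a vital status, all updated in annual stochastic steps.
Because no survey, primary-care or demographic microdata can be shipped, a
first-class synthetic-population module generates close-to-reality inputs of
the same shape, so every mechanism is exercised end to end without any
download.

## The model

* **Exposures.** Each simulant keeps a fixed percentile rank per exposure for
  life (a Gaussian copula on per-simulant normal scores); the value in year
  *t* is the stratum-year quantile at that rank, with the location of each
  distribution drifting log-linearly. This single mechanism gives lifelong
  exposure-quintile persistence and constant cross-exposure correlations.
  Smoking is simulated dynamically (initiation, cessation, relapse,
  pack-years); ETS exposure is derived from stratum smoking prevalence.
* **Incidence.** For condition *d* and simulant *i*,
  `p_i = p0(stratum, year) × Π_links RR^max(x_lag − TMREL, 0) × Π parents RR`,
  with lags of ~5 years (9 for cancers), protective factors contributing
  `RR^max(TMREL − x, 0)`, smoking-status RRs scaled by intensity, and
  cumulative pack-year effects (decaying after quitting) for COPD and lung,
  breast and colorectal cancer. The baseline `p0` is backed out of target
  rates through the population attributable fraction:
  `p0 = target / E[Π RR]`, i.e. `p0 = target × (1 − PAF)` with
  `PAF = 1 − 1/E[Π RR]`.
* **Mortality.** Competing annual risks: per-condition case fatality
  (sharing the incidence RRs) plus other-cause mortality modified by SBP,
  smoking, physical activity and selected diseases; combined as
  `1 − Π(1 − p_k)`, one proportionally attributed cause, and per-stratum
  calibration to an all-cause envelope, with the factors frozen on the base
  case so scenarios can genuinely move mortality.
* **Scenarios.** From 2023: (a) *theoretical minimum risk* (TMREL) — BMI 22,
  SBP 112 mmHg, total cholesterol 4 mmol/L, 4 portions each of fruit and
  vegetables, 7 active days/week, all smokers quit and initiation stops, no
  ETS; (b) *10% relative improvement* against each year's base case — e.g.
  BMI 28 → 28 − 0.1 × (28 − 22) = 27.4, with BMI reductions mediating SBP
  (−2.55 mmHg per unit) and total cholesterol (−0.23 mmol/L per unit) for
  BMI ≥ 25. Common random numbers pair every arm with the base case.
* **Outputs.** A tidy results cube (iteration × scenario × year × stratum ×
  metric) from which prevalence and incidence of major illness, all-cause
  mortality per 10,000 at risk, case-years prevented/postponed, counts living
  with/without major illness, age-standardised prevalence and deprivation
  gradients are derived, each with means and 2.5–97.5 percentile intervals
  across Monte-Carlo iterations.

The packaged relative risks are illustrative magnitudes, not meta-analytic
estimates; see `docs/methods.md` for what that does and does not let the
tests demonstrate.

## Worked example

```python
import morbsim

cfg = morbsim.RunConfig(n_simulants=5000, n_iterations=3, master_seed=1)
res = morbsim.Microsimulation(cfg).run()
print(res.summary())
```

prints (a few seconds on one CPU):

```
Microsimulation of major illness (CMS > 1.5)
  simulants: 5,000  iterations: 3  horizon: 2013-2043 (scenarios from 2023)

scenario                     prev 2043   abs diff (pp)  rel diff (%)  case-years prevented
baseline                         20.1%
tmrel_all                        19.8%            0.29           1.4                  -905
improve10_all                    20.0%            0.13           0.6                  -113
```

Read: under continuing trends, 20.1% of simulated adults live with major
illness in 2043. Eliminating all excess risk from 2023 lowers that by 0.29
percentage points (a 1.4% relative reduction) — yet *case-years prevented*
is negative (−905 person-years over 2023–2043): lower case fatality and
other-cause mortality keep people alive longer, some of them with major
illness. That survival paradox is a real feature of this class of model, and
its size here reflects the illustrative parameter set, not an empirical
estimate. Per-factor arms, sensitivity switches (no case-fatality effect,
alternative CMS threshold, direct-effect-only BMI) and stratified summaries
hang off `Scenario`, `RunConfig` and the cube helpers
(`inequality_gradient`, `standardise_to_reference`, `case_years_prevented`).

A CLI wraps the same library surface:

```bash
morbsim run --n 5000 --iterations 3 --seed 1 --out runs/demo
morbsim summarise --cube runs/demo/results_cube.csv --year 2043
```

## Layout

```
src/morbsim/registry.py     condition registry, risk links, TMRELs, CMS score
src/morbsim/population.py   synthetic cohort + calibration targets
src/morbsim/exposure.py     trajectories, lag buffers, smoking, ETS
src/morbsim/scenario.py     TMREL and relative-improvement transforms
src/morbsim/disease.py      dose-response, PAF calibration, incidence, recovery
src/morbsim/mortality.py    case fatality, other-cause deaths, envelope calibration
src/morbsim/outcomes.py     results cube, metrics, uncertainty summaries
src/morbsim/run.py          Microsimulation / SimulationResults orchestration
src/morbsim/data/           parameter tables (tab-delimited, checksummed)
```
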