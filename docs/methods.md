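# Methods

## Model structure

The engine simulates a roster of synthetic adults from 2013 to 2043 in
annual steps, ordered within each year as: entrants join → exposures update
(with the scenario transform applied from 2023) → disease incidence →
recovery → mortality → outcome accumulation. The years 2013–2022 are a
burn-in: they grow the exposure lag buffers and fix the calibration
quantities; results are reported from 2023, when the scenarios switch on.
The causal layering is conventional: behavioural exposures depend on
sociodemographics; biological exposures on behavioural and sociodemographic
ones; disease on all exposures and on other diseases; death on everything.
Exposure trajectories therefore depend only on sociodemographics and are
simulated once per iteration for the whole roster, regardless of vital
status; disease and mortality consume them afterwards.

26 modelled conditions aggregate to the 20 Cambridge Multimorbidity Score
(CMS) conditions; a simulant's score is the sum of the weights of the CMS
conditions with at least one *active* member condition, each counted once
(both diabetes subtypes, or several cancers, contribute their weight a
single time). "Major illness" is a score strictly greater than 1.5; the
threshold is a run parameter for the sensitivity analysis. 14 of the 20 CMS
conditions are lifelong (no recovery); the four named cancers and "other
cancers" remit 10 years after diagnosis (breast/colorectal/lung without
recurrence; prostate and other cancers may recur); pain, constipation,
asthma, alcohol problems and anxiety/depression recover stochastically with
per-condition annual probabilities and carry a past-history RR on
recurrence.

## Exposures

Continuous exposures use a Gaussian copula: each simulant holds a fixed
normal score per exposure, drawn jointly with a configured rank-correlation
matrix (converted exactly to normal-score correlations via
ρ_z = 2·sin(π·ρ_s/6)); the exposure value in a year is the stratum-year
quantile at that score. Locations evolve log-linearly (log link for
positive-scale exposures; logit link for the bounded 0–7 active-days
count). This one mechanism enforces lifelong quintile-group persistence and
time-constant exposure correlations, and makes base-case trajectories
deterministic given the score — so the lag buffer is simply the full matrix
of per-year values, back-filled before 2013 (ages extrapolated below entry
age, floored at 20) to cover the longest lag.

Smoking is dynamic: status (never/current/ex), cigarettes/day (rank-linked,
lognormal around 12/day), pack-years (+cigs/20 per smoking year), and a quit
clock. Adult initiation is rare (0.2%/year, declining), cessation 3.5%/year,
relapse 0.5%/year. ETS exposure is Bernoulli with probability
`coupling × stratum smoking prevalence` (coupling 0.9, truncated to [0,1]),
for non-smokers only; the proportional form is a stand-in flagged in the
configuration, since the coupling between ETS and smoking prevalence has no
canonical functional form.

## Disease incidence and calibration

Annual incidence is `p0 × Π link RRs × Π parent RRs (previous year's
states) × past-history RR`, clamped to [0, 0.999]. Continuous links use a
log-linear dose-response above the TMREL (below it for the protective
fruit/vegetables/physical activity, whose RR per unit encodes the deficit
risk); the multiplier never drops below 1. Smoking-status links scale the
tabulated current-smoker RR (referenced to 20 cigarettes/day) linearly in
lagged intensity, so the cigarettes-per-day scenario has a risk pathway;
ex-smokers revert to 1 once the lag has passed (full reversibility), except
the four cumulative links (COPD, lung/breast/colorectal cancer), where the
excess is linear in pack-years (capped at 2.5× the 20-pack-year reference)
and decays exponentially after quitting with a 10-year half-life — a chosen
form, since only the cumulativeness itself is a stated assumption. Lags are
fixed integers per link (4–5 years non-cancer, 9 cancer), not distributions.

`p0` is backed out of the stratum target rate through the population
attributable fraction: `p0 = target / E[Π RR | calibration stratum]`, the
stratum being sex × 10-year age band × deprivation quintile, with an
empty-stratum fallback to the overall at-risk mean. Targets vary by single
year of age and deprivation decile inside a stratum, so individual
`p0_i = target_i / E[Π RR]`; the within-stratum covariance between target
and multiplier is second-order and the closure tests (marginal incidence
within 3 binomial SEs of target at n = 50,000) bound the error. Divisors are
computed on the base-case arm each year and frozen for scenario arms —
otherwise calibration would silently re-absorb the intervention. Incidence
trends are part of the target surfaces: log-linear continuation for most
conditions, no calendar trend for chronic pain (reference-year incidence)
or for anxiety/depression and constipation.

## Mortality

Each alive simulant faces one competing risk per active condition plus an
other-cause risk. Case-fatality components share the incidence link RRs
(the equal-effects assumption) and are backed out of case-fatality targets
through the same PAF identity, divisors again frozen on the base case; the
no-case-fatality-effect sensitivity switch evaluates scenario case-fatality
RRs on base-case exposures instead. Other-cause mortality multiplies the
envelope rate by RRs for SBP, smoking and physical activity (current-year
values) and for prevalent CHD, stroke, diabetes and COPD — the disease set
is configurable since "several diseases" is open. Risks combine as
`1 − Π(1 − p_k)`; a single cause is drawn proportionally to the component
hazards `−log(1 − p_k)`. A per-stratum scalar on the proportional-hazard
scale (solved by Brent's method in [1e−9, 20], warned and capped when the
envelope is unattainable) matches expected deaths to the all-cause envelope
on the base-case arm and is frozen for scenario arms.

## Scenarios

Transforms apply from 2023, always against that year's base-case value.
TMREL: continuous factors to the iteration's sampled TMREL, activity to 7
days, all smokers to ex (pack-years frozen, quit clock from 2023),
initiation zero, no ETS. 10% improvement: biological factors lose 10% of
their excess over TMREL; fruit and vegetables (always moved together) gain
10%; 10% of base-case smokers quit — selected by a dedicated once-drawn
uniform so the *same individuals* quit in single-factor and combined arms —
and the rest cut cigarettes 10%; 10% of those under 7 active days gain one
day, recipients resampled annually against that year's base case (whether
recipients persist is unstated; annual resampling matches the
annually-relative definition). BMI arms additionally lower SBP by 2.55 mmHg
and total cholesterol by 0.23 mmol/L per unit of BMI reduction when
base-case BMI ≥ 25, clamped at the respective TMRELs and disabled under the
direct-effect-only switch; mediation deltas are recomputed each year from
that year's BMI delta, never accumulated. TMRELs (BMI 22 kg/m², SBP 112
mmHg, total cholesterol 4 mmol/L, fruit and vegetables 4×80 g portions,
activity 7 days, smoking 0) are redrawn once per Monte-Carlo iteration from
symmetric triangular distributions with ±10% support (a chosen form — the
existence of TMREL distributions is stated, their shape is not; physical
activity, smoking and ETS are fixed). Future entrants are covered by the
scenario from 2023 even before joining the 30+ population, with pack-year
accrual paused until entry to mirror the base case.

Common random numbers: every draw is keyed by (master seed, iteration,
purpose, year, condition) through hashed `SeedSequence` spawning, never by
arm, so a fraction-0 scenario is bit-identical to the base case and paired
differences isolate the intervention. Changing the scenario list cannot
perturb the base-case arm.

## Synthetic population and targets

The generator emulates the *shape* of English adult inputs: a declining
adult age structure, uniform deprivation deciles, survey-like exposure
distributions with deprivation gradients and secular trends (e.g. BMI mean
≈ 27 rising slightly; SBP ≈ 126 falling; smoking prevalence ≈ 19% at the
reference year, higher in deprived deciles and declining), Gompertz
mortality with a deprivation gradient, and steeply age-graded incidence for
degenerative conditions. Initial disease states are seeded from parametric
prevalence surfaces with back-dated onsets; entrants join at age 30 each
year, generated fresh from the same stratum distributions (distributionally
equivalent to cloning existing members, and identical across arms); counts
targets follow the closed accounting identity counts(t+1) = survivors(t) +
entrants(t+1), verified to 0.5%. Simulants reaching 100 stay in the 100
bin; deprivation is fixed for life, quintile = ⌈decile/2⌉.

What passing tests therefore show: the *mechanisms* — copula persistence,
lagged dose-response, PAF closure, common-random-number pairing, competing
risks, accounting identities — behave exactly as specified. What they do
not show: empirical validity of any projected magnitude. The packaged RRs
are illustrative (chosen so realistic contrasts imply RRs ≈ 1.1–3.0), the
exposure and rate surfaces are parametric stand-ins, and the balance
between incidence and survival effects (e.g. the sign of case-years
prevented under an all-factors TMREL) is parameter-dependent. The engine is
demonstrated to *permit* the survival paradox — a smoking arm configured
with mortality effects exceeding incidence effects yields negative
case-years prevented — not to estimate its real size.

## Numerical choices and degenerate inputs

Annual probabilities are clamped to [0, 0.999]; multipliers never fall
below 1; correlation matrices are checked positive semi-definite (error
otherwise) and Cholesky-factorised with a 1e−12 jitter; percentile
intervals use linear interpolation on sorted per-iteration values (2.5/97.5);
uncertainty summaries difference within iteration before summarising;
single-iteration runs report a central value without an interval; an empty
incidence-rate denominator returns a flagged missing value; ranks must lie
strictly inside (0,1). Problem sizes in the shipped tests (≤ 10,000
simulants, ≤ 3 iterations for end-to-end runs; 50,000 for one-shot closure
checks) were chosen as the smallest that hold the stochastic assertions at
3-SE tolerances; the engine itself is vectorised and runs 10,000 simulants
× 31 years × 2 arms in a few seconds.

## Known limitations

No within-year exposure variation or measurement error; no behaviour change
on diagnosis; no migration agent dynamics (entrants only); cause-of-death
attribution is proportional by construction; parent-condition RRs apply to
incidence only (the disease-as-risk-factor evidence concerns incidence);
whether multiple co-occurring cancers should ever score more than once is
resolved as "once" since the score is defined on the 20 conditions; relapsed
ex-smokers resume at zero cigarettes/day (their intensity rank is retained
only for initiation), a simplification that slightly understates relapse
risk.
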