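# Methods

`caresim` is a dynamic microsimulation of the joint burden of dementia and
physical frailty in an ageing population, together with the formal and
informal care costs that burden implies.  This note documents the model, the
synthetic data that stands in for the restricted survey and claims sources
such a model is normally estimated on, the numerical choices, and the known
limitations.

## 1. The transition engine

The population is a set of explicit individuals aged 60 and older, each
carrying a state vector: age, sex, educational attainment (less than high
school / high school / college or higher), eleven chronic-condition flags
(diabetes, coronary heart disease, stroke, hypertension, hyperlipidaemia,
cancer, respiratory disease, joint conditions, eye problems, chronic kidney
disease, other diagnoses), counts of basic and instrumental
activities-of-daily-living limitations (ADL 0–6, IADL 0–7), depression,
self-reported health (1–5), and vital status.

States evolve in a first-order Markov process with a **half-year cycle**.
Within a cycle the event order is fixed, because it matters at the margin:

1. **Mortality** — a draw from the age-band × sex × education table of
   half-year death probabilities.  Current conditions act multiplicatively
   on the hazard: with baseline probability `q` and per-condition log
   hazard ratios `γ_c`, the effective probability is
   `1 − exp(−(−log(1−q)) · exp(Σ_c γ_c x_c))`.
2. **Condition incidence** — survivors draw onset for each condition they
   do not yet have.  Chronic conditions are non-reversible.
3. **Functional decline** — ADL/IADL limitation increments, depression
   onset (non-reversible, like the chronic conditions), and a one-step
   worsening drift of self-reported health.

Ages advance by half a year per cycle and are capped at 105; the open 100+
parameter band serves all ages past 100.  Dead individuals are frozen.
Results are reported on a 3-year grid (six cycles per reporting interval);
conversion utilities `p_half = 1 − (1 − p_interval)^(1/6)` translate 3-year
probabilities to the engine cycle and back.

**Entry cohorts.**  Once per calendar year a cohort aged 60–62 enters, with
education drawn from a schedule whose college share rises over calendar
time (emulating the educational improvement of successive cohorts) and with
the scheduled count thinned binomially by a pre-entry cumulative survival,
emulating attrition between the census cohort and model entry.  The default
annual entry count is 3.5% of the baseline population size — the mid-2010s
Japanese ratio of the cohort turning 60 (≈1.5M/year) to the population aged
60+ (≈44M) — which holds the simulated 60+ population roughly stable.

**Common random numbers.**  Every cycle consumes a fixed number of uniform
draws per row regardless of vital status, so two runs sharing a seed differ
only where their parameters differ.  This makes dominance checks sharp:
raising any mortality cell can only reduce the number alive at every later
snapshot, and the test suite verifies exactly that.

The engine reproduces the exact matrix-power occupancy distribution of a
three-state (healthy/sick/dead) chain at n = 100,000 within three
multinomial standard errors; this is the engine's acceptance oracle.

## 2. Dementia and MCI classification

Dementia is not observed; it is operationalised the way survey-based
algorithms in the Health-and-Retirement-Study tradition do it.  A
**multivariate probit** links ten binary outcomes — failure on three
cognitive tests (immediate word recall, delayed word recall, serial sevens)
and difficulty with seven IADL items — to age, sex, education and the
comorbidity count through a latent multivariate normal.  Fitting is
outcome-wise maximum likelihood (univariate probits) plus a pairwise
estimate of the latent correlation: for each outcome pair the correlation
is solved so the model-implied joint success probability (a bivariate
normal orthant probability, evaluated via Owen's T function) matches the
observed pairwise rate; the assembled matrix is projected to the nearest
positive-definite correlation matrix.

For each simulated person the model yields two quantities:

* `p_fail` — probability of failing the battery (default rule: at least 2
  of the 3 tests; configurable), and
* `p_joint` — probability of battery failure *and* at least one IADL
  difficulty.

Both are joint orthant probabilities of the latent normal.  Under the
default exchangeable correlation they are computed exactly (to quadrature
accuracy) through the one-factor representation
`u_j = √ρ Z + √(1−ρ) ε_j` and 41-node Gauss–Hermite integration over Z;
for a general correlation matrix a scrambled-Sobol quasi-Monte-Carlo
evaluation with a fixed scramble seed is used instead.  The two routes
agree to < 0.02 in the tests, and both reduce to an exact 2^10 pattern
enumeration under independence.

**Labels.**  Dementia: `p_joint ≥ θ_dementia` (cognitive failure with
functional loss).  MCI: `p_fail ≥ θ_mci` without the IADL requirement, and
not dementia.  Both cutoffs are **calibrated** so that the modelled overall
prevalence matches external target prevalence curves (age–sex logistic
curves shaped after Japanese epidemiological surveys).  Because modelled
prevalence is a right-continuous step function of the cutoff, the search is
performed directly on the order statistics of the predicted probabilities —
the `round(π·n)`-th largest probability is the exact fixed point that
bisection on the cutoff converges to, and it matches a sort-based oracle at
person granularity by construction.  Persons sharing a covariate pattern
share a predicted probability, so attainable prevalence moves in tie-block
jumps; the pipeline therefore snaps to the nearest attainable share within
a practical tolerance (default 0.01), while the calibration primitive
itself resolves any reachable target to 1e-4.  Unreachable targets raise an
error reporting the attainable range.

Thresholds are calibrated once on the baseline year and held fixed over the
projection; prevalence changes thereafter are driven by the simulated
covariate dynamics (ageing, morbidity accumulation, educational
composition), not by re-anchoring.

## 3. Frailty classification

Frailty enters as a phenotype-style binary state.  A **logistic
regression** of a surveyed binary frailty phenotype on age, sex, education,
seven comorbid conditions (diabetes, heart disease, stroke, hypertension,
hyperlipidaemia, cancer, chronic renal failure), depression and impaired
mobility is fitted to a community survey fixture of 1,952 records aged 65+
(the size of the field survey it emulates).  "Impaired mobility in daily
living" is mapped from the simulated functional state as *any ADL
limitation or ≥ 2 IADL difficulties*; the mapping is configurable since no
canonical rule exists.  The fitted model extrapolates a probability to
every simulated person; a cutoff calibrated to a target prevalence (same
order-statistic machinery) yields the label.  Frailty is re-evaluated from
current covariates at every reporting period — unlike the chronic
conditions it can fluctuate — and persons under 65 (outside the survey's
support) are never labelled frail.

## 4. Life expectancy and the Sullivan partition

Period life tables are built from the engine's occurrence/exposure
experience: deaths and person-years by calendar year × single year of age ×
sex × education, with a death contributing a quarter-year within its
half-year cycle.  Central rates convert to interval probabilities with the
mid-interval assumption `q = w·m / (1 + (w/2)·m)` (capped at 1), the
standard `l/L/T/e` recursion follows, and the open terminal interval uses
the `L = l/m` convention; if no deaths are observed in the terminal
interval the last closed interval's rate is carried forward rather than
implying immortality.  Single-year tables are the internal form; an
abridged (5-year) view is available and pipeline runs on small populations
use 5-year intervals from age 65 with the open interval at 95+ so every
cell has exposure.

The **Sullivan method** partitions remaining life expectancy at 65 into
years with and without a condition:
`years_with = Σ_x prevalence_x · L_x / l_65`, with the prevalence curve
taken from the classified snapshot of the same period (period perspective).
The partition identity holds to 1e-9 by construction and is asserted on
every run; a constant-hazard table reproduces the geometric closed form
`e = (1−q)/q + 0.5` to 1e-6; and the life-table expectancy agrees with the
directly observed mean survival of a closed simulated cohort at n = 100,000
within Monte-Carlo error (cross-method oracle).

## 5. Costs

Three components, all annual, in constant 2016 US dollars, no discounting:

* **Health care** — monthly use by service type (inpatient vs
  outpatient + prescription) is regressed by least squares on age, sex and
  the eleven comorbidities; predicted monthly use × 12, floored at zero.
  The comorbidity *count* is exactly the sum of the flags and therefore
  cannot enter the same linear design (estimation software silently omits
  it); it is reported descriptively in the per-capita tables instead.
* **Formal long-term care** — the seven LTCI eligibility levels collapse to
  two costing tiers: *high* dependency (any ADL limitation — support in
  bathing, toileting, eating) and *mild* (IADL limitation or frailty
  without ADL limitation).  Mean monthly cost is looked up by age band ×
  sex × tier × setting (home/community vs care home) and annualised.
  Care-home residence is assigned stochastically from an age–tier
  probability table, because costing needs a residence split but no
  assignment rule is observable in the simulation.
* **Informal care** — home-based dependent persons receive 25 (high) or 10
  (mild) hours/week of unpaid care valued at $11/hour: exactly
  25×52×11 = $14,300 and 10×52×11 = $5,720 per person-year.  Care-home
  residents and persons without dependency receive none.

Aggregation reports totals by component for the four disjoint condition
groups (neither / dementia only / frailty only / both) and, in
headline style, overlapping "dementia" and "frailty" attributions that each
include the *both* group — the overlap is also reported separately.
Per-capita means follow the sex × education × {total / without / with
dementia-or-frailty} layout, with mean comorbidity counts.  The
household-capacity **sensitivity scenario** scales informal-care volume
down by 20% and community-based home-care costs up by 13% (both
configurable, validated to [0,1]) and reports the combined formal+informal
total.

## 6. Uncertainty

The full pipeline is replicated (default **50 bootstrap iterations**) with
independent seeds derived from one master seed.  Each iteration redraws the
stochastic baseline population, the entry cohorts, and all transition,
classification-calibration and residence randomness; the estimated model
coefficients are held fixed across iterations (an optional flag also
refits the estimation surveys per iteration, off by default).  Summaries
per cell are the mean, the 5th–95th percentile range by the
**nearest-rank** convention (for 50 iterations: ranks 3 and 48), and the
Monte-Carlo standard error `sd/√n`.  Iterations run sequentially; the
seed-derivation contract makes any parallel execution bit-identical to the
sequential order.  Note that nearest-rank percentiles cannot see the mass
beyond their rank, so in cells that are degenerate at the percentile level
(e.g. a count of 0 in 48 of 50 iterations) the mean may sit marginally
outside the point interval; the interval-ordering checks allow exactly
that granularity and nothing more.

## 7. Synthetic data: what it emulates, what it does not

All inputs are generated, with known ground truth, because the data the
real analysis used (nationally representative health surveys, a
cognitive-test survey, a community frailty survey, national health-insurance
and long-term-care claims, census–death-record linkage) are restricted.

* Baseline population: age pyramid declining exponentially (rate 0.045/yr),
  55% female, per-sex education shares (women 45/45/10, men 35/45/20 for
  <HS/HS/college), condition flags from logistic models with age/sex/
  education gradients, binomial ADL/IADL counts rising in age.
* Mortality: Gompertz, `log h = a_sex + b·age` with (a,b) = (−14.41, 0.13)
  women, (−12.93, 0.12) men, education hazard ratios (1.15, 1.0, 0.85),
  chosen so that *after* the condition offsets the age-specific rates
  resemble mid-2010s Japanese period tables (m75 ≈ 0.012 women / 0.025
  men; life expectancy at 65 ≈ 24 / 19 years).
* Incidence: per-condition Gompertz-style hazards with education gradients.
* Survey fixtures: the cognitive survey draws its ten outcomes from the
  latent normal with exchangeable correlation ρ = 0.3 (the real model's
  correlation structure is not published; this default is a configurable
  stand-in); the frailty survey (default n = 1,952, ages 65+) and claims
  fixtures draw from the logistic and linear truths.  Claims noise is
  Gaussian with intercepts large relative to the noise so the non-negativity
  floor binds with negligible probability and least squares recovers the
  truth.
* Calibration targets: logistic-in-age prevalence curves per sex shaped
  after Japanese epidemiological surveys (dementia steeply rising and
  roughly doubling per 5 years of age, a flat MCI curve, frailty rising
  from 65).

The generator does **not** emulate survey weighting, nonresponse,
measurement error in the cognitive tests, the census–death-record linkage
mechanics, health behaviours, or secular trends in incidence (one parameter
set "as of" the baseline is held constant, as in the study design).
Passing tests therefore demonstrate that the pipeline is internally correct
— it recovers known truths, satisfies its invariants and closed forms, and
reproduces printed-table arithmetic — not that its outputs match any real
country's headline projections, which require the restricted microdata.

## 8. Numerical choices and degenerate inputs

* One master seed per run; sub-streams per module/stage derived by hashing
  a label path, so any stage can be regenerated in isolation and derived
  seeds stay below 2^31.
* Probit pairwise correlations: Brent root search on [−0.98, 0.98] with
  1e-6 tolerance, on a deterministic subsample of ≤ 2000 rows; boundary
  returned if the observed joint rate is unattainable.
* Quadrature: 41 Gauss–Hermite nodes; QMC: scrambled Sobol, 512 points
  (4096 in cross-validation tests), fixed scramble seed.
* Calibration: target 0 maps to cutoff 1.0; a target exactly equal to the
  prevalence at cutoff 0 is accepted at the smallest attaining cutoff.
* Degenerate fits (one-class outcomes, separation, rank deficiency) raise
  typed errors naming the offending outcome or columns; missing parameter
  cells raise errors naming the stratum cell.
* Duplicating an estimation dataset leaves point estimates unchanged and
  shrinks standard errors by √2 (likelihood-scaling check in the suite).

## 9. Problem sizes used by the shipped checks

The test suite and the acceptance script use a 2,000-person population for
pipeline runs (12-year horizon in the bootstrap-contract test, 27-year
horizon with the full 50-iteration bootstrap in the acceptance script),
n = 50,000–100,000 for closed-form Monte-Carlo oracles, and
n = 10,000–20,000 for parameter recovery.  These sizes make every
stochastic criterion's Monte-Carlo error small relative to its tolerance
while the whole suite stays comfortably fast; the package itself has no
intrinsic size limit and the defaults (20,000 persons, 27-year horizon)
scale linearly.

## 10. Known limitations

* Non-reversibility of chronic conditions and depression is a modelling
  simplification; remission is out of scope.
* The battery-failure rule (≥ 2 of 3 tests) and the exact probit outcome
  set stand in for unpublished detail of the emulated algorithm; both are
  configurable.
* One global threshold pair is matched to overall target prevalence;
  per-age–sex achieved prevalence is reported for validation, and
  per-cell thresholds are not enabled by default.
* Cost attribution by condition group is prevalence-based, not causal:
  the "dementia-related" total is the full cost of persons with dementia,
  matching headline-style accounting, not an incremental cost of illness.
* No migration, no behavioural covariates, no productivity (indirect)
  costs, no discounting, no co-payment or fee-schedule detail.
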