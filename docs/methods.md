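# Methods

`eyeforce` is a continuous-time stock-flow (system-dynamics) model of
public-sector eye care for an aging population, with four linked stages:
population, prevalence, care demand, and the ophthalmologist workforce.
This note records the model, its assumptions, the numerical choices, what
the synthetic-data generator does and does not emulate, and known
limitations.

## Population (cohort-component projection)

The resident population is carried on 1-year age cohorts (0..99 plus an
absorbing 100+ bin) by gender, ethnicity (Chinese, Malay, Indian, Other)
and educational attainment (none, primary, secondary, tertiary).  Four
flows act on it:

* **Births** — per-ethnicity rates (births per reproductive-age female,
  ages 15–49, per year) times the reproductive-age female population;
  newborns enter age 0 in the "none" education stratum and are split by a
  configurable female fraction (default 0.5).
* **Deaths** — age-specific annual mortality applied to every cell.
* **Net migration** — a gap-closure rule: each year a fraction (default
  0.3/yr) of the gap between the desired national population path and the
  current resident total enters (allocated over a migrant age profile
  concentrated at working ages) or leaves (proportionally to current
  counts).
* **Aging** — at whole-year boundaries every cohort shifts up one year;
  survivors of 99 and of 100+ pool in 100+.

Education is fixed per person from labour-force entry: when a cohort
crosses the entry age (default 25) its education mix is reassigned from a
time-varying distribution that drifts linearly toward tertiary attainment
over the projection horizon, reflecting rising attainment in younger
generations.

**Integration.** Explicit Euler with a default step of 0.25 year; cohort
shifting only at whole-year boundaries.  This keeps 1-year cohorts well
defined while flows remain continuous.  All flows are stable at the
default step (total outflow rate × dt < 1 everywhere); stock-balance
audits confirm conservation to ~1e-15 relative per step.  Rate series
beyond their last data year are held at the last value.

**Desired-population path.** The national target is stated only as an
endpoint (6.9 million, scaled to the synthetic world).  A gap-closure
rule chasing a path that moves until the horizon leaves a standing lag of
roughly (path slope − natural increase)/closure-fraction, about 2–3% at
2040.  The generator therefore uses a path that reaches the target at
2035 and then holds, and calibrates the path level by fixed-point
iteration so the simulated total attains the stated target at 2040 —
mirroring the emulated setting, where the demographic module was
calibrated against national statistics.

## Prevalence

Nine conditions are tracked: cataract, diabetic retinopathy (DR),
glaucoma, age-related macular degeneration, myopia, (other) refractive
error, epiretinal membrane, retinal vein occlusion, and a residual
"other" class.  Prevalence proportions are stratified by single-year age
(40 to 100+), ethnicity and education, and are applied marginally — one
person can be counted under several conditions, matching how per-condition
survey prevalences are reported.  Under-40 prevalence is set to zero;
service use by the under-40s (and non-residents) is absorbed downstream by
the uptake factors.  DR carries a calendar-year multiplier (default:
linear from 1.0 to 1.3 over 2010–2040) encoding the expected rise in
diabetes.

## Care demand

Per condition, on the 40+ age × education grid:

* **Untreated pool** = max(0, prevalent − in care − completed care); the
  clamp exists because uptake also absorbs groups outside the prevalent
  base.
* **New patients/yr** = education-specific uptake factor × untreated pool.
  Baseline uptake (calibrated in the emulated setting): none 0.045,
  primary 0.07, secondary 0.076, tertiary 0.15 per year.
* **Decanting** — a per-condition fraction of *new* patients is diverted
  to community primary eyecare clinics and leaves specialist demand;
  existing patients are not retroactively transferred (flow-level
  decanting avoids a discontinuity in the stock).
* **Completion** — only cataract (3 y), myopia (1 y) and refractive error
  (2 y) have a finite course: outflow = stock / duration into a
  completed-care stock.  All other conditions need lifelong care.
  Completed patients do not re-enter the untreated pool.
* **Mortality** — age-specific population mortality applied to both
  stocks; both stocks age along the cohort chain with 100+ absorbing.
* **Demand** = patients in care × average visits per patient-year
  (default 2.4, configurable per condition).

Initialization takes an administrative base-year visit volume: patients =
visits / 2.4, split across conditions by the case mix (cataract 0.31,
DR 0.09, glaucoma 0.17, AMD 0.03, myopia 0.02, refractive error 0.02,
ERM 0.01, RVO 0.01, other 0.34), allocated within a condition
proportionally to the prevalent pool, with completed-care stocks seeded
at 0.1 of in-care for the curable conditions.  The waiting list is merged
into the in-care stock at initialization.

## Workforce

**Requirement.**  Required ophthalmologists = annual visit demand /
workload, where workload (visits per ophthalmologist per year) is a
linear fit to a 2003–2014 historical series, held at the fitted 2014
value beyond the data (a linear-trend option exists).  A scenario
multiplier (0.85 under moderated workload) scales the effective workload.
Head counts are reported rounded up; all internal arithmetic is
continuous.  The work-hours split (clinical 0.86 / research 0.09 /
teaching 0.02 / administration 0.03) is carried as metadata — the
workload ratio already reflects actual clinical time.

**Supply.**  A training conveyor: medical students (5-year course,
exogenous admissions, zero default dropout) graduate; 10% enter other
residencies, the rest become house officers (10%/yr attrition).  House
officers feed the medical-officer pool — hired against an exogenous
desired headcount using the same gap-plus-expected-attrition rule as
ophthalmologists — and the ophthalmology residency.  The residency is a
5-stage one-year aging chain: intake (the policy lever, bounded by the
upstream pools) accumulates in stage 1 and the chain advances at
whole-year boundaries, so a resident entering in year t graduates at the
start of year t+5 exactly.  Graduates are hired up to desired hiring
(gap + 3%/yr expected attrition); the surplus leaves the public system
permanently.

**Intake planning.**  For a required-headcount trajectory (typically the
lower and upper credible bounds of the demand projection), the smallest
constant integer intake is found by bisection (supply is monotone in
intake; a brute-force scan oracle verifies this in tests) such that
simulated supply meets the trajectory at the horizon and never
undershoots by more than a slack (default 10% of the trajectory maximum)
mid-horizon.  The planning simulation pre-fills the residency chain at
the candidate intake, i.e. it asks whether the policy, applied
consistently, sustains the requirement.

## Scenarios

All overrides start at 2013; before that the four scenarios coincide
exactly.

* **business_as_usual** — uptake flat at baseline; 5% of new DR,
  glaucoma, myopia and refractive-error patients decanted.
* **current_policy** — uptake ramps linearly to 2040 endpoints
  (none 13%, primary 20%, secondary 21%, tertiary 46%).
* **new_model_of_care** — as current policy, with decanting raised to 20%
  (DR, glaucoma) and 90% (myopia, refractive error).
* **moderated_workload** — as new model of care, with the workload
  multiplier at 0.85.

Ramps are linear (only endpoints are stated); decants and the multiplier
switch on as steps at 2013 (a configurable phase-in exists).  Uptake
ramps anchor at the *baseline model's* uptake values, so scenario runs
under posterior draws propagate parameter uncertainty correctly.  The
90% decant switch-on transiently drains the specialist stock of the
short-duration conditions, so new-model demand dips in 2013–14 before
resuming growth — a real policy-shock feature, not an artifact.

## Calibration and uncertainty

The four education-specific uptake factors are the most influential
unknowns.  Observation model: log-normal error on annual visits
(visits are positive; multiplicative error is natural), default σ = 0.05
on the log scale (0.03 in the synthetic generator); flat priors on
[0, 1].  The sampler is component-wise random-walk Metropolis with
proposal scales adapted toward ~30% acceptance during burn-in; burn-in
discarded is the larger of 20% and a Geweke-stable prefix.  Chains are
deterministic given a seed.

The observed series may be a single aggregate column or stratified by
education.  A single aggregate series of ~10 points cannot identify four
factors under flat priors (their sensitivities are nearly collinear);
the synthetic generator therefore emits education-stratified series, for
which the four sub-problems decouple and recovery is sharp.  Real
applications with aggregate data should fix or tie some factors.

Uncertainty propagation re-runs the scenario per (optionally thinned)
posterior draw and reports per-year 2.5/97.5 linear-interpolation
percentiles of each output.  The production configuration sizes this at
6 000 retained draws × 4 scenarios = 24 000 sensitivity model runs;
tests and the reproduction script use shorter chains (1 000–1 500
iterations) and thinned propagation (≤ 200 runs per scenario), which
leaves the studied properties unchanged.

A caveat found while validating: *relative* interval width can contract
slightly with the horizon (demand's elasticity to uptake falls as the
treated/completed share of the prevalent pool rises), while absolute
width grows.  Credible intervals far out should therefore not be read as
a fixed relative error band.

## Synthetic-data generator

The generator emulates the *statistical structure* of the study setting
with known ground truth, at a default scale of 500 000 residents (about
a tenth of the emulated resident population; all tested properties are
scale-free).  Per seed it draws: a realistic age pyramid (Gaussian bulge
centred at 40, with cohort-level texture), CMIO-like ethnic shares,
education mixes that worsen with age; declining birth-rate series
(2000–2013) and Gompertz mortality (2003–2013) with slight improvement;
a migrant profile at working ages; logistic-in-age prevalence per
condition with myopia most and RVO least prevalent and mild
ethnicity/education gradients; the default case mix; a declining
workload series (2003–2014, ~6 200 → ~5 100); and pipeline rates scaled
to the world.  The base-year in-care stock is set to 10% of the
prevalent pool (mirroring the visits-to-prevalence ratio of the emulated
setting), which fixes the administrative starting demand.  The observed
history (2010–2020, stratified by education) is produced by running the
model itself at the true uptake factors and multiplying log-normal noise
(σ = 0.03).

What it does **not** emulate: actual survey prevalence values, real
administrative visit counts, private-sector care, migration policy
detail, or condition co-occurrence.  Passing tests therefore demonstrate
the *mechanisms and internal consistency* of the model, not agreement
with any real jurisdiction's absolute counts; in particular the
published absolute projections and per-scenario intake ranges are not
reproduction targets.

**Aging-stress world.**  A separate mechanism probe isolates the
age-prevalence interaction: an old-age bulge placed entirely above 40
over a flat young pyramid (so cohorts crossing 40 are near-constant and
the 40+ head count evolves steadily), age-flat mortality,
education-uniform fast uptake (0.9/yr), no migration, no decanting, and
treatment completion disabled (the completed-care stock has
1/mortality-scale memory and cannot track a shifting age structure).
Care stocks start at their analytic per-cell equilibrium and spin up
five years before measurement.  With a cell-uniform ("flat") prevalence
table, demand growth then matches 40+ head-count growth to within half a
percentage point (the residual is the ~1-year stock-tracking lag); with
the age-increasing table, demand growth exceeds head-count growth by
tens of points — the mechanism by which an aging population outpaces its
own head count in care demand.

## Numerical choices and degenerate inputs

* Explicit Euler, dt = 0.25 yr everywhere; 1/dt must be an integer so
  whole-year boundaries are hit exactly.
* Deaths are rate × stock × dt with rates validated to [0, 1], so a cell
  cannot go negative from mortality alone; extreme emigration is clamped
  at zero (and would surface in the balance audit).
* Display rounding (nearest 100 for counts/visits, integers for head
  counts, half-up for percents and two-decimal ratios) never feeds back
  into computation.
* Percentiles are linear-interpolation (`numpy.percentile` default).
* Empty prevalent pools: initialization falls back to the overall
  prevalent shape for a condition with an empty pool and raises if the
  whole pool is empty; a stratum with zero prevalence receives zero
  patients.
* The requirement's reported head count uses ceiling with a 1e-9 guard
  against floating-point spill.

## Known limitations

* Conditions are independent marginal stocks; comorbidity is not
  modelled.
* PEC-side (community) care is not modelled beyond the diverted count.
* Visit intensity is a single constant per condition; no first/review
  split, no surgical/clinic distinction, no waiting-time dynamics.
* The medical-officer demand side is exogenous; other eye-care cadres
  are out of scope.
* Uptake identifiability from aggregate series is poor (see above); the
  stratified calibration the generator enables is an idealization.
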