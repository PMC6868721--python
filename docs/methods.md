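# Methods

## Model overview

`hfsim` is a hybrid discrete-event / agent-based microsimulation of heart-
failure (HF) treatment.  Each patient is an agent with an inner state
x = (age, sex, NYHA class) and a treatment ledger a (itemized euro
accumulators, visit counters, lengths of stay, and a tokenized history).
Time advances in daily steps over a configurable horizon (default five
years, 1825 days).  Every living agent in the inactive "patient pool" state
makes exactly **one categorical draw per day** over

    {outpatient death p00, outpatient clinic p01, hospital admission p02(NYHA),
     physician p03, specialist p04, stay}

with the residual mass meaning "stay in the pool".  A single categorical
draw (rather than independent Bernoulli draws per channel) matches the
one-transition-per-step semantics of the underlying discrete Markov model at
a sampling step of one day; it also means an admission preempts any other
event on the same day.  Rates quoted per year (e.g. 12 physician visits per
year) are converted to daily probabilities by dividing by 365, capped at 1.

The expected occupancy of a state-homogeneous kernel obeys the balance
recurrence

    P[i, k+1] = P[i, k] + (Σ_j P[j, k] p_ji − Σ_j P[i, k] p_ij) · Δt,  Δt = 1 day,

implemented in `propagate_expected_occupancy` and used as a deterministic
oracle: the Monte-Carlo occupancy of a homogeneous cohort must agree with it
within binomial standard errors (tested).

## Care pathways

**Outpatient.**  Physician and specialist are one combined state costing
€544/12 per visit (the €544 annual standard rate at 12 visits/year).
Outpatient-clinic visits (default one per year) cost €209 on the first visit
and €134 afterwards and are the only outpatient events that may change the
NYHA class, via the outpatient transition matrix.  Medication is drawn once
per patient-year per ATC group — C03 diuretics, C07 beta blockers, C09
renin–angiotensin agents — from sex-specific Weibull/Gamma distributions,
and accrued at `annual/365` per day so partial survival years are prorated.

**Medication residual.**  The three ATC groups cover roughly 30% of total HF
medication spending, so an ATCxx residual of `residual_factor × (C03 + C07 +
C09 draws)` is booked on top of the group draws, with `residual_factor =
3.33` by default.  With this default, the closed-form mean annual medication
cost is ≈ €1209 and the simulated outpatient total ≈ €1890 with a ≈ 64%
medication share, matching the reported simulation outputs of the source
study within ~1–2%.  An alternative reading of the scaling rule — the total
medication cost equal to 3.33 × the group sum, i.e. a residual factor of
2.33 — yields a mean of ≈ €930/year and is available by overriding
`medication.residual_factor`.  The factor is a declared calibration knob
because the two readings cannot be distinguished from the printed rule
alone, while the reported outputs clearly favour the default.

**Inpatient.**  On admission the agent branches into intensive care (ICU)
or intermediate care (IMC) — mutually exclusive — with age/sex-specific
probabilities and fixed median stays, billed at 1664 and 480 points per day
(TISS-28 score 32).  The ward length of stay (LOS) is drawn from the
NYHA-specific distribution (a fixed 3-day median for class I), rounded to
whole days with a minimum of one.  DRG reimbursement uses two case flat
rates: ages ≥ 65 get 3134 points within a 4–11-day treatment window, younger
patients 2688 points within 3–10 days.  Above the window each extra day adds
a supplement; below it a per-day short-stay rate replaces the flat rate.
The catalogue's per-day amounts are not part of the shipped parameter set,
so both default to the pro-rata policy `flat_rate / max_los` (≈ 284.9 and
268.8 points/day); both are override knobs.  This keeps DRG points
monotonically non-decreasing in LOS (property-tested).  An individual
medical procedure (IMP) occurs with an age/sex probability and bills the
age/sex average point score.  One point is valued at €1 by default
(`point_value`).

**Mortality.**  Inpatient mortality is applied once per episode with the
age/sex per-admission probability; the table already includes ICU/IMC
deaths, so those branches carry zero separate mortality.  Death takes effect
at the end of the stay; the full stay is still reimbursed.  Survivors may
change NYHA class at discharge via the inpatient transition matrix (row of
the pre-admission class).  Outpatient mortality is zero by default (no
cause-of-death data for outpatient care in the source data).

**Age dynamics.**  Age advances by 1/365 year per day; all age-bin lookups
(ICU/IMC/IMP/mortality, DRG age band) use the *current* age, so long
horizons can cross bin boundaries.  Age bins are the closed integer ranges
0–55, 56–65, 66–75, 76–85, 86+.

**Telemonitoring overlay.**  A program charges €1000 per enrolled patient up
front (booked regardless of later death) plus €45 per month (month = 365/12
days, giving exactly 12 fees per simulated year; fees stop at death).  In
exchange, enrolled agents' daily admission probability is multiplied by 0.79
(−21%) and their LOS distribution's scale parameter by 0.65 (−35% mean,
shape preserved).  Enrollment is a predicate on the baseline NYHA class:
TM_1 enrolls everyone, TM_2 excludes class I.  The factors apply uniformly
across classes.

## Numerical and design choices

- **Transition matrices** are stored as the printed row percentages and
  renormalized on load (printed rows carry < 0.1 percentage points of
  rounding error).
- **Distribution parameter convention**: Weibull(scale λ, shape k) and
  Gamma(shape k, scale θ), chosen because it yields plausible means for
  every printed distribution (e.g. NYHA IV LOS mean 7.56 × 1.83 ≈ 13.8
  days), while the reversed Weibull order produces absurd means (≈ €1/yr for
  C09).  The convention is switchable via `param_order` in the parameter
  file.
- **Episode handling**: ward/ICU/IMC stays are scheduled as blocks with the
  LOS drawn at entry (the data describe LOS distributions, not daily
  discharge hazards).  Agents inside an episode make no pool draws.
- **Event order within a day**: episode resolution (death/discharge), then
  the pool draw and its dispatched event, then fee/medication bookkeeping,
  then history logging.
- **Randomness**: each run uses one PCG64 generator seeded from a
  `SeedSequence` child of the master seed.  Every decision channel consumes
  one fixed-shape uniform array per day, positionally indexed by agent, and
  LOS/medication values are inverse-CDF transforms of those uniforms.
  Results are therefore reproducible bit-for-bit given (config, seed),
  independent of scheduling order, and agents not enrolled in a program have
  identical trajectories across program arms with the same seed (tested).
- **History files** use tokens `PH SP OC AD IC IM CC DE MD` with the day
  appended (`PH5 OC28 IC52 AD54 CC64`) and optional `:detail` suffixes: ward
  LOS and IMP flag on `AD`, ICU/IMC days on `IC`/`IM`, the new class on
  `CC`, and the settled annual medication amounts on `MD`.  The ward token
  is logged at ward entry (after any ICU/IMC days), mirroring the worked
  specimen; this ordering is a documented convention, not asserted of the
  source.  `replay_history` recomputes every euro accumulator from the
  token stream (plus the baseline agent state and program definition) and
  must reproduce the simulated ledger bit-exactly — the model's own
  verification procedure, applied to every agent in the test suite.
- **Annualized costs** in mortality-enabled scenarios are normalized by
  person-years at risk (days alive / 365); a patient's death day ends
  accrual the same day.
- **Aggregation**: scenarios run `n_runs` independently seeded replications;
  outcomes are reported as mean ± SD with a normal-approximation 95% CI
  across runs, per starting NYHA class and overall.

## Scenario presets and study conditions

All presets use 10,000 patients (2,500 per NYHA class by deterministic
largest-remainder allocation), a fixed baseline age of 70, five-year
horizon.  The source study does not print the age/sex composition for
scenarios 1, 2 and 4; the presets use age 70 with a 50/50 sex split
(scenario 3 is male-only per its description).

- **scenario1** — conventional care; inpatient mortality and NYHA class
  changes disabled (pure cost accounting).
- **scenario2** — inpatient mortality enabled, classes fixed.
- **scenario3** — 70-year-old men; class changes in both care settings plus
  inpatient mortality.
- **scenario4** — scenario-1 conditions plus the TM_1 overlay.  With
  mortality enabled the telemonitoring arm's first-year cost increase is
  ~14.6% and TM_1 does not break even within five years; under scenario-1
  conditions the model reproduces both reported findings of the source
  (first-year increase ≈ 10%, TM_2 break-even in year 2, TM_1 in year 3),
  so the preset uses the latter reading.

The sensitivity analysis runs fixed-class cohorts per (age 50–90, sex) cell
twice — mortality off for the cost outcome, mortality on for 5-year
mortality — and reports relative percentage differences of across-run means
against the same-sex age-70 reference, plus male-vs-female contrasts.

## Run-to-run stability metric

The verification procedure compares two independent batches of runs with
identical configuration and different master seeds, per starting NYHA
class, for mean total cost and mortality.  Cost deviations are relative
(|b1 − b2| / b1, in %).  Mortality is itself a percentage, and its deviation
is reported in percentage points: a relative reading is statistically
unattainable at any realistic batch size for low-mortality classes — for a
class-level mortality p estimated from N patient-histories per batch, the
expected relative batch difference is ≈ 0.8·sqrt(2p(1−p)/N)/p, which exceeds
0.5% for p < ~0.4 even at N = 250,000 — whereas both readings are far below
0.5 on their respective scales for costs and for the point-scale mortality
deviation (observed ≈ 0.2%).

## What the synthetic cohorts do and do not capture

Cohort generation allocates NYHA classes and sexes deterministically
(largest remainder) so preset cohorts match the printed counts exactly, and
supports fixed or distribution-drawn baseline ages.  The generator does not
reproduce the empirical age/sex histograms of the source data sets, nor
comorbidities, lifestyle attributes, outpatient mortality, or
NYHA-dependent outpatient cost profiles (the source data could not resolve
them).  Passing tests therefore demonstrate internal consistency of the
model and agreement with the published simulation outputs under the stated
study conditions — not calibration against patient-level clinical data,
which is not distributed with the package.

## Problem sizes used in tests and the acceptance script

Scenario-level checks run 10,000 patients with 5–10 replications; the
run-to-run stability check uses two batches of 100 runs × 10,000 patients in
the acceptance script and 20 runs per batch in the test suite; per-table
frequency checks use 2·10⁴–2·10⁵ draws against closed-form means or printed
probabilities within three standard errors.  These sizes were chosen so the
whole suite completes in minutes on one CPU while keeping Monte-Carlo noise
well below the tolerances being asserted.

## Known limitations

- Outpatient mortality is zero by default, so all-cause survival is
  overestimated, especially for NYHA I–II.
- DRG supplement and short-stay per-day amounts are a pro-rata policy, not
  catalogue values; absolute inpatient costs for very long or very short
  stays inherit that assumption.
- Admission rates depend on NYHA class only (not age or sex), as in the
  source parameterization.
- The medication residual factor is a calibration knob (see above); per-ATC
  subgroup structure and prescription behaviour are not modeled.
- ICU/IMC stays use fixed median durations; their true dispersion is not
  represented.
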