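# Methods

## Model structure

`hrhsim` implements a deterministic, discrete-time (annual), needs-based
planning model that is *dynamic* (multi-year, with parameters changeable over
time), *multi-professional* (every service must be fully allocated across
professions, so professions' requirements are interdependent) and
*needs-based* (requirements derive from population, prevalence and planned
service levels, not from historical utilization or provider-population
ratios).

Two quantities are computed per profession `n` and year `t` and compared:

- **Requirement** `N[n,t]`: population `P` × prevalence `H` × planned
  services per prevalent person `Q` gives service volumes per stratum;
  the division of work `W` allocates each service's volume across
  professions; dividing by productivity `R` converts allocated services to
  FTEs.  Each year is cross-sectional: unmet need is not carried forward as
  a backlog.
- **Effective supply** `N'[n,t] = S·D·A·F`: the licensed stock `S` is
  projected by a stock-and-flow recurrence (age-specific exits; inflows from
  a training pipeline with seats, program length, one-shot attrition at
  graduation, graduate out-migration, and a graduate age distribution; plus
  in-migration), then discounted by participation `D`, activity `A` and
  clinical focus `F`.  Only `F` is specific to the planned
  population/conditions; `S`, `D`, `A` describe the whole profession.

The gap is `N − N'`, positive for shortages.  Scenarios are ordered lists of
absolute overrides — "parameter X becomes v from year τ" — applied as
persisting step changes; years before τ are untouched, and the overridden
configuration is re-validated (e.g. division-of-work shares must still sum
to 1 from τ on).

## Data model and broadcast semantics

Every rate/level parameter is a sparse `StratifiedRateTable` over a subset of
the six dimensions (health state, age group, sex, service, profession,
year).  Lookups project queries onto the table's dimensions, so a table over
(service, profession) answers any stratum — this lets the division of work be
supplied anywhere between coarse (profession, service) and fully stratified
(all six dimensions), which matters because planners rarely have fully
stratified allocation data.  Missing entries resolve to an optional default
or fail loudly ("parameter not specified"): a service with planned volume but
no allocation is treated as a modelling bug, never as silent zero work.

One age-band list serves both sides of the model: population bands carry the
children being planned for, provider bands the workforce; each side holds
zeros on the other's bands.

## Numerical choices

- All reductions use compensated summation (`math.fsum`) over
  deterministically ordered terms; results are permutation-stable and the
  engines match independent naive re-implementations to 1e-9 relative.
- Division-of-work shares must sum to 1 within `dow_tolerance`
  (default 1e-9).  Renormalization is opt-in (`renormalize_dow`), off by
  default, because silently rescaling hides data errors.
- Headcounts are real-valued; deterministic rates produce fractional people
  by design.  Negative intermediate stocks (possible only with pathological
  inputs) are clamped to zero with a logged warning.
- Within a year, exits apply to the prior-year stock first, then entrants
  are added — the literal reading of the stock recurrence — and effective
  supply is evaluated on the end-of-year stock.
- Activity is bounded at 1.5 (not 1.0) because mean clinical FTE can exceed
  one for some physician groups.
- Rounding to whole FTEs happens only in display helpers and never in stored
  values; CSV output uses shortest round-trip float formatting, so files are
  byte-deterministic and lossless on re-read.

## Design choices where the design was open

- **Aging between bands is off by default.**  The stock recurrence contains
  no inter-band flow; an opt-in mode promotes `1/band_width` of each band's
  post-update stock per year (top band retains, totals conserved), since a
  long horizon without aging under-states movement into high-exit bands.
- **Pipeline seeding.**  Cohorts that entered before the first configured
  entry year are seeded at the earliest configured seat count (a steady
  pipeline), matching a status-quo baseline in which parameters are held
  constant; disable `seed_steady_state` to make unseeded history an error.
- **Attrition timing.**  Program attrition multiplies the whole cohort once,
  indexed by graduation year, rather than compounding per enrolment year.
- **Override semantics.**  Overrides are absolute replacements (scenarios
  are stated as "from 15% to 10%", not as deltas), persist to the end of the
  horizon, and conflicting overrides (same target, selector and effective
  year) are an error rather than last-wins.
- **Symbol hygiene.**  The per-year supply discounts and the pipeline both
  traditionally use the letters D and F; the configuration disambiguates as
  `participation`/`grad_age_distribution` and `clinical_focus`/`attrition`.

## Synthetic data and calibration

No jurisdictional administrative tables are distributed.  The fixtures
module provides:

- `generate(FixtureSpec)` — seeded random configurations (Dirichlet
  division-of-work rows, bounded prevalences, valid supply specs) used by
  the property-based tests; identical seeds are bit-reproducible.
- Exact linear calibration: requirements are homogeneous of degree −1 in
  productivity and the year-`t` stock is affine in the initial-stock scale,
  so a profession's requirement and its pre-focus supply can each be pinned
  to a target with one closed-form scalar.  `calibrate_shortage` pins the
  gap by rescaling the profession's own productivity rows, which leaves
  every other profession's gap unchanged; rescaling shared service levels
  would not.
- `packaged_fixture()` — a seven-profession, two-condition (anxiety,
  depression, ages 5–19) configuration.  The division-of-work shares, the
  clinical-focus levels (0.4% FP, 0.1% NP, 1.8% pediatrician,
  4.1% psychiatrist, 9.3% psychologist, 0.1% RN, 10% social worker), the
  140 000 population and the baseline shortages used as calibration anchors
  (83, 2, 35, 28, 76, 1 FTE) are published planning values; everything else
  — service levels, productivity rates, stocks, flows, growth — is
  synthetic.  Where published shares do not close to 1.0, the residual is
  assigned synthetically (documented in `fixtures.py`).  Planned
  psychotherapy levels are chosen so the published share shifts reproduce
  the published direction of every profession's gap change.  The
  social-worker side is calibrated to the internally consistent pair:
  requirement 125 FTE and pre-focus supply 360 FTE in the scenario year,
  the unique solution of gap(F=0.10)=89 and gap(F=0.05)=107.
- `worked_example()` — the same 125/360 arithmetic in a minimal
  one-profession configuration; this is what `scripts/acceptance.py` runs.

What passing tests show — and what they do not: the suite verifies the
model's algebra (oracle equivalence, conservation under task shifting, stock
accounting, pipeline lag, homogeneity, scenario isolation) and the
calibrated scenario arithmetic.  It does not validate the synthetic
magnitudes against any real jurisdiction: real planning runs require real
tables for every parameter, and the generator makes no claim about, e.g.,
true service levels or productivity norms.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: random
instances up to 4 age bands × 2 sexes × 3 health states × 4 services ×
7 professions × 5 years (100 instances for oracle equivalence, 200 random
task shifts for conservation, 100 trajectories for stock accounting), and
the packaged fixture at 7 professions × 15 years.  The engines are
dictionary-based and run these sizes in milliseconds; nothing in the
implementation limits larger strata counts or horizons.

## Limitations

- Deterministic only: no parameter uncertainty, no stochastic demand.
- No backlog/waiting-list dynamics; requirements are re-derived each year.
- No behavioural feedback (participation, migration and seats do not respond
  to gaps) and no cost side.
- Out-migration destinations are not modelled; exits are a single all-cause
  rate.
- One entry-to-practice program per profession (one program length); mixed
  program lengths require merging pipelines upstream.
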