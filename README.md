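# hrhsim — dynamic, multi-professional, needs-based workforce planning

`hrhsim` is a simulator for health-workforce (HRH) planning that compares,
per profession and per year, the full-time-equivalent (FTE) providers a
population *needs* with the FTEs the licensed workforce can actually
*deliver* — and lets planners rehearse policy changes (task shifting, changes
in clinical focus, training-seat expansions) as explicit scenarios.  It is
aimed at health-system planners and researchers who want needs-based,
multi-professional projections rather than provider-population ratios or
historical-utilization extrapolation.

## The model

**Requirements** for profession *n* in year *t* follow the needs-based chain
from demography to FTEs:

```
N[n,t] = Σ_q  Σ_{h,i,j} ( P[i,j,t] · H[h,i,j,t] · Q[h,i,j,q,t] · W[h,i,j,q,n,t] ) / R[n,q,t]
```

with population *P* (age group *i*, sex *j*), health-state prevalence *H*,
planned level of service *Q* (services of type *q* per prevalent person),
division of work *W* (the share of each service assigned to each profession;
shares sum to 1 per service stratum) and productivity *R* (services per FTE
per year).  Because every service must be allocated across professions,
shifting work to one profession automatically relieves the others.

**Supply** is a stock-and-flow projection of the licensed headcount with a
training pipeline:

```
N'[n,t] = S[n,t] · D[n,t] · A[n,t] · F[n,t]
S[i,n,t] = S[i,n,t-1] · (1 − E[i,n,t]) + I[i,n,t]
I[i,n,t] = G[i,n,t] · (1 − O[n,t]) + M[i,n,t]
G[i,n,t] = C[n,t−y] · (1 − attrition) · D_grad[i]
```

with exits *E*, graduates *G* from cohorts *C* that entered *y* (program
length) years earlier, graduate out-migration *O*, in-migration *M*,
participation *D*, activity *A* and clinical focus *F* — the often-overlooked
share of clinical time devoted to the specific population and conditions
being planned for.  The **gap** is `N − N'` (positive = shortage).

Scenarios are ordered lists of absolute parameter overrides, each effective
from a given year onward (persisting step changes).  The simulator is fully
deterministic; randomness exists only in the synthetic-configuration
generator and is seed-controlled.

## Worked example

The packaged one-profession configuration (`hrhsim.worked_example()`) is
calibrated so that social workers have an FTE requirement of 125 and a
pre-focus supply (stock × participation × activity) of 360 in the scenario
year:

```bash
python examples/04_calibrated_focus_example.py
```

```
status_quo: requirement 125.0 FTE, supply 36.0 FTE, gap 89.0 FTE
reduced_clinical_focus: requirement 125.0 FTE, supply 18.0 FTE, gap 107.0 FTE
```

At clinical focus 0.10 only 36 of the 360 pre-focus FTEs reach this
population, leaving a 89-FTE shortage; a scenario halving the focus to 0.05
halves the effective supply, and the shortage grows to 107 FTE.  The other
examples (`examples/01–03`) walk through the requirements chain, the
stock-and-flow projection, and a five-scenario comparison on the packaged
seven-profession configuration (pediatric anxiety/depression planning across
family physicians, nurse practitioners, pediatricians, psychiatrists,
psychologists, registered nurses and social workers).

## Command line

```bash
hrhsim synth --out fixture                 # write a complete config directory
hrhsim validate --config fixture/config.yaml
hrhsim run --config fixture/config.yaml \
           --scenario fixture/scenarios/focus_reduce_sw.yaml \
           --out results --plot png
```

`run` writes per-scenario gap and stock/flow CSVs, optional per-profession
gap plots, and a JSON run manifest.  Exit codes: 0 success, 1 validation or
model error, 2 usage error.

## Layout

- `src/hrhsim/domain.py` — stratified tables, registries, config, validation
- `src/hrhsim/requirements.py` — needs-based FTE requirements
- `src/hrhsim/supply.py` — stock-and-flow supply with training pipeline
- `src/hrhsim/scenarios.py` — overrides, scenario application, runs
- `src/hrhsim/reporting.py` — gaps, summaries, deterministic output files
- `src/hrhsim/fixtures.py` — synthetic generator, calibration, packaged fixture
- `src/hrhsim/config_io.py`, `src/hrhsim/cli.py` — files and command line
- `docs/methods.md` — modelling assumptions, parameters and limitations
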