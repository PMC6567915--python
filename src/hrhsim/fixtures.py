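"""Synthetic model configurations for testing and demonstration.

No real jurisdictional planning tables ship with this package: the
administrative data behind the motivating application (pediatric anxiety and
depression services in a province of ~140 000 children aged 5-19, planned
across seven professions) are not public.  This module therefore provides

* :func:`generate` — seeded, random-but-valid configurations of arbitrary
  size for property-based testing;
* :func:`calibrate_shortage` and friends — exact linear calibration of a
  profession's requirement and supply so a configuration reproduces a chosen
  gap;
* :func:`packaged_fixture` — a hand-built seven-profession, two-condition
  configuration whose division-of-work shares and clinical-focus levels are
  the published planning values, with all other magnitudes synthetic and
  pinned by calibration to the published baseline shortages; and
* :func:`worked_example` — the minimal one-profession configuration whose
  clinical-focus scenario arithmetic (requirement 125 FTE, pre-focus supply
  360 FTE, focus 0.10 -> 0.05) yields the 89 -> 107 FTE shortage pair.

Every magnitude not listed as a published value (productivity rates, service
levels, stocks, flows) is a synthetic choice; see ``docs/methods.md``.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .domain import (
    AgeBand,
    ModelConfig,
    ProfessionSupplySpec,
    StrataRegistry,
    StratifiedRateTable,
    TrainingPipelineSpec,
    YearSeries,
    validate_config,
)
from .errors import CalibrationError, ConfigValidationError
from .requirements import requirements_for_year
from .scenarios import Override, Scenario
from .supply import supply_timeseries

# ---------------------------------------------------------------------------
# Published planning values (division of work, clinical focus) and synthetic
# completions where the published shares do not close to 1.
# ---------------------------------------------------------------------------

PROFESSIONS = (
    "family_physician",
    "nurse_practitioner",
    "pediatrician",
    "psychiatrist",
    "psychologist",
    "registered_nurse",
    "social_worker",
)

SERVICES = (
    "diagnostic_assessment",
    "clinical_assessment",
    "care_plan_development",
    "psychotherapy",
)

#: Baseline division of work per service.  Published shares; the residuals
#: needed to close each service to 1.0 (NP in clinical assessment,
#: psychiatrist/psychologist in care-plan development, SW/NP/RN in
#: psychotherapy) are synthetic completions.
BASELINE_DOW: dict[str, dict[str, float]] = {
    "diagnostic_assessment": {
        "family_physician": 0.0, "nurse_practitioner": 0.0, "pediatrician": 0.0,
        "psychiatrist": 0.60, "psychologist": 0.20, "registered_nurse": 0.0,
        "social_worker": 0.20,
    },
    "clinical_assessment": {
        "family_physician": 0.15, "nurse_practitioner": 0.05, "pediatrician": 0.20,
        "psychiatrist": 0.15, "psychologist": 0.10, "registered_nurse": 0.0,
        "social_worker": 0.35,
    },
    "care_plan_development": {
        "family_physician": 0.10, "nurse_practitioner": 0.0, "pediatrician": 0.15,
        "psychiatrist": 0.15, "psychologist": 0.15, "registered_nurse": 0.0,
        "social_worker": 0.45,
    },
    "psychotherapy": {
        "family_physician": 0.30, "nurse_practitioner": 0.05, "pediatrician": 0.09,
        "psychiatrist": 0.01, "psychologist": 0.25, "registered_nurse": 0.02,
        "social_worker": 0.28,
    },
}

#: Division of work after the "shift work to less scarce professions"
#: scenario (effective from the first scenario year).
NURSE_SHIFT_DOW: dict[str, dict[str, float]] = {
    "diagnostic_assessment": {
        "family_physician": 0.10, "nurse_practitioner": 0.05, "pediatrician": 0.10,
        "psychiatrist": 0.40, "psychologist": 0.25, "registered_nurse": 0.0,
        "social_worker": 0.10,
    },
    "clinical_assessment": {
        "family_physician": 0.10, "nurse_practitioner": 0.05, "pediatrician": 0.10,
        "psychiatrist": 0.05, "psychologist": 0.05, "registered_nurse": 0.40,
        "social_worker": 0.25,
    },
    "care_plan_development": {
        "family_physician": 0.05, "nurse_practitioner": 0.05, "pediatrician": 0.05,
        "psychiatrist": 0.15, "psychologist": 0.15, "registered_nurse": 0.40,
        "social_worker": 0.15,
    },
    "psychotherapy": {
        "family_physician": 0.15, "nurse_practitioner": 0.05, "pediatrician": 0.15,
        "psychiatrist": 0.15, "psychologist": 0.20, "registered_nurse": 0.02,
        "social_worker": 0.28,
    },
}

#: Published baseline clinical-focus levels (share of clinical FTE devoted to
#: anxiety/depression among school-aged children).
BASELINE_CLINICAL_FOCUS = {
    "family_physician": 0.004,
    "nurse_practitioner": 0.001,
    "pediatrician": 0.018,
    "psychiatrist": 0.041,
    "psychologist": 0.093,
    "registered_nurse": 0.001,
    "social_worker": 0.10,
}

#: Published increased clinical-focus levels (all professions but social workers).
INCREASED_CLINICAL_FOCUS = {
    "family_physician": 0.02,
    "nurse_practitioner": 0.02,
    "pediatrician": 0.10,
    "psychiatrist": 0.10,
    "psychologist": 0.15,
    "registered_nurse": 0.01,
}

#: Published 2018 baseline shortages used as calibration anchors for every
#: profession except social workers (whose anchor is the internally
#: consistent 89-FTE value of the clinical-focus scenario pair).
BASELINE_SHORTAGE_ANCHORS = {
    "family_physician": 83.0,
    "nurse_practitioner": 2.0,
    "pediatrician": 35.0,
    "psychiatrist": 28.0,
    "psychologist": 76.0,
    "registered_nurse": 1.0,
}

#: The self-contained worked-example pair: at clinical focus 0.10 the gap is
#: 89 FTE and at 0.05 it is 107 FTE, which pins requirement 125 FTE and
#: pre-focus supply (stock x participation x activity) 360 FTE.
WORKED_EXAMPLE_REQUIREMENT = 125.0
WORKED_EXAMPLE_PRE_FOCUS_SUPPLY = 360.0
SCENARIO_YEAR = 2019


# ---------------------------------------------------------------------------
# Random generator
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Size, seed and optional calibration targets for a random configuration."""

    n_professions: int = 7
    n_age_groups: int = 3
    n_sexes: int = 2
    n_health_states: int = 2
    n_services: int = 4
    start_year: int = 2018
    n_years: int = 15
    seed: int = 0
    total_population: float = 140_000.0
    #: profession -> (target baseline shortage in FTE, clinical focus)
    calibration_targets: dict[str, tuple[float, float]] | None = None


def generate(spec: FixtureSpec) -> ModelConfig:
    """Generate a valid, seeded random configuration per ``spec``.

    Identical specs (including seed) produce identical configurations.
    Division-of-work rows are Dirichlet draws (summing to one), prevalences
    are bounded so health states stay mutually exclusive, and every bound in
    the data model is respected by construction.
    """
    for name in ("n_professions", "n_age_groups", "n_sexes", "n_health_states",
                 "n_services", "n_years"):
        if getattr(spec, name) < 1:
            raise ValueError(f"{name} must be >= 1")
    rng = np.random.default_rng(spec.seed)

    bands = [
        AgeBand(f"a{5 + 5 * k:02d}_{9 + 5 * k:02d}", 5 + 5 * k, 9 + 5 * k)
        for k in range(spec.n_age_groups)
    ]
    sexes = ["female", "male", "sex3", "sex4"][: spec.n_sexes]
    states = [f"hs{k + 1}" for k in range(spec.n_health_states)]
    services = [f"svc{k + 1}" for k in range(spec.n_services)]
    professions = [f"prof{k + 1}" for k in range(spec.n_professions)]
    end_year = spec.start_year + spec.n_years - 1
    registry = StrataRegistry(bands, sexes, states, services, professions,
                              spec.start_year, end_year)

    # Population: fixed first-year total, smooth growth.
    cell_weights = rng.dirichlet(np.ones(len(bands) * len(sexes)))
    growth = float(rng.uniform(0.0, 0.01))
    pop_values: dict[tuple, float] = {}
    for k, (band, j) in enumerate((b, j) for b in bands for j in sexes):
        base = spec.total_population * float(cell_weights[k])
        for t in registry.years:
            pop_values[(band.label, j, t)] = base * (1.0 + growth) ** (t - spec.start_year)
    population = StratifiedRateTable(("age_group", "sex", "year"), pop_values,
                                     default=0.0, name="population")

    prevalence = StratifiedRateTable(
        ("health_state", "age_group", "sex"),
        {
            (h, b.label, j): float(rng.uniform(0.01, 0.3 / len(states)))
            for h in states for b in bands for j in sexes
        },
        default=0.0,
        name="prevalence",
    )
    service_levels = StratifiedRateTable(
        ("health_state", "service"),
        {(h, q): float(rng.uniform(0.5, 6.0)) for h in states for q in services},
        default=0.0,
        name="service_levels",
    )
    dow_values: dict[tuple, float] = {}
    for q in services:
        shares = rng.dirichlet(np.ones(len(professions)))
        for n, w in zip(professions, shares):
            dow_values[(q, n)] = float(w)
    division_of_work = StratifiedRateTable(("service", "profession"), dow_values,
                                           name="division_of_work")
    productivity = StratifiedRateTable(
        ("profession", "service"),
        {(n, q): float(rng.uniform(100.0, 2000.0)) for n in professions for q in services},
        name="productivity",
    )

    supply: dict[str, ProfessionSupplySpec] = {}
    for n in professions:
        grad_bands = bands[: min(2, len(bands))]
        grad_dist = {b.label: p for b, p in zip(grad_bands, ([1.0] if len(grad_bands) == 1 else [0.8, 0.2]))}
        supply[n] = ProfessionSupplySpec(
            initial_stock={b.label: float(rng.uniform(50.0, 500.0)) for b in bands},
            exit_rates=StratifiedRateTable(
                ("age_group",),
                {(b.label,): float(rng.uniform(0.01, 0.08)) for b in bands},
                name=f"exit_rates[{n}]",
            ),
            in_migration=StratifiedRateTable(
                ("age_group",),
                {(b.label,): float(rng.uniform(0.0, 10.0)) for b in grad_bands},
                default=0.0,
                name=f"in_migration[{n}]",
            ),
            participation=YearSeries.coerce(float(rng.uniform(0.7, 0.95))),
            activity=YearSeries.coerce(float(rng.uniform(0.6, 1.0))),
            clinical_focus=YearSeries.coerce(float(rng.uniform(0.02, 0.2))),
            pipeline=TrainingPipelineSpec(
                program_length_years=int(rng.integers(1, 6)),
                cohort_entries={spec.start_year: float(rng.uniform(20.0, 80.0))},
                attrition=YearSeries.coerce(float(rng.uniform(0.05, 0.2))),
                grad_out_migration=YearSeries.coerce(float(rng.uniform(0.1, 0.4))),
                grad_age_distribution=grad_dist,
            ),
        )

    config = ModelConfig(
        registry=registry,
        population=population,
        prevalence=prevalence,
        service_levels=service_levels,
        division_of_work=division_of_work,
        productivity=productivity,
        supply=supply,
    )
    if spec.calibration_targets:
        for n, (target_gap, focus) in spec.calibration_targets.items():
            if n not in config.supply:
                raise ValueError(f"calibration target for unknown profession {n!r}")
            config.supply[n].clinical_focus = YearSeries.coerce(float(focus))
            config = calibrate_shortage(config, n, float(target_gap), spec.start_year)
    violations = validate_config(config)
    if violations:  # pragma: no cover - construction guarantees validity
        raise ConfigValidationError(violations)
    return config


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def _ensure_profession_dim(table: StratifiedRateTable, professions: list[str]) -> StratifiedRateTable:
    """Expand a table to carry an explicit profession dimension."""
    if "profession" in table.dims:
        return table
    new_dims = tuple(d for d in ("health_state", "age_group", "sex", "service", "profession", "year")
                     if d in table.dims or d == "profession")
    values: dict[tuple, float] = {}
    pos = new_dims.index("profession")
    for key, v in table.values.items():
        for n in professions:
            new_key = key[:pos] + (n,) + key[pos:]
            values[new_key] = v
    return StratifiedRateTable(new_dims, values, default=table.default, name=table.name)


def calibrate_requirement(config: ModelConfig, profession: str, target_fte: float,
                          year: int) -> ModelConfig:
    """Rescale one profession's productivity so its requirement hits ``target_fte``.

    The FTE requirement is homogeneous of degree -1 in productivity, so a
    single scalar on the profession's productivity rows solves the target
    exactly; no other profession's requirement changes.
    """
    if profession not in config.registry.professions:
        raise CalibrationError(f"unknown profession {profession!r}")
    if target_fte < 0:
        raise CalibrationError(f"requirement target {target_fte!r} is negative")
    current = requirements_for_year(config, year)[profession]
    if abs(current - target_fte) <= 1e-12 * max(1.0, abs(target_fte)):
        return config.copy()
    if current <= 0.0:
        raise CalibrationError(
            f"{profession} has zero baseline requirement; nothing to rescale"
        )
    if target_fte == 0.0:
        raise CalibrationError("cannot calibrate a positive requirement to exactly zero")
    cfg = config.copy()
    cfg.productivity = _ensure_profession_dim(cfg.productivity, cfg.registry.professions)
    cfg.productivity.scale_where(current / target_fte, {"profession": profession})
    return cfg


def calibrate_pre_focus_supply(config: ModelConfig, profession: str, target_fte: float,
                               year: int) -> ModelConfig:
    """Rescale one profession's initial stock so stock x participation x activity
    equals ``target_fte`` in ``year``.

    The year-``year`` stock is affine in the initial-stock scale (entrant
    flows are unaffected), so the scale solves exactly in one step.
    """
    if profession not in config.supply:
        raise CalibrationError(f"no supply spec for {profession!r}")
    if target_fte < 0:
        raise CalibrationError(f"supply target {target_fte!r} is negative")

    def pre_focus(cfg: ModelConfig) -> float:
        traj, _ = supply_timeseries(cfg)
        spec = cfg.supply[profession]
        return (traj.stock_total(profession, year)
                * spec.participation.at(year) * spec.activity.at(year))

    u_full = pre_focus(config)
    zeroed = config.copy()
    zeroed.supply[profession].initial_stock = {
        a: 0.0 for a in zeroed.supply[profession].initial_stock
    }
    u_flows = pre_focus(zeroed)
    if u_full - u_flows <= 0:
        raise CalibrationError(
            f"{profession} has zero initial stock contribution in {year}; cannot rescale"
        )
    alpha = (target_fte - u_flows) / (u_full - u_flows)
    if alpha < 0:
        raise CalibrationError(
            f"target {target_fte} below the flow-only supply {u_flows}; "
            "would need negative stock"
        )
    cfg = config.copy()
    cfg.supply[profession].initial_stock = {
        a: v * alpha for a, v in cfg.supply[profession].initial_stock.items()
    }
    return cfg


def calibrate_shortage(config: ModelConfig, profession: str, target_shortage: float,
                       year: int) -> ModelConfig:
    """Rescale the requirement side so ``gap(profession, year) == target_shortage``.

    Holds the published division-of-work and clinical-focus values fixed and
    leaves every other profession's gap unchanged (the rescaled productivity
    rows belong to ``profession`` alone).
    """
    _, eff = supply_timeseries(config)
    supply_fte = eff[(profession, year)]
    required = supply_fte + target_shortage
    if required < 0:
        raise CalibrationError(
            f"target shortage {target_shortage} needs negative requirement "
            f"({required}) for {profession} in {year}"
        )
    return calibrate_requirement(config, profession, required, year)


# ---------------------------------------------------------------------------
# The packaged seven-profession configuration
# ---------------------------------------------------------------------------

_CHILD_BANDS = [AgeBand("05-09", 5, 9), AgeBand("10-14", 10, 14), AgeBand("15-19", 15, 19)]
_PROVIDER_BANDS = [AgeBand("25-34", 25, 34), AgeBand("35-44", 35, 44),
                   AgeBand("45-54", 45, 54), AgeBand("55-64", 55, 64)]

_EXIT_BY_BAND = {"25-34": 0.02, "35-44": 0.015, "45-54": 0.025, "55-64": 0.07}

#: Synthetic supply-side magnitudes per profession:
#: (stock by provider band, participation, activity, seats, program length,
#:  grad out-migration, in-migration by the two youngest provider bands)
_SUPPLY_PARAMS: dict[str, tuple[dict[str, float], float, float, float, int, float, tuple[float, float]]] = {
    "family_physician": ({"25-34": 200, "35-44": 280, "45-54": 300, "55-64": 220},
                         0.95, 0.95, 45, 2, 0.35, (8, 4)),
    "nurse_practitioner": ({"25-34": 30, "35-44": 35, "45-54": 35, "55-64": 20},
                           0.90, 0.85, 6, 2, 0.50, (1, 0.5)),
    "pediatrician": ({"25-34": 25, "35-44": 35, "45-54": 35, "55-64": 25},
                     0.95, 0.90, 6, 4, 0.50, (2, 1)),
    "psychiatrist": ({"25-34": 20, "35-44": 30, "45-54": 35, "55-64": 25},
                     0.95, 0.90, 5, 5, 0.40, (2, 1)),
    "psychologist": ({"25-34": 120, "35-44": 140, "45-54": 140, "55-64": 100},
                     0.90, 0.85, 8, 6, 0.30, (2, 1)),
    "registered_nurse": ({"25-34": 2200, "35-44": 2600, "45-54": 2400, "55-64": 1800},
                         0.85, 0.85, 300, 4, 0.25, (40, 20)),
    "social_worker": ({"25-34": 130, "35-44": 150, "45-54": 160, "55-64": 110},
                      0.90, 0.85, 20, 2, 0.40, (5, 2)),
}

#: Synthetic productivity (services per FTE per year) by service type.
_PRODUCTIVITY_BY_SERVICE = {
    "diagnostic_assessment": 400.0,
    "clinical_assessment": 800.0,
    "care_plan_development": 600.0,
    "psychotherapy": 1000.0,
}

#: Synthetic annual services per prevalent case by (health state, service).
#: Psychotherapy levels are population averages (not every prevalent case
#: receives a full course); together with the productivity rates they set the
#: relative FTE weight of the four services, chosen so the published share
#: shifts reproduce the published direction of every profession's gap change.
_SERVICE_LEVELS = {
    ("anxiety", "diagnostic_assessment"): 1.0,
    ("anxiety", "clinical_assessment"): 2.0,
    ("anxiety", "care_plan_development"): 1.0,
    ("anxiety", "psychotherapy"): 3.0,
    ("depression", "diagnostic_assessment"): 1.0,
    ("depression", "clinical_assessment"): 2.0,
    ("depression", "care_plan_development"): 1.0,
    ("depression", "psychotherapy"): 4.0,
}

#: Synthetic prevalences by (health state, child age band).
_PREVALENCE = {
    ("anxiety", "05-09"): 0.040, ("anxiety", "10-14"): 0.065, ("anxiety", "15-19"): 0.090,
    ("depression", "05-09"): 0.015, ("depression", "10-14"): 0.050, ("depression", "15-19"): 0.080,
}


def _build_packaged_config() -> ModelConfig:
    registry = StrataRegistry(
        age_groups=_CHILD_BANDS + _PROVIDER_BANDS,
        sexes=["female", "male"],
        health_states=["anxiety", "depression"],
        services=list(SERVICES),
        professions=list(PROFESSIONS),
        start_year=2018,
        end_year=2032,
    )

    band_weights = {"05-09": 0.32, "10-14": 0.33, "15-19": 0.35}
    sex_weights = {"female": 0.49, "male": 0.51}
    growth = 0.003  # medium-growth style projection, synthetic
    pop_values: dict[tuple, float] = {}
    for a, wa in band_weights.items():
        for j, wj in sex_weights.items():
            base = 140_000.0 * wa * wj
            for t in registry.years:
                pop_values[(a, j, t)] = base * (1.0 + growth) ** (t - 2018)
    population = StratifiedRateTable(("age_group", "sex", "year"), pop_values,
                                     default=0.0, name="population")

    prevalence = StratifiedRateTable(
        ("health_state", "age_group"),
        {(h, a): v for (h, a), v in _PREVALENCE.items()},
        default=0.0,
        name="prevalence",
    )
    service_levels = StratifiedRateTable(
        ("health_state", "service"),
        {k: v for k, v in _SERVICE_LEVELS.items()},
        default=0.0,
        name="service_levels",
    )
    division_of_work = StratifiedRateTable(
        ("service", "profession"),
        {(q, n): w for q, shares in BASELINE_DOW.items() for n, w in shares.items()},
        name="division_of_work",
    )
    productivity = StratifiedRateTable(
        ("profession", "service"),
        {(n, q): _PRODUCTIVITY_BY_SERVICE[q] for n in PROFESSIONS for q in SERVICES},
        name="productivity",
    )

    all_band_labels = [b.label for b in registry.age_groups]
    supply: dict[str, ProfessionSupplySpec] = {}
    for n, (stock, part, act, seats, length, out_mig, (mig_a, mig_b)) in _SUPPLY_PARAMS.items():
        supply[n] = ProfessionSupplySpec(
            initial_stock={a: float(stock.get(a, 0.0)) for a in all_band_labels},
            exit_rates=StratifiedRateTable(
                ("age_group",),
                {(a,): float(_EXIT_BY_BAND.get(a, 0.0)) for a in all_band_labels},
                name=f"exit_rates[{n}]",
            ),
            in_migration=StratifiedRateTable(
                ("age_group",),
                {("25-34",): float(mig_a), ("35-44",): float(mig_b)},
                default=0.0,
                name=f"in_migration[{n}]",
            ),
            participation=YearSeries.coerce(part),
            activity=YearSeries.coerce(act),
            clinical_focus=YearSeries.coerce(BASELINE_CLINICAL_FOCUS[n]),
            pipeline=TrainingPipelineSpec(
                program_length_years=length,
                cohort_entries={2018: float(seats)},
                attrition=YearSeries.coerce(0.10),
                grad_out_migration=YearSeries.coerce(out_mig),
                grad_age_distribution={"25-34": 0.85, "35-44": 0.15},
            ),
        )

    return ModelConfig(
        registry=registry,
        population=population,
        prevalence=prevalence,
        service_levels=service_levels,
        division_of_work=division_of_work,
        productivity=productivity,
        supply=supply,
    )


def packaged_scenarios() -> list[Scenario]:
    """The five packaged policy scenarios, effective from the scenario year."""
    yr = SCENARIO_YEAR
    shift_overrides = [
        Override("division_of_work", {"service": q, "profession": n}, yr, w)
        for q, shares in NURSE_SHIFT_DOW.items()
        for n, w in shares.items()
    ]
    return [
        Scenario("status_quo", []),
        Scenario("dow_shift_to_nurses", shift_overrides),
        Scenario("dow_no_fp_psychotherapy", [
            Override("division_of_work",
                     {"service": "psychotherapy", "profession": "family_physician"}, yr, 0.0),
            Override("division_of_work",
                     {"service": "psychotherapy", "profession": "psychiatrist"}, yr, 0.31),
        ]),
        Scenario("focus_increase_all_but_sw", [
            Override("clinical_focus", {"profession": n}, yr, f)
            for n, f in INCREASED_CLINICAL_FOCUS.items()
        ]),
        Scenario("focus_reduce_sw", [
            Override("clinical_focus", {"profession": "social_worker"}, yr, 0.05),
        ]),
    ]


@functools.lru_cache(maxsize=1)
def _calibrated_packaged_config() -> ModelConfig:
    config = _build_packaged_config()
    # Pin the social-worker scenario-year arithmetic to the published
    # clinical-focus pair: pre-focus supply 360 FTE and requirement 125 FTE
    # give gap 89 at focus 0.10 and 107 at focus 0.05.
    config = calibrate_pre_focus_supply(
        config, "social_worker", WORKED_EXAMPLE_PRE_FOCUS_SUPPLY, SCENARIO_YEAR
    )
    config = calibrate_requirement(
        config, "social_worker", WORKED_EXAMPLE_REQUIREMENT, SCENARIO_YEAR
    )
    # Anchor the remaining professions to the published 2018 baseline shortages.
    for n, gap in BASELINE_SHORTAGE_ANCHORS.items():
        config = calibrate_shortage(config, n, gap, 2018)
    violations = validate_config(config)
    if violations:  # pragma: no cover
        raise ConfigValidationError(violations)
    return config


def packaged_fixture() -> tuple[ModelConfig, list[Scenario]]:
    """The calibrated seven-profession configuration and its five scenarios."""
    return _calibrated_packaged_config().copy(), packaged_scenarios()


# ---------------------------------------------------------------------------
# Minimal worked example (one profession)
# ---------------------------------------------------------------------------


def worked_example() -> tuple[ModelConfig, Scenario]:
    """One-profession configuration behind the 89 -> 107 FTE focus pair.

    Social workers with FTE requirement 125, pre-focus supply 360 and clinical
    focus 0.10 in the scenario year; the returned scenario halves the focus to
    0.05 from that year on.  All other magnitudes are synthetic and the two
    targets are imposed by exact linear calibration.
    """
    registry = StrataRegistry(
        age_groups=[AgeBand("05-19", 5, 19), AgeBand("25-64", 25, 64)],
        sexes=["all"],
        health_states=["anxiety_depression"],
        services=["mental_health_service"],
        professions=["social_worker"],
        start_year=2018,
        end_year=2032,
    )
    config = ModelConfig(
        registry=registry,
        population=StratifiedRateTable(("age_group",), {("05-19",): 140_000.0},
                                       default=0.0, name="population"),
        prevalence=StratifiedRateTable(("health_state", "age_group"),
                                       {("anxiety_depression", "05-19"): 0.11},
                                       default=0.0, name="prevalence"),
        service_levels=StratifiedRateTable(("service",), {("mental_health_service",): 5.0},
                                           default=0.0, name="service_levels"),
        division_of_work=StratifiedRateTable(("profession",), {("social_worker",): 1.0},
                                             name="division_of_work"),
        productivity=StratifiedRateTable(("profession", "service"),
                                         {("social_worker", "mental_health_service"): 500.0},
                                         name="productivity"),
        supply={
            "social_worker": ProfessionSupplySpec(
                initial_stock={"05-19": 0.0, "25-64": 500.0},
                exit_rates=StratifiedRateTable(("age_group",),
                                               {("05-19",): 0.0, ("25-64",): 0.03},
                                               name="exit_rates[social_worker]"),
                in_migration=StratifiedRateTable(("age_group",), {("25-64",): 10.0},
                                                 default=0.0,
                                                 name="in_migration[social_worker]"),
                participation=YearSeries.coerce(0.9),
                activity=YearSeries.coerce(0.8),
                clinical_focus=YearSeries.coerce(0.10),
                pipeline=TrainingPipelineSpec(
                    program_length_years=2,
                    cohort_entries={2018: 30.0},
                    attrition=YearSeries.coerce(0.10),
                    grad_out_migration=YearSeries.coerce(0.25),
                    grad_age_distribution={"25-64": 1.0},
                ),
            )
        },
    )
    config = calibrate_pre_focus_supply(
        config, "social_worker", WORKED_EXAMPLE_PRE_FOCUS_SUPPLY, SCENARIO_YEAR
    )
    config = calibrate_requirement(
        config, "social_worker", WORKED_EXAMPLE_REQUIREMENT, SCENARIO_YEAR
    )
    scenario = Scenario(
        "reduced_clinical_focus",
        [Override("clinical_focus", {"profession": "social_worker"}, SCENARIO_YEAR, 0.05)],
    )
    return config, scenario
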