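"""Policy scenarios as time-effective parameter overrides.

A :class:`Scenario` is an ordered list of :class:`Override` records.  Each
override replaces one parameter — selected by a partial index tuple — with an
absolute value for every year at and after its effective year (a persisting
step change; years before are untouched).  This mirrors how planners state
interventions: "beginning in <year>, parameter X becomes <value>".

Supported targets:

* whole-model tables: ``population``, ``prevalence``, ``service_levels``,
  ``division_of_work``, ``productivity`` (selector = any subset of the
  table's dimensions);
* per-profession supply scalars: ``participation``, ``activity``,
  ``clinical_focus``, ``attrition``, ``grad_out_migration`` (selector must
  name the profession);
* ``seats`` — the training-program intake from the effective year on;
* per-profession tables: ``exit_rates``, ``in_migration``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .domain import ModelConfig, StratifiedRateTable, validate_config
from .errors import (
    ConfigValidationError,
    ConflictingOverridesError,
    HrhSimError,
    ParameterNotSpecifiedError,
    ScenarioError,
)
from .reporting import compute_gap
from .requirements import requirements_timeseries
from .supply import StockTrajectory, supply_timeseries

SUPPLY_SCALAR_TARGETS = ("participation", "activity", "clinical_focus",
                         "attrition", "grad_out_migration")
SUPPLY_TABLE_DIMS = {"exit_rates": ("age_group", "year"),
                     "in_migration": ("age_group", "year")}


@dataclass(frozen=True)
class Override:
    """One absolute parameter replacement effective from a given year."""

    target: str
    selector: dict = field(default_factory=dict)
    effective_year: int = 0
    value: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "selector", dict(self.selector))

    def key(self) -> tuple:
        return (self.target, tuple(sorted(self.selector.items())), self.effective_year)


@dataclass
class Scenario:
    """A named, ordered list of overrides; an empty list is the baseline."""

    name: str
    overrides: list[Override] = field(default_factory=list)


def _expanded_with_override(
    table: StratifiedRateTable,
    registry,
    role_dims: tuple[str, ...],
    selector: dict,
    effective_year: int,
    value: float,
) -> StratifiedRateTable:
    """Return a new table equal to ``table`` except on the override slice.

    The result's dimensions are the table's own plus any selector dimensions
    plus ``year`` (so a step change can coexist with year-broadcast baseline
    values).  Entries missing from the source (no default) stay missing.
    """
    bad = [d for d in selector if d not in role_dims]
    if bad:
        raise ScenarioError(f"selector dimensions {bad} not valid for this target")
    for d, label in selector.items():
        if label not in registry.labels(d):
            raise ScenarioError(f"unknown {d} label {label!r} in selector")
    new_dims = tuple(d for d in role_dims if d in table.dims or d in selector or d == "year")
    label_lists = [registry.labels(d) for d in new_dims]
    values: dict[tuple, float] = {}
    for combo in itertools.product(*label_lists):
        coords = dict(zip(new_dims, combo))
        if coords["year"] >= effective_year and all(
            coords[d] == v for d, v in selector.items()
        ):
            values[combo] = float(value)
        else:
            try:
                values[combo] = table.lookup(coords)
            except ParameterNotSpecifiedError:
                pass
    return StratifiedRateTable(dims=new_dims, values=values,
                               default=table.default, name=table.name)


def _apply_override(config: ModelConfig, ov: Override) -> None:
    reg = config.registry
    if ov.target in ModelConfig.TABLE_ROLE_DIMS:
        role_dims = ModelConfig.TABLE_ROLE_DIMS[ov.target]
        setattr(
            config,
            ov.target,
            _expanded_with_override(
                config.table(ov.target), reg, role_dims,
                ov.selector, ov.effective_year, ov.value,
            ),
        )
        return

    profession = ov.selector.get("profession")
    if profession is None:
        raise ScenarioError(f"override of {ov.target!r} requires a profession selector")
    if profession not in config.supply:
        raise ScenarioError(f"no supply spec for profession {profession!r}")
    spec = config.supply[profession]

    if ov.target in ("participation", "activity", "clinical_focus"):
        series = getattr(spec, ov.target)
        setattr(spec, ov.target, series.override_from(ov.effective_year, ov.value))
    elif ov.target in ("attrition", "grad_out_migration"):
        series = getattr(spec.pipeline, ov.target)
        setattr(spec.pipeline, ov.target, series.override_from(ov.effective_year, ov.value))
    elif ov.target == "seats":
        kept = {y: c for y, c in spec.pipeline.cohort_entries.items() if y < ov.effective_year}
        kept[int(ov.effective_year)] = float(ov.value)
        spec.pipeline.cohort_entries = kept
    elif ov.target in SUPPLY_TABLE_DIMS:
        selector = {d: v for d, v in ov.selector.items() if d != "profession"}
        setattr(
            spec,
            ov.target,
            _expanded_with_override(
                getattr(spec, ov.target), reg, SUPPLY_TABLE_DIMS[ov.target],
                selector, ov.effective_year, ov.value,
            ),
        )
    else:
        raise ScenarioError(f"unknown override target {ov.target!r}")


def apply_scenario(config: ModelConfig, scenario: Scenario) -> ModelConfig:
    """Return a new config with every override applied; the input is untouched.

    The result is re-validated: an override set that breaks an invariant
    (e.g. division-of-work shares no longer summing to one from the effective
    year) raises :class:`ConfigValidationError` naming the offending tuples.
    """
    cfg = config.copy()
    reg = cfg.registry
    seen = set()
    for ov in scenario.overrides:
        key = ov.key()
        if key in seen:
            raise ConflictingOverridesError(
                f"duplicate override for {ov.target} {ov.selector} @ {ov.effective_year}"
            )
        seen.add(key)
        if not (reg.start_year <= ov.effective_year <= reg.end_year):
            raise ScenarioError(
                f"effective year {ov.effective_year} outside horizon "
                f"[{reg.start_year}, {reg.end_year}]"
            )
        _apply_override(cfg, ov)
    violations = validate_config(cfg)
    if violations:
        raise ConfigValidationError(violations)
    return cfg


@dataclass
class ScenarioRun:
    """Everything produced by simulating one scenario (or its error)."""

    name: str
    config: ModelConfig | None = None
    requirements: dict[tuple[str, int], float] | None = None
    supply: dict[tuple[str, int], float] | None = None
    trajectory: StockTrajectory | None = None
    gaps: "GapSeries | None" = None
    error: str | None = None


def simulate(config: ModelConfig, name: str = "baseline") -> ScenarioRun:
    """Run requirements and supply projections and pair them into gaps."""
    req = requirements_timeseries(config)
    traj, sup = supply_timeseries(config)
    gaps = compute_gap(req, sup)
    return ScenarioRun(name=name, config=config, requirements=req,
                       supply=sup, trajectory=traj, gaps=gaps)


def run(config: ModelConfig, scenarios: list[Scenario]) -> dict[str, ScenarioRun]:
    """Simulate each scenario against ``config``; deterministic throughout.

    A failing scenario is reported in its :class:`ScenarioRun` ``error`` field
    and does not stop the remaining scenarios.
    """
    names = [s.name for s in scenarios]
    if len(set(names)) != len(names):
        raise ScenarioError("scenario names must be unique within a run")
    results: dict[str, ScenarioRun] = {}
    for scenario in scenarios:
        try:
            cfg = apply_scenario(config, scenario)
            results[scenario.name] = simulate(cfg, scenario.name)
        except HrhSimError as e:
            results[scenario.name] = ScenarioRun(name=scenario.name, error=str(e))
    return results
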