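"""Core data model for needs-based, multi-professional workforce planning.

The simulator compares two quantities per profession ``n`` and year ``t``:

* the FTE *requirement* ``N[n, t]``, derived from population demography,
  condition prevalence, planned service levels, the division of work across
  professions and per-profession productivity; and
* the effective FTE *supply* ``N'[n, t] = S * D * A * F`` where ``S`` is the
  licensed stock projected by a stock-and-flow model, ``D`` participation,
  ``A`` activity (clinical FTE per participating provider) and ``F`` clinical
  focus (share of clinical time devoted to the planned population/conditions).

Every parameter is carried by a :class:`StratifiedRateTable`, a sparse mapping
from index tuples over a subset of the six planning dimensions to real values,
with broadcast semantics over dimensions the table does not use.  This module
defines those containers plus :func:`validate_config`, which returns invariant
violations as data rather than raising.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import ParameterNotSpecifiedError, PipelineNotSeededError

#: Canonical ordering of planning dimensions; every table's ``dims`` is an
#: ordered subset of this tuple and CSV columns follow the same order.
DIM_ORDER = ("health_state", "age_group", "sex", "service", "profession", "year")


@dataclass(frozen=True)
class AgeBand:
    """A labelled, inclusive age band, e.g. ``AgeBand("25-34", 25, 34)``."""

    label: str
    lower: int
    upper: int

    @property
    def width(self) -> int:
        return self.upper - self.lower + 1


@dataclass
class StrataRegistry:
    """Registry of the strata labels a configuration may index over.

    Age bands must be ordered and non-overlapping; years form the contiguous
    inclusive range ``[start_year, end_year]``.  The same age-band list serves
    both the population (requirements side) and providers (supply side); bands
    used by only one side simply carry zeros on the other.
    """

    age_groups: list[AgeBand]
    sexes: list[str]
    health_states: list[str]
    services: list[str]
    professions: list[str]
    start_year: int
    end_year: int

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.end_year + 1))

    @property
    def age_labels(self) -> list[str]:
        return [b.label for b in self.age_groups]

    def band(self, label: str) -> AgeBand:
        for b in self.age_groups:
            if b.label == label:
                return b
        raise KeyError(f"unknown age band {label!r}")

    def labels(self, dim: str) -> list:
        if dim == "health_state":
            return list(self.health_states)
        if dim == "age_group":
            return self.age_labels
        if dim == "sex":
            return list(self.sexes)
        if dim == "service":
            return list(self.services)
        if dim == "profession":
            return list(self.professions)
        if dim == "year":
            return self.years
        raise KeyError(f"unknown dimension {dim!r}")


@dataclass
class StratifiedRateTable:
    """Sparse parameter table over a subset of the planning dimensions.

    ``values`` maps full index tuples (ordered as in ``dims``) to reals.
    Lookups project the query coordinates onto ``dims``: dimensions absent
    from the table are ignored, so a table over ``(service, profession)``
    answers queries for any age group, sex, health state or year (broadcast).
    A missing tuple resolves to ``default`` when set, otherwise raises
    :class:`ParameterNotSpecifiedError`.
    """

    dims: tuple[str, ...]
    values: dict[tuple, float] = field(default_factory=dict)
    default: float | None = None
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        dims = tuple(self.dims)
        unknown = [d for d in dims if d not in DIM_ORDER]
        if unknown:
            raise ValueError(f"unknown dimensions {unknown} in table {self.name!r}")
        ordered = tuple(d for d in DIM_ORDER if d in dims)
        if ordered != dims:
            # Reorder keys into canonical dimension order.
            perm = [dims.index(d) for d in ordered]
            self.values = {
                tuple(k[p] for p in perm): float(v) for k, v in self.values.items()
            }
        else:
            self.values = {tuple(k): float(v) for k, v in self.values.items()}
        self.dims = ordered
        if self.default is not None:
            self.default = float(self.default)

    # -- access ----------------------------------------------------------

    def key_for(self, coords: Mapping[str, object]) -> tuple:
        try:
            return tuple(coords[d] for d in self.dims)
        except KeyError as e:
            raise KeyError(
                f"query for table {self.name!r} missing coordinate {e.args[0]!r}"
            ) from None

    def lookup(self, coords: Mapping[str, object]) -> float:
        """Value at ``coords`` projected onto this table's dimensions."""
        key = self.key_for(coords)
        try:
            return self.values[key]
        except KeyError:
            if self.default is not None:
                return self.default
            raise ParameterNotSpecifiedError(self.name, dict(zip(self.dims, key))) from None

    def set_value(self, coords: Mapping[str, object], value: float) -> None:
        self.values[self.key_for(coords)] = float(value)

    def scale_where(self, factor: float, selector: Mapping[str, object]) -> None:
        """Multiply stored entries matching ``selector`` (a partial index) by ``factor``."""
        idx = {self.dims.index(d): v for d, v in selector.items() if d in self.dims}
        for key in list(self.values):
            if all(key[i] == v for i, v in idx.items()):
                self.values[key] = self.values[key] * factor

    def items(self) -> Iterator[tuple[tuple, float]]:
        return iter(self.values.items())

    # -- records ---------------------------------------------------------

    def to_records(self) -> list[dict]:
        recs = [dict(zip(self.dims, k)) | {"value": v} for k, v in sorted(self.values.items())]
        return recs

    @classmethod
    def from_records(
        cls,
        dims: Iterable[str],
        records: Iterable[Mapping],
        default: float | None = None,
        name: str = "",
    ) -> "StratifiedRateTable":
        dims = tuple(dims)
        values = {tuple(r[d] for d in dims): float(r["value"]) for r in records}
        return cls(dims=dims, values=values, default=default, name=name)


def lookup(table: StratifiedRateTable, coords: Mapping[str, object]) -> float:
    """Module-level alias for :meth:`StratifiedRateTable.lookup`."""
    return table.lookup(coords)


@dataclass
class YearSeries:
    """A per-year scalar parameter with step semantics.

    ``points`` maps years to values; the value at year ``t`` is the value at
    the greatest configured year ``<= t`` (or the earliest configured value
    for years before it).  A constant parameter is a single point.
    """

    points: dict[int, float]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("YearSeries requires at least one point")
        self.points = {int(y): float(v) for y, v in self.points.items()}

    @classmethod
    def coerce(cls, value) -> "YearSeries":
        if isinstance(value, YearSeries):
            return value
        if isinstance(value, Mapping):
            return cls(dict(value))
        return cls({0: float(value)})

    def at(self, year: int) -> float:
        keys = sorted(self.points)
        chosen = keys[0]
        for k in keys:
            if k <= year:
                chosen = k
            else:
                break
        return self.points[chosen]

    def override_from(self, year: int, value: float) -> "YearSeries":
        """Step change: ``value`` for all years >= ``year``, earlier points kept."""
        kept = {y: v for y, v in self.points.items() if y < year}
        kept[int(year)] = float(value)
        return YearSeries(kept)


@dataclass
class TrainingPipelineSpec:
    """Entry-to-practice training program for one profession.

    ``cohort_entries`` maps entry years to entering student counts (seats
    filled) with the same step semantics as :class:`YearSeries`; cohorts that
    entered before the earliest configured year are seeded at the earliest
    configured value when ``seed_steady_state`` is true (a steady pipeline),
    otherwise querying them raises :class:`PipelineNotSeededError`.
    ``attrition`` is applied once to the whole cohort, indexed by graduation
    year; ``grad_out_migration`` is the share of graduates who never enter
    local practice; ``grad_age_distribution`` splits graduates across age
    bands and must sum to one.
    """

    program_length_years: int
    cohort_entries: dict[int, float]
    attrition: YearSeries
    grad_out_migration: YearSeries
    grad_age_distribution: dict[str, float]
    seed_steady_state: bool = True

    def __post_init__(self) -> None:
        self.program_length_years = int(self.program_length_years)
        self.cohort_entries = {int(y): float(c) for y, c in self.cohort_entries.items()}
        self.attrition = YearSeries.coerce(self.attrition)
        self.grad_out_migration = YearSeries.coerce(self.grad_out_migration)
        self.grad_age_distribution = {a: float(p) for a, p in self.grad_age_distribution.items()}

    def entries_for(self, entry_year: int) -> float:
        """Students entering in ``entry_year`` (step-extended seat counts)."""
        if not self.cohort_entries:
            raise PipelineNotSeededError(entry_year)
        keys = sorted(self.cohort_entries)
        if entry_year < keys[0]:
            if self.seed_steady_state:
                return self.cohort_entries[keys[0]]
            raise PipelineNotSeededError(entry_year)
        chosen = keys[0]
        for k in keys:
            if k <= entry_year:
                chosen = k
            else:
                break
        return self.cohort_entries[chosen]


@dataclass
class ProfessionSupplySpec:
    """Complete supply-side parameterization for one profession."""

    initial_stock: dict[str, float]
    exit_rates: StratifiedRateTable
    in_migration: StratifiedRateTable
    participation: YearSeries
    activity: YearSeries
    clinical_focus: YearSeries
    pipeline: TrainingPipelineSpec

    def __post_init__(self) -> None:
        self.initial_stock = {a: float(v) for a, v in self.initial_stock.items()}
        self.participation = YearSeries.coerce(self.participation)
        self.activity = YearSeries.coerce(self.activity)
        self.clinical_focus = YearSeries.coerce(self.clinical_focus)


@dataclass
class Options:
    """Model-wide switches and tolerances."""

    aging_enabled: bool = False
    dow_tolerance: float = 1e-9
    renormalize_dow: bool = False


@dataclass
class ModelConfig:
    """A complete baseline model: registry, parameter tables and supply specs."""

    registry: StrataRegistry
    population: StratifiedRateTable
    prevalence: StratifiedRateTable
    service_levels: StratifiedRateTable
    division_of_work: StratifiedRateTable
    productivity: StratifiedRateTable
    supply: dict[str, ProfessionSupplySpec]
    options: Options = field(default_factory=Options)

    #: table role -> full dimension set the role may use
    TABLE_ROLE_DIMS = {
        "population": ("age_group", "sex", "year"),
        "prevalence": ("health_state", "age_group", "sex", "year"),
        "service_levels": ("health_state", "age_group", "sex", "service", "year"),
        "division_of_work": ("health_state", "age_group", "sex", "service", "profession", "year"),
        "productivity": ("profession", "service", "year"),
    }

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    def table(self, role: str) -> StratifiedRateTable:
        return getattr(self, role)


# ---------------------------------------------------------------------------
# Gap series
# ---------------------------------------------------------------------------


@dataclass
class GapRecord:
    requirement_fte: float
    supply_fte: float
    gap_fte: float


@dataclass
class GapSeries:
    """Per (profession, year): FTE requirement, effective supply and gap.

    Gap is ``requirement - supply``; positive values are shortages, negative
    values surpluses.
    """

    records: dict[tuple[str, int], GapRecord]

    def gap(self, profession: str, year: int) -> float:
        return self.records[(profession, year)].gap_fte

    def requirement(self, profession: str, year: int) -> float:
        return self.records[(profession, year)].requirement_fte

    def supply(self, profession: str, year: int) -> float:
        return self.records[(profession, year)].supply_fte

    def professions(self) -> list[str]:
        seen: dict[str, None] = {}
        for (n, _t) in self.records:
            seen.setdefault(n)
        return list(seen)

    def years(self) -> list[int]:
        return sorted({t for (_n, t) in self.records})

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "profession": n,
                "year": t,
                "requirement_fte": r.requirement_fte,
                "supply_fte": r.supply_fte,
                "gap_fte": r.gap_fte,
            }
            for (n, t), r in self.records.items()
        ]
        return pd.DataFrame(rows, columns=["profession", "year", "requirement_fte", "supply_fte", "gap_fte"])


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One invariant violation: rule name, offending location, message."""

    rule: str
    where: tuple
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.where}: {self.message}"


def _check_bounds(table: StratifiedRateTable, role: str, lo, hi, out: list[Violation],
                  lo_strict: bool = False) -> None:
    def bad(v: float) -> bool:
        if lo is not None and (v <= lo if lo_strict else v < lo):
            return True
        return hi is not None and v > hi

    for key, v in table.items():
        if not math.isfinite(v) or bad(v):
            out.append(Violation("bounds", (role,) + key, f"value {v!r} outside bounds"))
    if table.default is not None and bad(table.default):
        out.append(Violation("bounds", (role, "<default>"), f"default {table.default!r} outside bounds"))


def _check_labels(table: StratifiedRateTable, role: str, registry: StrataRegistry,
                  out: list[Violation]) -> None:
    allowed = {d: set(registry.labels(d)) for d in table.dims}
    for key in table.values:
        for d, component in zip(table.dims, key):
            if component not in allowed[d]:
                out.append(Violation("unknown_label", (role,) + key,
                                     f"{component!r} is not a registered {d}"))
                break


def validate_config(config: ModelConfig) -> list[Violation]:
    """Collect every invariant violation in ``config``; empty list means valid.

    Pure function: never mutates the config and never raises for data
    problems — violations are returned as records.
    """
    out: list[Violation] = []
    reg = config.registry

    # Registry invariants.
    for dim in ("age_group", "sex", "health_state", "service", "profession"):
        labels = reg.labels(dim)
        if len(set(labels)) != len(labels):
            out.append(Violation("duplicate_labels", (dim,), "labels not unique"))
    for a, b in zip(reg.age_groups, reg.age_groups[1:]):
        if b.lower <= a.upper:
            out.append(Violation("age_bands", (a.label, b.label),
                                 "age bands overlap or are out of order"))
    for band in reg.age_groups:
        if band.upper < band.lower:
            out.append(Violation("age_bands", (band.label,), "upper bound below lower bound"))
    if reg.end_year < reg.start_year:
        out.append(Violation("years", (reg.start_year, reg.end_year), "empty year range"))

    # Table dimension roles and bounds.
    role_bounds = {
        "population": (0.0, None, False),
        "prevalence": (0.0, 1.0, False),
        "service_levels": (0.0, None, False),
        "division_of_work": (0.0, 1.0, False),
        "productivity": (0.0, None, True),  # strictly positive
    }
    for role, (lo, hi, strict) in role_bounds.items():
        table = config.table(role)
        allowed = ModelConfig.TABLE_ROLE_DIMS[role]
        extra = [d for d in table.dims if d not in allowed]
        if extra:
            out.append(Violation("dims", (role,), f"dimensions {extra} not allowed for {role}"))
            continue
        _check_labels(table, role, reg, out)
        _check_bounds(table, role, lo, hi, out, lo_strict=strict)

    # Prevalences of the (mutually exclusive) health states sum to <= 1.
    try:
        for band in reg.age_groups:
            for j in reg.sexes:
                for t in reg.years:
                    vals = []
                    missing = False
                    for h in reg.health_states:
                        try:
                            vals.append(config.prevalence.lookup(
                                {"health_state": h, "age_group": band.label, "sex": j, "year": t}))
                        except ParameterNotSpecifiedError:
                            missing = True
                    if missing:
                        continue  # flagged at use time by the requirements engine
                    if math.fsum(vals) > 1.0 + 1e-9:
                        out.append(Violation("prevalence_sum", (band.label, j, t),
                                             f"health-state prevalences sum to {math.fsum(vals)!r} > 1"))
    except Exception as e:  # pragma: no cover - defensive
        out.append(Violation("prevalence_sum", (), f"could not evaluate: {e}"))

    # Division-of-work shares sum to 1 wherever planned services are nonzero.
    # Violations are deduplicated at the granularity of the table itself so a
    # single bad stored share yields a single violation.
    tol = config.options.dow_tolerance
    dow = config.division_of_work
    group_dims = tuple(d for d in dow.dims if d != "profession")
    seen_groups: set[tuple] = set()
    for h in reg.health_states:
        for band in reg.age_groups:
            for j in reg.sexes:
                for q in reg.services:
                    for t in reg.years:
                        coords = {"health_state": h, "age_group": band.label,
                                  "sex": j, "service": q, "year": t}
                        try:
                            level = config.service_levels.lookup(coords)
                        except ParameterNotSpecifiedError:
                            out.append(Violation("parameter_not_specified",
                                                 ("service_levels", h, band.label, j, q, t),
                                                 "no value and no default"))
                            continue
                        if level <= 0:
                            continue
                        group = tuple(coords.get(d) for d in group_dims)
                        if group in seen_groups:
                            continue
                        shares = []
                        bad_lookup = False
                        for n in reg.professions:
                            try:
                                shares.append(dow.lookup(coords | {"profession": n}))
                            except ParameterNotSpecifiedError:
                                out.append(Violation("parameter_not_specified",
                                                     ("division_of_work", h, band.label, j, q, n, t),
                                                     "no value and no default"))
                                bad_lookup = True
                                break
                        seen_groups.add(group)
                        if bad_lookup:
                            continue
                        total = math.fsum(shares)
                        if abs(total - 1.0) > tol:
                            out.append(Violation("division_of_work_sum", group,
                                                 f"shares sum to {total!r} (dims {group_dims})"))

    # Supply-side invariants.
    age_set = set(reg.age_labels)
    for n, spec in config.supply.items():
        if n not in reg.professions:
            out.append(Violation("unknown_profession", (n,), "supply spec for unregistered profession"))
            continue
        for a, v in spec.initial_stock.items():
            if a not in age_set:
                out.append(Violation("unknown_label", ("initial_stock", n, a), "unknown age band"))
            if v < 0:
                out.append(Violation("bounds", ("initial_stock", n, a), f"stock {v!r} < 0"))
        missing_bands = age_set - set(spec.initial_stock)
        if missing_bands:
            out.append(Violation("initial_stock_coverage", (n,),
                                 f"missing age bands {sorted(missing_bands)} (zeros allowed but must be explicit)"))
        _check_labels(spec.exit_rates, f"exit_rates[{n}]", reg, out)
        _check_bounds(spec.exit_rates, f"exit_rates[{n}]", 0.0, 1.0, out)
        _check_labels(spec.in_migration, f"in_migration[{n}]", reg, out)
        _check_bounds(spec.in_migration, f"in_migration[{n}]", 0.0, None, out)
        for label, series, lo, hi, strict in (
            ("participation", spec.participation, 0.0, 1.0, False),
            ("activity", spec.activity, 0.0, 1.5, True),
            ("clinical_focus", spec.clinical_focus, 0.0, 1.0, False),
        ):
            for y, v in series.points.items():
                low_bad = v <= lo if strict else v < lo
                if low_bad or v > hi:
                    out.append(Violation("bounds", (label, n, y), f"value {v!r} outside bounds"))
        pipe = spec.pipeline
        if pipe.program_length_years < 1:
            out.append(Violation("bounds", ("program_length_years", n),
                                 f"{pipe.program_length_years!r} < 1"))
        for y, c in pipe.cohort_entries.items():
            if c < 0:
                out.append(Violation("bounds", ("cohort_entries", n, y), f"{c!r} < 0"))
        for label, series in (("attrition", pipe.attrition),
                              ("grad_out_migration", pipe.grad_out_migration)):
            for y, v in series.points.items():
                if not 0.0 <= v <= 1.0:
                    out.append(Violation("bounds", (label, n, y), f"{v!r} outside [0, 1]"))
        dist = pipe.grad_age_distribution
        for a, p in dist.items():
            if a not in age_set:
                out.append(Violation("unknown_label", ("grad_age_distribution", n, a),
                                     "unknown age band"))
            if not 0.0 <= p <= 1.0:
                out.append(Violation("bounds", ("grad_age_distribution", n, a),
                                     f"{p!r} outside [0, 1]"))
        if abs(math.fsum(dist.values()) - 1.0) > 1e-9:
            out.append(Violation("grad_age_distribution_sum", (n,),
                                 f"distribution sums to {math.fsum(dist.values())!r}"))

    return out
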