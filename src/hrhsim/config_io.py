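"""Configuration and scenario (de)serialization plus the run manifest.

A model lives in one YAML document plus long-format CSV parameter tables.
The document holds the strata registry, options and per-profession supply
specs inline; the five whole-model tables (population, prevalence, service
levels, division of work, productivity) are CSVs referenced by relative path.
Each CSV has a header of dimension-name columns (any subset of
``health_state, age_group, sex, service, profession, year``) plus ``value``;
omitted dimension columns broadcast.  Serialization is lossless:
``load_config(save_config(cfg))`` equals ``cfg`` field by field.
"""

from __future__ import annotations

import datetime
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .domain import (
    DIM_ORDER,
    AgeBand,
    ModelConfig,
    Options,
    ProfessionSupplySpec,
    StrataRegistry,
    StratifiedRateTable,
    TrainingPipelineSpec,
    YearSeries,
    validate_config,
)
from .errors import ConfigValidationError, HrhSimError
from .scenarios import Override, Scenario

TABLE_ROLES = ("population", "prevalence", "service_levels", "division_of_work", "productivity")


# ---------------------------------------------------------------------------
# Tables <-> records / CSV
# ---------------------------------------------------------------------------


def _table_to_inline(table: StratifiedRateTable) -> dict:
    return {
        "dims": list(table.dims),
        "default": table.default,
        "records": table.to_records(),
    }


def _table_from_inline(doc: dict, name: str) -> StratifiedRateTable:
    return StratifiedRateTable.from_records(
        tuple(doc["dims"]), doc.get("records", []), default=doc.get("default"), name=name
    )


def read_table_csv(path: Path, default: float | None = None,
                   name: str = "") -> StratifiedRateTable:
    """Read a long-format CSV table; dimension columns are inferred from the header."""
    header = pd.read_csv(path, nrows=0).columns.tolist()
    dims = tuple(d for d in DIM_ORDER if d in header)
    if "value" not in header:
        raise HrhSimError(f"{path}: table CSV needs a 'value' column")
    dtypes = {d: (int if d == "year" else str) for d in dims}
    frame = pd.read_csv(path, dtype={**dtypes, "value": float},
                        float_precision="round_trip")
    values = {
        tuple(int(row[d]) if d == "year" else str(row[d]) for d in dims): float(row["value"])
        for row in frame.to_dict("records")
    }
    return StratifiedRateTable(dims=dims, values=values, default=default, name=name)


def write_table_csv(table: StratifiedRateTable, path: Path) -> None:
    rows = table.to_records()
    frame = pd.DataFrame(rows, columns=list(table.dims) + ["value"])
    frame.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Config <-> dict
# ---------------------------------------------------------------------------


def _series_to_doc(series: YearSeries):
    return {"points": dict(series.points)}


def _supply_to_dict(spec: ProfessionSupplySpec) -> dict:
    return {
        "initial_stock": dict(spec.initial_stock),
        "exit_rates": _table_to_inline(spec.exit_rates),
        "in_migration": _table_to_inline(spec.in_migration),
        "participation": _series_to_doc(spec.participation),
        "activity": _series_to_doc(spec.activity),
        "clinical_focus": _series_to_doc(spec.clinical_focus),
        "pipeline": {
            "program_length_years": spec.pipeline.program_length_years,
            "cohort_entries": dict(spec.pipeline.cohort_entries),
            "attrition": _series_to_doc(spec.pipeline.attrition),
            "grad_out_migration": _series_to_doc(spec.pipeline.grad_out_migration),
            "grad_age_distribution": dict(spec.pipeline.grad_age_distribution),
            "seed_steady_state": spec.pipeline.seed_steady_state,
        },
    }


def _supply_from_dict(doc: dict, profession: str) -> ProfessionSupplySpec:
    pipe = doc["pipeline"]
    return ProfessionSupplySpec(
        initial_stock=doc["initial_stock"],
        exit_rates=_table_from_inline(doc["exit_rates"], f"exit_rates[{profession}]"),
        in_migration=_table_from_inline(doc["in_migration"], f"in_migration[{profession}]"),
        participation=YearSeries.coerce(doc["participation"].get("points", doc["participation"])
                                        if isinstance(doc["participation"], dict)
                                        else doc["participation"]),
        activity=YearSeries.coerce(doc["activity"].get("points", doc["activity"])
                                   if isinstance(doc["activity"], dict) else doc["activity"]),
        clinical_focus=YearSeries.coerce(doc["clinical_focus"].get("points", doc["clinical_focus"])
                                         if isinstance(doc["clinical_focus"], dict)
                                         else doc["clinical_focus"]),
        pipeline=TrainingPipelineSpec(
            program_length_years=pipe["program_length_years"],
            cohort_entries=pipe["cohort_entries"],
            attrition=YearSeries.coerce(pipe["attrition"].get("points", pipe["attrition"])
                                        if isinstance(pipe["attrition"], dict) else pipe["attrition"]),
            grad_out_migration=YearSeries.coerce(
                pipe["grad_out_migration"].get("points", pipe["grad_out_migration"])
                if isinstance(pipe["grad_out_migration"], dict) else pipe["grad_out_migration"]),
            grad_age_distribution=pipe["grad_age_distribution"],
            seed_steady_state=pipe.get("seed_steady_state", True),
        ),
    )


def config_to_dict(config: ModelConfig) -> dict:
    """Fully inline dict form of a config (tables as record lists)."""
    reg = config.registry
    return {
        "registry": {
            "age_groups": [{"label": b.label, "lower": b.lower, "upper": b.upper}
                           for b in reg.age_groups],
            "sexes": list(reg.sexes),
            "health_states": list(reg.health_states),
            "services": list(reg.services),
            "professions": list(reg.professions),
            "years": {"start": reg.start_year, "end": reg.end_year},
        },
        "options": {
            "aging_enabled": config.options.aging_enabled,
            "dow_tolerance": config.options.dow_tolerance,
            "renormalize_dow": config.options.renormalize_dow,
        },
        "tables": {role: _table_to_inline(config.table(role)) for role in TABLE_ROLES},
        "supply": {n: _supply_to_dict(s) for n, s in config.supply.items()},
    }


def config_from_dict(doc: dict, base_dir: Path | None = None) -> ModelConfig:
    """Build a config from its dict form; table entries may be inline records
    (``records``) or CSV references (``csv``, resolved against ``base_dir``)."""
    regdoc = doc["registry"]
    registry = StrataRegistry(
        age_groups=[AgeBand(b["label"], int(b["lower"]), int(b["upper"]))
                    for b in regdoc["age_groups"]],
        sexes=list(regdoc["sexes"]),
        health_states=list(regdoc["health_states"]),
        services=list(regdoc["services"]),
        professions=list(regdoc["professions"]),
        start_year=int(regdoc["years"]["start"]),
        end_year=int(regdoc["years"]["end"]),
    )
    optdoc = doc.get("options", {})
    options = Options(
        aging_enabled=bool(optdoc.get("aging_enabled", False)),
        dow_tolerance=float(optdoc.get("dow_tolerance", 1e-9)),
        renormalize_dow=bool(optdoc.get("renormalize_dow", False)),
    )
    tables = {}
    for role in TABLE_ROLES:
        try:
            tdoc = doc["tables"][role]
        except KeyError:
            raise HrhSimError(f"parameter not specified: missing table {role!r}") from None
        if "csv" in tdoc:
            if base_dir is None:
                raise HrhSimError(f"table {role!r} references a CSV but no base directory given")
            tables[role] = read_table_csv(Path(base_dir) / tdoc["csv"],
                                          default=tdoc.get("default"), name=role)
        else:
            tables[role] = _table_from_inline(tdoc, role)
    supply = {n: _supply_from_dict(s, n) for n, s in doc.get("supply", {}).items()}
    return ModelConfig(registry=registry, options=options, supply=supply, **tables)


# ---------------------------------------------------------------------------
# Files
# ---------------------------------------------------------------------------


def load_config(path, validate: bool = True) -> ModelConfig:
    """Load and (by default) validate a config document.

    Raises :class:`ConfigValidationError` carrying the violation list when the
    parsed config breaks an invariant.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    config = config_from_dict(doc, base_dir=path.parent)
    if validate:
        violations = validate_config(config)
        if violations:
            raise ConfigValidationError(violations)
    return config


def save_config(config: ModelConfig, out_dir, config_name: str = "config.yaml") -> Path:
    """Write a config directory: YAML document plus one CSV per model table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = config_to_dict(config)
    for role in TABLE_ROLES:
        table = config.table(role)
        csv_name = f"{role}.csv"
        write_table_csv(table, out / csv_name)
        doc["tables"][role] = {"csv": csv_name, "dims": list(table.dims),
                               "default": table.default}
    path = out / config_name
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def load_scenario(path) -> Scenario:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return Scenario(
        name=str(doc["name"]),
        overrides=[
            Override(
                target=str(o["target"]),
                selector={str(k): (int(v) if k == "year" else v)
                          for k, v in (o.get("selector") or {}).items()},
                effective_year=int(o["effective_year"]),
                value=float(o["value"]),
            )
            for o in doc.get("overrides", [])
        ],
    )


def save_scenario(scenario: Scenario, path) -> Path:
    doc = {
        "name": scenario.name,
        "overrides": [
            {
                "target": o.target,
                "selector": dict(o.selector),
                "effective_year": o.effective_year,
                "value": o.value,
            }
            for o in scenario.overrides
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def write_manifest(out_dir, config_path, scenario_paths, statuses: dict[str, str],
                   options: dict | None = None) -> Path:
    """Write the run manifest (written for every run, including failed ones)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "hrhsim",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": str(config_path),
        "scenarios": [str(p) for p in scenario_paths],
        "options": options or {},
        "status": statuses,
    }
    path = out / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path
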