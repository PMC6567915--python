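"""Independent reference implementations used to cross-check the engines.

These deliberately re-derive the model from its defining formulas with plain
nested loops and naive accumulation, sharing no computation structure with
the package's engines (which group terms, use compensated summation and
precompute volumes/workloads).  Table lookups are data access, not
computation, and are shared.
"""

from __future__ import annotations

from hrhsim.domain import ModelConfig, YearSeries
from hrhsim.errors import ParameterNotSpecifiedError


def _step_at(series: YearSeries, year: int) -> float:
    """Independent re-derivation of step-function semantics."""
    best_key, best_val = None, None
    for k, v in series.points.items():
        if k <= year and (best_key is None or k > best_key):
            best_key, best_val = k, v
    if best_key is None:  # before the first point
        first = min(series.points)
        return series.points[first]
    return best_val


def oracle_requirements(config: ModelConfig) -> dict[tuple[str, int], float]:
    """FTE requirements per (profession, year) by direct quadruple loop."""
    reg = config.registry
    out: dict[tuple[str, int], float] = {}
    for t in reg.years:
        for n in reg.professions:
            total = 0.0
            for q in reg.services:
                volume_share = 0.0
                for h in reg.health_states:
                    for band in reg.age_groups:
                        for j in reg.sexes:
                            coords = {
                                "health_state": h, "age_group": band.label, "sex": j,
                                "service": q, "profession": n, "year": t,
                            }
                            volume_share += (
                                config.population.lookup(coords)
                                * config.prevalence.lookup(coords)
                                * config.service_levels.lookup(coords)
                                * config.division_of_work.lookup(coords)
                            )
                if volume_share != 0.0:
                    rate = config.productivity.lookup(
                        {"profession": n, "service": q, "year": t}
                    )
                    total += volume_share / rate
            out[(n, t)] = total
    return out


def oracle_supply(config: ModelConfig) -> dict[tuple[str, int], float]:
    """Effective supply per (profession, year) by direct recurrence (no aging)."""
    reg = config.registry
    assert not config.options.aging_enabled, "oracle covers the no-aging recurrence"
    out: dict[tuple[str, int], float] = {}
    for n, spec in config.supply.items():
        pipe = spec.pipeline
        stock = {b.label: spec.initial_stock.get(b.label, 0.0) for b in reg.age_groups}
        for t in reg.years:
            if t != reg.start_year:
                entry_year = t - pipe.program_length_years
                cohort = None
                for k in sorted(pipe.cohort_entries):
                    if k <= entry_year:
                        cohort = pipe.cohort_entries[k]
                if cohort is None:
                    cohort = pipe.cohort_entries[min(pipe.cohort_entries)]
                completing = cohort * (1.0 - _step_at(pipe.attrition, t))
                staying = 1.0 - _step_at(pipe.grad_out_migration, t)
                new_stock = {}
                for band in reg.age_groups:
                    a = band.label
                    grads = completing * pipe.grad_age_distribution.get(a, 0.0)
                    try:
                        migrants = spec.in_migration.lookup({"age_group": a, "year": t})
                    except ParameterNotSpecifiedError:
                        migrants = 0.0
                    try:
                        exit_rate = spec.exit_rates.lookup({"age_group": a, "year": t})
                    except ParameterNotSpecifiedError:
                        exit_rate = 0.0
                    new_stock[a] = stock[a] * (1.0 - exit_rate) + grads * staying + migrants
                stock = new_stock
            total = sum(stock.values())
            out[(n, t)] = (
                total
                * _step_at(spec.participation, t)
                * _step_at(spec.activity, t)
                * _step_at(spec.clinical_focus, t)
            )
    return out


def relclose(a: float, b: float, tol: float = 1e-9) -> bool:
    return abs(a - b) <= tol * max(1.0, abs(a), abs(b))
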