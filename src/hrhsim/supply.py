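"""Stock-and-flow projection of the licensed workforce and effective supply.

For each profession the licensed stock by age band evolves as::

    S[i, t] = S[i, t-1] * (1 - E[i, t]) + I[i, t]

where ``E`` is the all-cause exit rate (license non-renewal, retirement,
out-migration) and the inflow ``I`` combines new local graduates — net of
graduate out-migration — with in-migrating licensees::

    I[i, t] = G[i, t] * (1 - O[t]) + M[i, t]
    G[i, t] = C[t - y] * (1 - attrition[t]) * grad_age_distribution[i]

``C[t - y]`` is the cohort that entered the (length-``y``) training program
``y`` years earlier, so a seat change first reaches the workforce after the
full program length.  Effective supply converts the end-of-year stock to FTEs
on the planned population: ``N'[t] = S[t] * D[t] * A[t] * F[t]``
(participation, activity, clinical focus).

Within-year order of operations: exits are applied to the prior-year stock,
then entrants are added; effective supply is evaluated on the end-of-year
stock.  Optional aging promotes a fraction ``1 / band_width`` of each band's
post-update stock to the next band (the top band retains); promotion
conserves totals.  It is off by default because the stock recurrence contains
no inter-band flow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .domain import ModelConfig, ProfessionSupplySpec, StrataRegistry, TrainingPipelineSpec
from .errors import ParameterNotSpecifiedError

logger = logging.getLogger(__name__)


@dataclass
class StockTrajectory:
    """Projected stocks and flows per profession.

    ``stock`` maps (profession, age_group, year) to licensed headcount;
    the flow maps record per-(profession, year) totals.  Headcounts are real
    valued — deterministic rates yield fractional people by design.
    """

    stock: dict[tuple[str, str, int], float] = field(default_factory=dict)
    graduates: dict[tuple[str, int], float] = field(default_factory=dict)
    entrants: dict[tuple[str, int], float] = field(default_factory=dict)
    exits: dict[tuple[str, int], float] = field(default_factory=dict)

    def stock_total(self, profession: str, year: int) -> float:
        return math.fsum(
            v for (n, _a, t), v in self.stock.items() if n == profession and t == year
        )

    def stock_by_age(self, profession: str, year: int) -> dict[str, float]:
        return {
            a: v for (n, a, t), v in self.stock.items() if n == profession and t == year
        }

    def to_frame(self, effective_supply: dict[tuple[str, int], float] | None = None):
        import pandas as pd

        rows = []
        for (n, a, t), s in self.stock.items():
            rows.append(
                {
                    "profession": n,
                    "age_group": a,
                    "year": t,
                    "stock": s,
                    "entrants": self.entrants.get((n, t), 0.0),
                    "graduates": self.graduates.get((n, t), 0.0),
                    "exits": self.exits.get((n, t), 0.0),
                    "effective_supply_fte": (
                        effective_supply.get((n, t)) if effective_supply else None
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "profession", "age_group", "year", "stock",
                "entrants", "graduates", "exits", "effective_supply_fte",
            ],
        )


def graduates(pipeline: TrainingPipelineSpec, year: int) -> dict[str, float]:
    """New graduates by age band in ``year``.

    The cohort that entered ``program_length_years`` earlier graduates net of
    program attrition (applied once, indexed by graduation year) and is split
    across age bands by the graduate age distribution.
    """
    cohort = pipeline.entries_for(year - pipeline.program_length_years)
    completed = cohort * (1.0 - pipeline.attrition.at(year))
    return {a: completed * p for a, p in pipeline.grad_age_distribution.items()}


def entrants(grads: dict[str, float], spec: ProfessionSupplySpec, year: int) -> dict[str, float]:
    """New practitioners by age band: retained graduates plus in-migrants."""
    retained = 1.0 - spec.pipeline.grad_out_migration.at(year)
    bands = list(grads)
    for key in spec.in_migration.values:
        coords = dict(zip(spec.in_migration.dims, key))
        a = coords.get("age_group")
        if a is not None and a not in bands:
            bands.append(a)
    out: dict[str, float] = {}
    for a in bands:
        try:
            mig = spec.in_migration.lookup({"age_group": a, "year": year})
        except ParameterNotSpecifiedError:
            mig = 0.0
        out[a] = grads.get(a, 0.0) * retained + mig
    return out


def advance_stock(
    prior: dict[str, float],
    spec: ProfessionSupplySpec,
    entrants_t: dict[str, float],
    year: int,
    registry: StrataRegistry,
    aging_enabled: bool = False,
) -> tuple[dict[str, float], float]:
    """One-year stock update; returns (new stock by band, total exits).

    Negative intermediate stocks (possible only with pathological inputs) are
    clamped to zero with a logged warning.
    """
    new: dict[str, float] = {}
    exit_terms: list[float] = []
    for band in registry.age_groups:
        a = band.label
        s_prev = prior.get(a, 0.0)
        try:
            e = spec.exit_rates.lookup({"age_group": a, "year": year})
        except ParameterNotSpecifiedError:
            if s_prev == 0.0:
                e = 0.0
            else:
                raise
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"exit rate {e!r} outside [0, 1] for ({a}, {year})")
        exited = s_prev * e
        exit_terms.append(exited)
        updated = (s_prev - exited) + entrants_t.get(a, 0.0)
        if updated < 0.0:
            logger.warning("clamping negative stock %r at (%s, %s)", updated, a, year)
            updated = 0.0
        new[a] = updated
    if aging_enabled:
        bands = registry.age_groups
        promoted = {b.label: new[b.label] / b.width for b in bands}
        aged: dict[str, float] = {}
        for k, band in enumerate(bands):
            a = band.label
            out_flow = promoted[a] if k < len(bands) - 1 else 0.0  # top band retains
            in_flow = promoted[bands[k - 1].label] if k > 0 else 0.0
            aged[a] = new[a] - out_flow + in_flow
        new = aged
    return new, math.fsum(exit_terms)


def effective_supply(stock_total: float, spec: ProfessionSupplySpec, year: int) -> float:
    """FTEs effectively available to the planned population in ``year``."""
    return (
        stock_total
        * spec.participation.at(year)
        * spec.activity.at(year)
        * spec.clinical_focus.at(year)
    )


def supply_timeseries(config: ModelConfig) -> tuple[StockTrajectory, dict[tuple[str, int], float]]:
    """Project stocks, flows and effective supply for every profession.

    The initial stock is the licensed headcount in the first horizon year;
    flows apply from the second year onward.
    """
    reg = config.registry
    traj = StockTrajectory()
    eff: dict[tuple[str, int], float] = {}
    for n, spec in config.supply.items():
        current = {b.label: float(spec.initial_stock.get(b.label, 0.0)) for b in reg.age_groups}
        for t in reg.years:
            try:
                if t == reg.start_year:
                    traj.graduates[(n, t)] = 0.0
                    traj.entrants[(n, t)] = 0.0
                    traj.exits[(n, t)] = 0.0
                else:
                    grads = graduates(spec.pipeline, t)
                    inflow = entrants(grads, spec, t)
                    current, exited = advance_stock(
                        current, spec, inflow, t, reg, config.options.aging_enabled
                    )
                    traj.graduates[(n, t)] = math.fsum(grads.values())
                    traj.entrants[(n, t)] = math.fsum(inflow.values())
                    traj.exits[(n, t)] = exited
                for a, s in current.items():
                    traj.stock[(n, a, t)] = s
                eff[(n, t)] = effective_supply(math.fsum(current.values()), spec, t)
            except Exception as e:
                e.add_note(f"while projecting supply for ({n}, {t})")
                raise
    return traj, eff
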