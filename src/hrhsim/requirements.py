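"""Needs-based FTE requirements.

Requirements for profession ``n`` in year ``t`` are::

    N[n, t] = sum_q  sum_{h,i,j} ( P[i,j,t] * H[h,i,j,t] * Q[h,i,j,q,t]
                                   * W[h,i,j,q,n,t] ) / R[n,q,t]

where ``P`` is population, ``H`` health-state prevalence, ``Q`` the planned
level of service, ``W`` the division of work (shares summing to one per
service stratum) and ``R`` productivity (services per FTE per year).  The
computation is split into three composable steps — service volumes, workload
allocation and FTE conversion — each usable on its own.

Sums use compensated summation (:func:`math.fsum`) over deterministically
ordered terms so results are permutation-stable across platforms.
"""

from __future__ import annotations

import math

from .domain import ModelConfig
from .errors import DivisionOfWorkError, ProductivityUndefinedError

#: ServiceVolume maps (health_state, age_group, sex, service) -> services in a year.
ServiceVolume = dict[tuple[str, str, str, str], float]
#: AllocatedWorkload maps (profession, service) -> services assigned in a year.
AllocatedWorkload = dict[tuple[str, str], float]


def service_volume(config: ModelConfig, year: int) -> ServiceVolume:
    """Total services required per (health_state, age_group, sex, service).

    The value at each stratum is ``population * prevalence * service_level``;
    it is zero whenever any factor is zero.
    """
    reg = config.registry
    if year not in reg.years:
        raise ValueError(f"year {year} outside horizon [{reg.start_year}, {reg.end_year}]")
    volume: ServiceVolume = {}
    for h in reg.health_states:
        for band in reg.age_groups:
            i = band.label
            for j in reg.sexes:
                coords = {"health_state": h, "age_group": i, "sex": j, "year": year}
                p = config.population.lookup(coords)
                prev = config.prevalence.lookup(coords)
                for q in reg.services:
                    level = config.service_levels.lookup(coords | {"service": q})
                    volume[(h, i, j, q)] = p * prev * level
    return volume


def allocate_workload(volume: ServiceVolume, config: ModelConfig, year: int) -> AllocatedWorkload:
    """Assign service volumes to professions via the division of work.

    Shares must sum to one (within ``options.dow_tolerance``) at every stratum
    with nonzero volume; with ``options.renormalize_dow`` they are rescaled
    instead of rejected.  Allocation conserves total volume per service.
    """
    reg = config.registry
    opts = config.options
    dow = config.division_of_work
    terms: dict[tuple[str, str], list[float]] = {
        (n, q): [] for n in reg.professions for q in reg.services
    }
    for (h, i, j, q), vol in volume.items():
        if vol == 0.0:
            continue
        coords = {"health_state": h, "age_group": i, "sex": j, "service": q, "year": year}
        shares = [dow.lookup(coords | {"profession": n}) for n in reg.professions]
        total = math.fsum(shares)
        if abs(total - 1.0) > opts.dow_tolerance:
            if opts.renormalize_dow and total > 0:
                shares = [w / total for w in shares]
            else:
                raise DivisionOfWorkError(coords, total)
        for n, w in zip(reg.professions, shares):
            if w != 0.0:
                terms[(n, q)].append(vol * w)
    return {key: math.fsum(parts) for key, parts in terms.items()}


def fte_requirements(workload: AllocatedWorkload, config: ModelConfig, year: int) -> dict[str, float]:
    """Convert allocated service workloads to FTE requirements per profession.

    Each profession's requirement is the sum over services of workload divided
    by productivity; productivity is only consulted (and must be positive)
    where the workload is nonzero.
    """
    reg = config.registry
    out: dict[str, float] = {}
    for n in reg.professions:
        parts = []
        for q in reg.services:
            w = workload.get((n, q), 0.0)
            if w == 0.0:
                continue
            r = config.productivity.lookup({"profession": n, "service": q, "year": year})
            if r <= 0:
                raise ProductivityUndefinedError(n, q, year, r)
            parts.append(w / r)
        out[n] = math.fsum(parts)
    return out


def requirements_for_year(config: ModelConfig, year: int) -> dict[str, float]:
    """FTE requirements per profession for one year (three steps composed)."""
    vol = service_volume(config, year)
    work = allocate_workload(vol, config, year)
    return fte_requirements(work, config, year)


def requirements_timeseries(config: ModelConfig) -> dict[tuple[str, int], float]:
    """FTE requirements per (profession, year) over the whole horizon.

    Each year is computed independently (the model is cross-sectional per
    year: no backlog of unmet need is carried forward).
    """
    out: dict[tuple[str, int], float] = {}
    for t in config.registry.years:
        try:
            per_prof = requirements_for_year(config, t)
        except Exception as e:
            e.add_note(f"while computing requirements for year {t}")
            raise
        for n, val in per_prof.items():
            out[(n, t)] = val
    return out
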