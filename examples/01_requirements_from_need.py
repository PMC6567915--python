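"""From population need to FTE requirements, step by step.

Builds a tiny one-stratum model — 1000 children, 10% with the condition,
2 planned services each per year — splits the resulting 200 services across
three professions (60/20/20) and converts them to FTEs at 60 services per
FTE per year.
"""

import hrhsim as hs
from hrhsim.domain import AgeBand, StrataRegistry, StratifiedRateTable

registry = StrataRegistry(
    age_groups=[AgeBand("10-14", 10, 14)],
    sexes=["all"],
    health_states=["condition"],
    services=["assessment"],
    professions=["psychiatrist", "psychologist", "social_worker"],
    start_year=2020,
    end_year=2020,
)
config = hs.ModelConfig(
    registry=registry,
    population=StratifiedRateTable(("age_group",), {("10-14",): 1000.0}),
    prevalence=StratifiedRateTable(("health_state",), {("condition",): 0.10}),
    service_levels=StratifiedRateTable(("service",), {("assessment",): 2.0}),
    division_of_work=StratifiedRateTable(
        ("profession",),
        {("psychiatrist",): 0.6, ("psychologist",): 0.2, ("social_worker",): 0.2},
    ),
    productivity=StratifiedRateTable(
        ("profession",), {(n,): 60.0 for n in registry.professions}
    ),
    supply={},
)

volume = hs.service_volume(config, 2020)
workload = hs.allocate_workload(volume, config, 2020)
requirements = hs.fte_requirements(workload, config, 2020)

print("total services needed:", sum(volume.values()))
for n in registry.professions:
    print(f"  {n}: {workload[(n, 'assessment')]:.0f} services -> "
          f"{requirements[n]:.2f} FTE required")
# 1000 x 0.10 x 2 = 200 services; a 60% share is 120 services, which at 60
# services/FTE/year means 2 FTE psychiatrists are required.
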