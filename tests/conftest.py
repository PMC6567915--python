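import pytest
from hypothesis import HealthCheck, settings

import hrhsim as hs
from hrhsim.domain import AgeBand, StrataRegistry, StratifiedRateTable

settings.register_profile(
    "hrhsim",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("hrhsim")


@pytest.fixture(scope="session")
def packaged_bundle():
    """The calibrated seven-profession configuration and its five scenarios."""
    return hs.packaged_fixture()


@pytest.fixture(scope="session")
def packaged_runs(packaged_bundle):
    """All five packaged scenarios simulated once, shared across tests."""
    config, scenarios = packaged_bundle
    return config, hs.run(config, scenarios)


@pytest.fixture(scope="session")
def worked():
    """The one-profession 125/360 worked-example configuration and scenario."""
    return hs.worked_example()


@pytest.fixture
def point_config_factory():
    """Build a one-stratum config (one band/sex/state/service) for hand checks."""

    def make(shares: dict[str, float], population: float = 1000.0,
             prevalence: float = 0.1, service_level: float = 2.0,
             productivity: float = 60.0, start_year: int = 2020,
             end_year: int = 2020) -> hs.ModelConfig:
        professions = list(shares)
        registry = StrataRegistry(
            age_groups=[AgeBand("10-14", 10, 14)],
            sexes=["all"],
            health_states=["condition"],
            services=["service"],
            professions=professions,
            start_year=start_year,
            end_year=end_year,
        )
        return hs.ModelConfig(
            registry=registry,
            population=StratifiedRateTable(("age_group",), {("10-14",): population},
                                           name="population"),
            prevalence=StratifiedRateTable(("health_state",), {("condition",): prevalence},
                                           name="prevalence"),
            service_levels=StratifiedRateTable(("service",), {("service",): service_level},
                                               name="service_levels"),
            division_of_work=StratifiedRateTable(
                ("profession",), {(n,): w for n, w in shares.items()},
                name="division_of_work"),
            productivity=StratifiedRateTable(
                ("profession",), {(n,): productivity for n in professions},
                name="productivity"),
            supply={},
        )

    return make
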