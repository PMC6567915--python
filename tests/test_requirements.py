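"""Needs-based requirements: volumes, allocation, FTE conversion."""

import math

import pytest
from hypothesis import given, strategies as st

import hrhsim as hs
from hrhsim.errors import DivisionOfWorkError, ParameterNotSpecifiedError
from oracles import oracle_requirements, relclose

YEAR = 2020
STRATUM = ("condition", "10-14", "all", "service")


class TestServiceVolume:
    def test_single_stratum_product(self, point_config_factory):
        config = point_config_factory({"psychiatrist": 1.0})
        volume = hs.service_volume(config, YEAR)
        assert volume[STRATUM] == pytest.approx(1000 * 0.1 * 2)  # 200 services

    def test_zero_population_means_zero_volume(self, point_config_factory):
        config = point_config_factory({"psychiatrist": 1.0}, population=0.0)
        assert all(v == 0.0 for v in hs.service_volume(config, YEAR).values())


class TestAllocateWorkload:
    def test_published_diagnostic_assessment_split(self, point_config_factory):
        # 60% of diagnostic assessments to psychiatrists, 20% each to
        # psychologists and social workers, on 200 services.
        config = point_config_factory(
            {"psychiatrist": 0.6, "psychologist": 0.2, "social_worker": 0.2}
        )
        volume = hs.service_volume(config, YEAR)
        workload = hs.allocate_workload(volume, config, YEAR)
        assert workload[("psychiatrist", "service")] == pytest.approx(120.0)
        assert workload[("psychologist", "service")] == pytest.approx(40.0)
        assert workload[("social_worker", "service")] == pytest.approx(40.0)

    def test_shifted_split_conserves_total(self, point_config_factory):
        shares = {"family_physician": 0.10, "nurse_practitioner": 0.05,
                  "pediatrician": 0.10, "psychiatrist": 0.40,
                  "psychologist": 0.25, "social_worker": 0.10}
        config = point_config_factory(shares)
        workload = hs.allocate_workload(hs.service_volume(config, YEAR), config, YEAR)
        expected = {"family_physician": 20, "nurse_practitioner": 10, "pediatrician": 20,
                    "psychiatrist": 80, "psychologist": 50, "social_worker": 20}
        for n, w in expected.items():
            assert workload[(n, "service")] == pytest.approx(w)
        assert math.fsum(workload.values()) == pytest.approx(200.0)

    def test_single_profession_receives_everything(self, point_config_factory):
        config = point_config_factory({"solo": 1.0})
        workload = hs.allocate_workload(hs.service_volume(config, YEAR), config, YEAR)
        assert workload[("solo", "service")] == pytest.approx(200.0)

    def test_bad_share_sum_raises_naming_stratum(self, point_config_factory):
        config = point_config_factory({"a": 0.6, "b": 0.3})  # sums to 0.9
        with pytest.raises(DivisionOfWorkError, match="shares sum") as excinfo:
            hs.allocate_workload(hs.service_volume(config, YEAR), config, YEAR)
        assert excinfo.value.total == pytest.approx(0.9)
        assert excinfo.value.coords["service"] == "service"

    def test_renormalization_opt_in(self, point_config_factory):
        config = point_config_factory({"a": 0.6, "b": 0.3})
        config.options.renormalize_dow = True
        workload = hs.allocate_workload(hs.service_volume(config, YEAR), config, YEAR)
        assert math.fsum(workload.values()) == pytest.approx(200.0)
        assert workload[("a", "service")] == pytest.approx(200 * 0.6 / 0.9)

    def test_unallocated_service_is_hard_error(self, point_config_factory):
        config = point_config_factory({"a": 1.0})
        config.division_of_work.values.clear()  # Q > 0 but no shares, no default
        with pytest.raises(ParameterNotSpecifiedError):
            hs.allocate_workload(hs.service_volume(config, YEAR), config, YEAR)


class TestFteRequirements:
    def test_single_quotient(self, point_config_factory):
        config = point_config_factory({"psychiatrist": 0.6, "psychologist": 0.2,
                                       "social_worker": 0.2})
        workload = hs.allocate_workload(hs.service_volume(config, YEAR), config, YEAR)
        req = hs.fte_requirements(workload, config, YEAR)
        assert req["psychiatrist"] == pytest.approx(120 / 60)  # 2.0 FTE

    def test_homogeneous_degree_minus_one_in_productivity(self, point_config_factory):
        config = point_config_factory({"a": 0.5, "b": 0.5})
        base = hs.requirements_for_year(config, YEAR)
        doubled = config.copy()
        for key in doubled.productivity.values:
            doubled.productivity.values[key] *= 2.0
        halved = hs.requirements_for_year(doubled, YEAR)
        for n in base:
            assert halved[n] == pytest.approx(base[n] / 2.0, rel=1e-12)


class TestRequirementsTimeseries:
    def test_population_growth_scales_requirements_linearly(self, point_config_factory):
        config = point_config_factory({"a": 1.0}, start_year=2020, end_year=2024)
        # Replace the static population with 1%/year growth.
        config.population = hs.StratifiedRateTable(
            ("age_group", "year"),
            {("10-14", t): 1000.0 * 1.01 ** (t - 2020) for t in range(2020, 2025)},
            name="population",
        )
        series = hs.requirements_timeseries(config)
        for t in range(2021, 2025):
            assert series[("a", t)] / series[("a", t - 1)] == pytest.approx(1.01, rel=1e-12)

    def test_single_year_horizon_matches_one_shot_composition(self, point_config_factory):
        config = point_config_factory({"a": 0.7, "b": 0.3})
        assert hs.requirements_timeseries(config) == {
            (n, YEAR): v for n, v in hs.requirements_for_year(config, YEAR).items()
        }

    @pytest.mark.parametrize("seed", [3, 11, 42])
    def test_matches_independent_nested_loop_oracle(self, seed):
        config = hs.generate(hs.FixtureSpec(
            n_professions=4, n_age_groups=3, n_sexes=2, n_health_states=2,
            n_services=3, n_years=3, seed=seed))
        engine = hs.requirements_timeseries(config)
        reference = oracle_requirements(config)
        assert engine.keys() == reference.keys()
        for key in engine:
            assert relclose(engine[key], reference[key])


@given(
    delta=st.floats(min_value=0.0, max_value=0.3),
    donor=st.sampled_from(["a", "b"]),
)
def test_share_shift_monotonicity(point_config_factory, delta, donor):
    """Moving share to a profession never decreases its requirement and never
    increases the donor's; untouched professions are unaffected."""
    shares = {"a": 0.4, "b": 0.3, "c": 0.3}
    config = point_config_factory(shares)
    base = hs.requirements_for_year(config, YEAR)
    shifted_shares = dict(shares)
    shifted_shares[donor] -= delta
    shifted_shares["c"] += delta
    shifted = point_config_factory(shifted_shares)
    new = hs.requirements_for_year(shifted, YEAR)
    assert new["c"] >= base["c"]
    assert new[donor] <= base[donor]
    other = "b" if donor == "a" else "a"
    assert new[other] == base[other]
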