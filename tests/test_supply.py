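"""Stock-and-flow supply projection: pipeline, stock updates, effective FTEs."""

import math

import pytest

import hrhsim as hs
from hrhsim.domain import StratifiedRateTable, TrainingPipelineSpec, YearSeries
from hrhsim.errors import PipelineNotSeededError
from oracles import oracle_supply, relclose


def make_pipeline(entries, length=4, attrition=0.1, out_migration=0.25,
                  dist=None, seed_steady_state=True):
    return TrainingPipelineSpec(
        program_length_years=length,
        cohort_entries=entries,
        attrition=YearSeries.coerce(attrition),
        grad_out_migration=YearSeries.coerce(out_migration),
        grad_age_distribution=dist or {"25-34": 1.0},
        seed_steady_state=seed_steady_state,
    )


def make_spec(stock, exit_rate=0.0, migration=None, participation=1.0, activity=1.0,
              focus=1.0, pipeline=None):
    bands = list(stock)
    return hs.ProfessionSupplySpec(
        initial_stock=stock,
        exit_rates=StratifiedRateTable(("age_group",), {(a,): exit_rate for a in bands}),
        in_migration=StratifiedRateTable(("age_group",), migration or {}, default=0.0),
        participation=YearSeries.coerce(participation),
        activity=YearSeries.coerce(activity),
        clinical_focus=YearSeries.coerce(focus),
        pipeline=pipeline or make_pipeline({2018: 0.0}, dist={a: 1.0 / len(bands) for a in bands}),
    )


class TestGraduates:
    def test_cohort_net_of_attrition_after_program_length(self):
        pipeline = make_pipeline({2018: 50.0}, length=4, attrition=0.1)
        grads = hs.graduates(pipeline, 2022)  # entered 2018, graduates 2022
        assert grads == {"25-34": pytest.approx(45.0)}  # 50 * 0.9

    def test_total_attrition_means_no_graduates(self):
        pipeline = make_pipeline({2018: 50.0}, attrition=1.0)
        assert sum(hs.graduates(pipeline, 2022).values()) == 0.0

    def test_age_distribution_split(self):
        pipeline = make_pipeline({2018: 50.0}, length=4, attrition=0.1,
                                 dist={"20-29": 0.8, "30-39": 0.2})
        grads = hs.graduates(pipeline, 2022)
        assert grads["20-29"] == pytest.approx(36.0)
        assert grads["30-39"] == pytest.approx(9.0)

    def test_unseeded_history_raises_without_steady_state(self):
        pipeline = make_pipeline({2020: 50.0}, length=4, seed_steady_state=False)
        with pytest.raises(PipelineNotSeededError):
            hs.graduates(pipeline, 2021)  # would need the 2017 cohort

    def test_steady_state_seeding_extends_first_cohort_backwards(self):
        pipeline = make_pipeline({2020: 50.0}, length=4, attrition=0.0)
        assert sum(hs.graduates(pipeline, 2021).values()) == pytest.approx(50.0)


class TestEntrants:
    def test_graduates_net_of_out_migration_plus_migrants(self):
        spec = make_spec({"25-34": 0.0}, migration={("25-34",): 4.0},
                         pipeline=make_pipeline({2018: 50.0}, out_migration=0.25))
        inflow = hs.entrants({"25-34": 36.0}, spec, 2022)
        assert inflow["25-34"] == pytest.approx(36 * 0.75 + 4)  # 31

    def test_full_out_migration_leaves_only_migrants(self):
        spec = make_spec({"25-34": 0.0},
                         pipeline=make_pipeline({2018: 50.0}, out_migration=1.0))
        assert hs.entrants({"25-34": 36.0}, spec, 2022)["25-34"] == 0.0

    def test_migration_only_inflow(self):
        spec = make_spec({"25-34": 0.0}, migration={("25-34",): 10.0})
        assert hs.entrants({"25-34": 0.0}, spec, 2022)["25-34"] == pytest.approx(10.0)


class TestAdvanceStock:
    def make_registry(self, bands):
        return hs.StrataRegistry(bands, ["all"], ["c"], ["q"], ["n"], 2018, 2032)

    def test_exits_then_entrants(self):
        registry = self.make_registry([hs.AgeBand("25-34", 25, 34)])
        spec = make_spec({"25-34": 100.0}, exit_rate=0.05)
        new, exits = hs.advance_stock({"25-34": 100.0}, spec, {"25-34": 10.0}, 2019, registry)
        assert new["25-34"] == pytest.approx(105.0)  # 100*0.95 + 10
        assert exits == pytest.approx(5.0)

    def test_closed_system_is_constant(self):
        registry = self.make_registry([hs.AgeBand("25-34", 25, 34)])
        spec = make_spec({"25-34": 100.0}, exit_rate=0.0)
        stock = {"25-34": 100.0}
        for t in range(2019, 2025):
            stock, _ = hs.advance_stock(stock, spec, {}, t, registry)
        assert stock["25-34"] == 100.0

    def test_aging_promotes_one_band_width_fraction(self):
        bands = [hs.AgeBand("25-34", 25, 34), hs.AgeBand("35-44", 35, 44)]
        registry = self.make_registry(bands)
        spec = make_spec({"25-34": 100.0, "35-44": 0.0}, exit_rate=0.0)
        new, _ = hs.advance_stock({"25-34": 100.0, "35-44": 0.0}, spec, {}, 2019,
                                  registry, aging_enabled=True)
        assert new["25-34"] == pytest.approx(90.0)
        assert new["35-44"] == pytest.approx(10.0)
        assert math.fsum(new.values()) == pytest.approx(100.0)  # promotion conserves

    def test_negative_inflow_clamped_to_zero(self, caplog):
        registry = self.make_registry([hs.AgeBand("25-34", 25, 34)])
        spec = make_spec({"25-34": 10.0})
        with caplog.at_level("WARNING"):
            new, _ = hs.advance_stock({"25-34": 10.0}, spec, {"25-34": -50.0}, 2019, registry)
        assert new["25-34"] == 0.0
        assert "clamping" in caplog.text


class TestEffectiveSupply:
    def test_identity_adjustment(self):
        spec = make_spec({"25-34": 0.0})
        assert hs.effective_supply(360.0, spec, 2020) == 360.0

    def test_zero_focus_means_zero_supply(self):
        spec = make_spec({"25-34": 0.0}, focus=0.0)
        assert hs.effective_supply(1e6, spec, 2020) == 0.0

    def test_calibrated_focus_example(self, worked):
        # Pre-focus supply of 360 FTE-equivalents at clinical focus 0.10
        # leaves 36 FTE for the planned population.
        config, _ = worked
        _, eff = hs.supply_timeseries(config)
        assert eff[("social_worker", 2019)] == pytest.approx(36.0, abs=1e-9)


class TestSupplyTimeseries:
    def test_static_population_no_flows_is_constant(self):
        config = hs.generate(hs.FixtureSpec(n_professions=1, n_years=5, seed=2))
        spec = config.supply["prof1"]
        spec.exit_rates = StratifiedRateTable(
            ("age_group",), {k: 0.0 for k in spec.exit_rates.values})
        spec.in_migration = StratifiedRateTable(("age_group",), {}, default=0.0)
        spec.pipeline.cohort_entries = {config.registry.start_year: 0.0}
        _, eff = hs.supply_timeseries(config)
        values = [eff[("prof1", t)] for t in config.registry.years]
        assert all(v == values[0] for v in values)

    def test_clinical_focus_scales_supply_but_not_stock(self):
        config = hs.generate(hs.FixtureSpec(n_professions=2, n_years=6, seed=9))
        traj1, eff1 = hs.supply_timeseries(config)
        doubled = config.copy()
        focus = doubled.supply["prof1"].clinical_focus
        doubled.supply["prof1"].clinical_focus = YearSeries(
            {y: 2 * v for y, v in focus.points.items()})
        traj2, eff2 = hs.supply_timeseries(doubled)
        assert traj1.stock == traj2.stock
        for t in config.registry.years:
            assert eff2[("prof1", t)] == pytest.approx(2 * eff1[("prof1", t)], rel=1e-12)
            assert eff2[("prof2", t)] == eff1[("prof2", t)]

    @pytest.mark.parametrize("seed", [1, 8, 23])
    def test_matches_independent_recurrence_oracle(self, seed):
        config = hs.generate(hs.FixtureSpec(
            n_professions=3, n_age_groups=3, n_years=5, seed=seed))
        _, engine = hs.supply_timeseries(config)
        reference = oracle_supply(config)
        assert engine.keys() == reference.keys()
        for key in engine:
            assert relclose(engine[key], reference[key])

    def test_stock_accounting_identity(self):
        config = hs.generate(hs.FixtureSpec(n_professions=3, n_years=6, seed=4))
        traj, _ = hs.supply_timeseries(config)
        reg = config.registry
        for n in config.supply:
            for t in reg.years[1:]:
                lhs = traj.stock_total(n, t)
                rhs = (traj.stock_total(n, t - 1)
                       - traj.exits[(n, t)] + traj.entrants[(n, t)])
                assert relclose(lhs, rhs)

    def test_pipeline_lag_blocks_early_effects(self):
        config = hs.generate(hs.FixtureSpec(n_professions=1, n_years=8, seed=6))
        start = config.registry.start_year
        config.supply["prof1"].pipeline.program_length_years = 3
        _, base = hs.supply_timeseries(config)
        boosted = config.copy()
        tau = start + 2
        boosted.supply["prof1"].pipeline.cohort_entries[tau] = 500.0
        _, bumped = hs.supply_timeseries(boosted)
        for t in config.registry.years:
            if t < tau + 3:
                assert bumped[("prof1", t)] == base[("prof1", t)]
            else:
                assert bumped[("prof1", t)] > base[("prof1", t)]
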