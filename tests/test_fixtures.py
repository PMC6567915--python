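"""Synthetic configuration generator, calibration and the packaged fixture."""

import math

import pytest

import hrhsim as hs
from hrhsim.errors import CalibrationError
from hrhsim.fixtures import (
    BASELINE_SHORTAGE_ANCHORS,
    NURSE_SHIFT_DOW,
    SCENARIO_YEAR,
)


class TestGenerate:
    def test_same_seed_reproduces_bitwise(self):
        spec = hs.FixtureSpec(seed=13, n_years=4)
        assert hs.generate(spec) == hs.generate(spec)

    def test_different_seeds_differ(self):
        assert hs.generate(hs.FixtureSpec(seed=1, n_years=4)) != hs.generate(
            hs.FixtureSpec(seed=2, n_years=4))

    def test_default_first_year_population_total(self):
        config = hs.generate(hs.FixtureSpec(seed=0, n_years=2))
        reg = config.registry
        total = math.fsum(
            config.population.lookup({"age_group": b.label, "sex": j, "year": reg.start_year})
            for b in reg.age_groups for j in reg.sexes
        )
        assert total == pytest.approx(140_000.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 5, 17])
    def test_generated_configs_are_valid(self, seed):
        config = hs.generate(hs.FixtureSpec(seed=seed, n_professions=4, n_years=3))
        assert hs.validate_config(config) == []

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            hs.generate(hs.FixtureSpec(n_services=0))


class TestCalibration:
    def test_round_trip_to_target(self):
        config = hs.generate(hs.FixtureSpec(seed=3, n_professions=3, n_years=3))
        year = config.registry.start_year
        calibrated = hs.calibrate_shortage(config, "prof2", 37.5, year)
        run = hs.simulate(calibrated)
        assert run.gaps.gap("prof2", year) == pytest.approx(37.5, abs=1e-6)

    def test_fixed_point_when_target_equals_current_gap(self):
        config = hs.generate(hs.FixtureSpec(seed=3, n_professions=3, n_years=3))
        year = config.registry.start_year
        current = hs.simulate(config).gaps.gap("prof1", year)
        again = hs.calibrate_shortage(config, "prof1", current, year)
        rerun = hs.simulate(again)
        assert rerun.gaps.gap("prof1", year) == pytest.approx(current, abs=1e-6)

    def test_calibrating_one_profession_leaves_others_unchanged(self):
        config = hs.generate(hs.FixtureSpec(seed=3, n_professions=3, n_years=3))
        year = config.registry.start_year
        base = hs.simulate(config).gaps
        calibrated = hs.calibrate_shortage(config, "prof2", 5.0, year)
        after = hs.simulate(calibrated).gaps
        for n in ("prof1", "prof3"):
            for t in config.registry.years:
                assert after.records[(n, t)] == base.records[(n, t)]

    def test_unachievable_target_raises(self):
        config = hs.generate(hs.FixtureSpec(seed=3, n_professions=2, n_years=3))
        year = config.registry.start_year
        _, eff = hs.supply_timeseries(config)
        impossible = -(eff[("prof1", year)] + 1.0)  # needs negative requirement
        with pytest.raises(CalibrationError):
            hs.calibrate_shortage(config, "prof1", impossible, year)

    def test_pre_focus_supply_pinning(self):
        config = hs.generate(hs.FixtureSpec(seed=6, n_professions=2, n_years=4))
        year = config.registry.start_year + 1
        pinned = hs.calibrate_pre_focus_supply(config, "prof1", 360.0, year)
        traj, _ = hs.supply_timeseries(pinned)
        spec = pinned.supply["prof1"]
        pre_focus = (traj.stock_total("prof1", year)
                     * spec.participation.at(year) * spec.activity.at(year))
        assert pre_focus == pytest.approx(360.0, abs=1e-9)


class TestPackagedFixture:
    def test_baseline_shortage_anchors(self, packaged_runs):
        _, runs = packaged_runs
        gaps = runs["status_quo"].gaps
        for n, anchor in BASELINE_SHORTAGE_ANCHORS.items():
            assert gaps.gap(n, 2018) == pytest.approx(anchor, abs=1e-6)

    def test_social_worker_focus_pair(self, packaged_runs):
        # The status-quo social-worker shortage of 89 FTE becomes 107 FTE
        # when clinical focus drops from 10% to 5%.
        _, runs = packaged_runs
        assert runs["status_quo"].gaps.gap("social_worker", SCENARIO_YEAR) == pytest.approx(
            89.0, abs=1e-6)
        assert runs["focus_reduce_sw"].gaps.gap("social_worker", SCENARIO_YEAR) == pytest.approx(
            107.0, abs=1e-6)

    def test_shift_scenario_diagnostic_assessment_shares(self, packaged_bundle):
        config, scenarios = packaged_bundle
        shift = next(s for s in scenarios if s.name == "dow_shift_to_nurses")
        applied = hs.apply_scenario(config, shift)
        for n, share in NURSE_SHIFT_DOW["diagnostic_assessment"].items():
            assert applied.division_of_work.lookup(
                {"service": "diagnostic_assessment", "profession": n,
                 "year": SCENARIO_YEAR}) == share

    def test_shift_scenario_gap_directions(self, packaged_runs):
        # Shifting work toward nurses relieves physicians, psychologists and
        # social workers while increasing NP, pediatrician and RN gaps.
        config, runs = packaged_runs
        base = runs["status_quo"].gaps
        shifted = runs["dow_shift_to_nurses"].gaps
        final = config.registry.end_year
        for n in ("family_physician", "psychologist", "psychiatrist", "social_worker"):
            assert shifted.gap(n, final) < base.gap(n, final)
        for n in ("nurse_practitioner", "pediatrician", "registered_nurse"):
            assert shifted.gap(n, final) > base.gap(n, final)

    def test_rn_shortage_becomes_surplus_under_increased_focus(self, packaged_runs):
        config, runs = packaged_runs
        base = runs["status_quo"].gaps
        focused = runs["focus_increase_all_but_sw"].gaps
        final = config.registry.end_year
        assert base.gap("registered_nurse", final) > 0  # shortage without the change
        assert focused.gap("registered_nurse", final) < 0  # surplus with it
        # And every changed profession's shortage shrinks.
        for n in ("family_physician", "nurse_practitioner", "pediatrician",
                  "psychiatrist", "psychologist"):
            assert focused.gap(n, final) < base.gap(n, final)

    def test_fixture_validates_clean(self, packaged_bundle):
        config, _ = packaged_bundle
        assert hs.validate_config(config) == []


class TestWorkedExample:
    def test_requirement_and_supply_pins(self, worked):
        config, _ = worked
        run = hs.simulate(config)
        assert run.gaps.requirement("social_worker", SCENARIO_YEAR) == pytest.approx(
            125.0, abs=1e-9)
        assert run.gaps.supply("social_worker", SCENARIO_YEAR) == pytest.approx(
            36.0, abs=1e-9)
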