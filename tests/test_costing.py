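"""Costing identities: unit-cost transfer, PIN, coverage, markups, ledgers."""
import numpy as np
import pandas as pd
import pytest

import fgmsim as f
from fgmsim.costing import (
    COV_COMBINED,
    CountryYearState,
    InterventionDefinition,
    LEDGER_COLUMNS,
    PIN_ELIGIBLE_COMMUNITIES,
    country_cost_ledger,
    default_unit_costs,
    eligible_community_share,
    target_population,
)
from fgmsim.errors import ValidationError


class TestTransferUnitCost:
    def test_half_gdp_halves_cost(self):
        entry = f.UnitCostEntry("mass_media", 100.0, 2000.0)
        assert f.transfer_unit_cost(entry, 1000.0) == pytest.approx(50.0)

    def test_same_gdp_is_identity(self):
        entry = f.UnitCostEntry("mass_media", 123.4, 5000.0)
        assert f.transfer_unit_cost(entry, 5000.0) == pytest.approx(123.4)

    def test_matches_ratio_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            cost, ref, tgt = rng.uniform(1, 1e4, 3)
            entry = f.UnitCostEntry("mass_media", cost, ref)
            assert f.transfer_unit_cost(entry, tgt) == pytest.approx(cost * tgt / ref)

    def test_nonpositive_gdp_rejected(self):
        entry = f.UnitCostEntry("mass_media", 100.0, 2000.0)
        with pytest.raises(ValidationError):
            f.transfer_unit_cost(entry, 0.0)


class TestNumberReached:
    def test_product(self):
        assert f.number_reached(1000, 0.5, 0.2) == pytest.approx(100)

    def test_zero_coverage(self):
        assert f.number_reached(1000, 0.5, 0.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="pin"):
            f.number_reached(1000, 1.5, 0.2)
        with pytest.raises(ValidationError, match="coverage"):
            f.number_reached(1000, 0.5, -0.1)

    def test_activity_cost_product(self):
        assert f.activity_cost(100, 25.0) == pytest.approx(2500.0)
        assert f.activity_cost(0, 25.0) == 0.0


class TestMarkups:
    def test_conflict_sum(self):
        # 1 + 2 + 2 + 1 + 7.5 + 12 + 1 = 26.5 over service delivery
        assert f.apply_markups(100.0, f.MarkupSchedule(), conflict=True) == pytest.approx(126.5)

    def test_nonconflict_sum(self):
        assert f.apply_markups(100.0, f.MarkupSchedule(), conflict=False) == pytest.approx(125.5)

    def test_zero_service_cost(self):
        assert f.apply_markups(0.0, f.MarkupSchedule(), conflict=True) == 0.0

    def test_multiplicative_in_service_cost(self):
        sched = f.MarkupSchedule()
        a = f.apply_markups(37.5, sched, False)
        assert f.apply_markups(2 * 37.5, sched, False) == pytest.approx(2 * a)

    def test_negative_markup_rejected(self):
        with pytest.raises(ValidationError):
            f.MarkupSchedule(supervision=-1.0)


class TestPinForYear:
    def _state(self, year=2020, approvals=(0.6, 0.6, 0.6), trend=0.0,
               legislation=True, type3=0.2):
        return CountryYearState(
            year=year, base_year=2020,
            community_approvals=np.array(approvals),
            historic_trend=trend, legislation_present=legislation,
            type3_share=type3,
        )

    def test_legislation_pin(self):
        leg = f.INTERVENTIONS["legislation_development"]
        assert f.pin_for_year(leg, self._state(legislation=True)) == 0.0
        assert f.pin_for_year(leg, self._state(legislation=False)) == 1.0

    def test_all_majority_communities_full_pin(self):
        ce = f.INTERVENTIONS["community_empowerment"]
        assert f.pin_for_year(ce, self._state()) == pytest.approx(1.0)

    def test_evolved_pin_matches_counting_oracle(self):
        rng = np.random.default_rng(10)
        approvals = rng.uniform(0, 1, 200)
        ce = f.INTERVENTIONS["community_empowerment"]
        state = self._state(year=2025, approvals=approvals, trend=0.03)
        expected = np.mean(approvals * 0.97**5 > 0.5)
        assert f.pin_for_year(ce, state) == pytest.approx(expected)

    def test_type3_pin(self):
        psy = f.INTERVENTIONS["psychosocial_support"]
        assert f.pin_for_year(psy, self._state(type3=0.31)) == pytest.approx(0.31)

    def test_unknown_intervention_rejected(self):
        bogus = InterventionDefinition(
            "bogus", "prevention", "communities",
            PIN_ELIGIBLE_COMMUNITIES, "per community", COV_COMBINED,
        )
        with pytest.raises(ValidationError, match="bogus"):
            f.pin_for_year(bogus, self._state())

    def test_pin_nonincreasing_over_time(self):
        rng = np.random.default_rng(11)
        approvals = rng.uniform(0, 1, 300)
        shares = [
            eligible_community_share(approvals, 0.03, n) for n in range(0, 15)
        ]
        assert np.all(np.diff(shares) <= 1e-12)


class TestCoverageTrajectory:
    def test_full_target_reached_in_2030(self):
        traj = f.coverage_trajectory(2020, 2030, 1.0)
        assert traj[2030] == pytest.approx(1.0)
        assert traj[2020] == 0.0

    def test_zero_target_all_zero(self):
        assert all(v == 0 for v in f.coverage_trajectory(2020, 2030, 0.0).values())

    def test_two_year_delay_steeper_ramp(self):
        base = f.coverage_trajectory(2020, 2030, 1.0)
        delayed = f.coverage_trajectory(2020, 2030, 1.0, delay_years=2)
        assert delayed[2020] == delayed[2021] == delayed[2022] == 0.0
        assert delayed[2030] == pytest.approx(1.0)
        # steeper slope after the delayed start, lower achieved coverage before
        assert delayed[2023] - delayed[2022] > base[2021] - base[2020]
        assert all(delayed[y] <= base[y] + 1e-12 for y in range(2020, 2030))
        assert np.all(np.diff([delayed[y] for y in range(2020, 2031)]) >= 0)

    def test_delay_past_end_rejected(self):
        with pytest.raises(ValidationError, match="delay"):
            f.coverage_trajectory(2020, 2022, 1.0, delay_years=5)


class TestLedgerAndAggregation:
    @pytest.fixture()
    def ledger(self, small_countries):
        c = small_countries[0]
        base = c.microdata.groupby("community_id")["supports_fgm"].mean().to_numpy()
        direct = f.coverage_trajectory(2020, 2030, 0.25)
        combined = {y: min(1.0, v * 4) for y, v in direct.items()}
        return country_cost_ledger(
            c.profile, base, default_unit_costs(), f.MarkupSchedule(),
            direct_coverage=direct, combined_coverage=combined,
        )

    def test_ledger_schema(self, ledger):
        assert tuple(ledger.columns) == LEDGER_COLUMNS
        assert (ledger["total_cost"] >= ledger["service_cost"]).all()

    def test_total_is_service_plus_markups(self, ledger, small_countries):
        pct = f.MarkupSchedule().total_pct(small_countries[0].profile.conflict) / 100
        assert np.allclose(ledger["total_cost"], ledger["service_cost"] * (1 + pct))
        assert np.allclose(ledger["total_cost"], ledger["service_cost"] + ledger["support_cost"])

    def test_partition_conserves_grand_total(self, ledger):
        grand = ledger["total_cost"].sum()
        for key in ("category", "year", "intervention"):
            assert f.aggregate(ledger, key)["total_cost"].sum() == pytest.approx(grand)

    def test_single_entry_aggregate(self, ledger):
        one = ledger.iloc[[0]]
        agg = f.aggregate(one, "category")
        assert agg["total_cost"].iloc[0] == pytest.approx(one["total_cost"].iloc[0])

    def test_matches_group_and_sum_oracle(self, ledger):
        got = f.aggregate(ledger, "intervention").set_index("intervention")["total_cost"]
        expected = ledger.groupby("intervention")["total_cost"].sum()
        pd.testing.assert_series_equal(got.sort_index(), expected.sort_index())

    def test_unknown_grouping_key_rejected(self, ledger):
        with pytest.raises(ValidationError, match="grouping"):
            f.aggregate(ledger, "flavour")

    def test_empty_ledger_rejected(self, ledger):
        with pytest.raises(ValidationError):
            f.aggregate(ledger.iloc[0:0], "category")

    def test_homogeneous_in_unit_cost(self, small_countries):
        c = small_countries[0]
        base = c.microdata.groupby("community_id")["supports_fgm"].mean().to_numpy()
        direct = f.coverage_trajectory(2020, 2030, 0.25)
        combined = {y: min(1.0, v * 4) for y, v in direct.items()}
        kw = dict(direct_coverage=direct, combined_coverage=combined)
        base_ledger = country_cost_ledger(
            c.profile, base, default_unit_costs(), f.MarkupSchedule(), **kw
        )
        doubled = {
            k: f.UnitCostEntry(k, 2 * e.reference_cost, e.reference_gdp_ppp)
            for k, e in default_unit_costs().items()
        }
        twice = country_cost_ledger(
            c.profile, base, doubled, f.MarkupSchedule(), **kw
        )
        assert twice["total_cost"].sum() == pytest.approx(2 * base_ledger["total_cost"].sum())


def test_target_population_mapping(small_countries):
    p = small_countries[0].profile
    assert target_population(f.INTERVENTIONS["community_empowerment"], p) == p.n_communities
    assert target_population(f.INTERVENTIONS["psychosocial_support"], p) == p.first_births_per_year
    assert target_population(f.INTERVENTIONS["legislation_development"], p) == 1.0
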