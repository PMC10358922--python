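import numpy as np
import pandas as pd
import pytest

from screenvar.standardization import (
    ELIGIBILITY_SCHEDULE,
    PERIODS,
    ScreeningCounts,
    apply_exclusions,
    compute_spr,
    expected_counts,
    load_national_margins,
    national_age_rates,
    participation_rate,
    round_half_up,
    single_age_populations,
)


class TestParticipationRate:
    @pytest.mark.parametrize(
        "invitees,screened,rate",
        [
            (37_869, 10_176, 26.9),   # lowest-participation territory, 2019-2020
            (81_624, 27_437, 33.6),   # remote areas, 2019-2020
            (100, 0, 0.0),
            (100, 100, 100.0),
        ],
    )
    def test_published_margin_arithmetic(self, invitees, screened, rate):
        assert round_half_up(participation_rate(invitees, screened)) == rate

    def test_zero_invitees_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="zero invitees"):
            participation_rate(0, 0)

    def test_screened_exceeding_invitees_rejected(self):
        with pytest.raises(ValueError):
            participation_rate(10, 11)

    def test_rounding_is_half_up_not_bankers(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(0.35, 1) == 0.4
        assert round_half_up(43.85, 1) == 43.9


class TestNationalAgeRates:
    def test_full_participation_gives_rate_one(self):
        nat = pd.DataFrame({"age": [50, 60], "year": [2019, 2019],
                            "invitees": [100, 200], "screened": [100, 200]})
        counts = ScreeningCounts(area=pd.DataFrame(), national=nat)
        assert (national_age_rates(counts)["rate"] == 1.0).all()

    def test_single_cell_quotient(self):
        nat = pd.DataFrame({"age": [60], "year": [2019],
                            "invitees": [200], "screened": [88]})
        counts = ScreeningCounts(area=pd.DataFrame(), national=nat)
        assert national_age_rates(counts)["rate"].iloc[0] == pytest.approx(0.44)

    def test_zero_invitee_cell_is_missing(self):
        nat = pd.DataFrame({"age": [60, 62], "year": [2019, 2019],
                            "invitees": [200, 0], "screened": [88, 0]})
        counts = ScreeningCounts(area=pd.DataFrame(), national=nat)
        rates = national_age_rates(counts)
        assert np.isnan(rates["rate"].iloc[1])

    def test_generator_round_trip_recovers_input_rates(self, small_system):
        """National rates recomputed from the synthetic table match the
        generator's input rates within sampling error."""
        recovered = national_age_rates(small_system["counts"])
        merged = recovered.merge(small_system["rates_in"], on=["age", "year"],
                                 suffixes=("_out", "_in"))
        # theta is population-weighted to one, so cell rates are unbiased
        # up to the pop-weighting of theta; national invitees per cell are
        # ~38k so sampling noise is well below 0.02
        assert len(merged) == 26
        assert np.abs(merged["rate_out"] - merged["rate_in"]).max() < 0.05
        assert np.abs(merged["rate_out"] - merged["rate_in"]).mean() < 0.02


class TestExpectedCounts:
    def test_uniform_rate_factorises_into_person_years(self, small_system):
        areas = small_system["areas"]
        rates = small_system["rates"].copy()
        rates["rate"] = 0.37
        E = expected_counts(areas, ELIGIBILITY_SCHEDULE, rates, "2019-2020")
        pops = single_age_populations(areas)
        elig = np.zeros(len(pops))
        for year in (2019, 2020):
            elig += pops[list(ELIGIBILITY_SCHEDULE[year])].sum(axis=1).to_numpy()
        np.testing.assert_allclose(E["expected"], 0.37 * elig, rtol=1e-12)

    def test_two_area_hand_example(self):
        # 2 areas, 1 eligible age in 1 year, pops 100 and 300, rate 0.5
        areas = pd.DataFrame({
            "area_id": ["a", "b"],
            "pop_50_54": [0, 0], "pop_55_59": [0, 0],
            "pop_60_64": [500, 1500],  # age 60 gets 100 / 300
            "pop_65_69": [0, 0], "pop_70_74": [0, 0],
        })
        rates = pd.DataFrame({"age": [60], "year": [2019], "rate": [0.5]})
        E = expected_counts(areas, {2019: (60,)}, rates, "one-year",
                            periods={"one-year": (2019, 2019)})
        np.testing.assert_allclose(E["expected"], [50.0, 150.0])

    def test_missing_rate_cell_is_a_hard_error_naming_the_cell(self, small_system):
        rates = small_system["rates"]
        rates_missing = rates[~((rates["age"] == 60) & (rates["year"] == 2019))]
        with pytest.raises(KeyError, match="age=60, year=2019"):
            expected_counts(small_system["areas"], ELIGIBILITY_SCHEDULE,
                            rates_missing, "2019-2020")

    def test_national_calibration_identity(self, small_system):
        """With internally derived rates, total expected equals total
        observed screens (up to rounding of the national invitee margins)."""
        E = small_system["expected"]["expected"].sum()
        obs = small_system["counts"].area["screened"].sum()
        assert E == pytest.approx(obs, rel=1e-4)

    def test_expanding_the_schedule_never_decreases_expected(self, small_system):
        narrow = {2019: (50, 55, 60, 65, 70), 2020: (50, 55, 60, 65, 70)}
        wide = {2019: (50, 52, 55, 60, 64, 65, 70), 2020: (50, 52, 55, 60, 64, 65, 70)}
        rates = small_system["rates"].copy()
        # provide rates for every age used
        extra = []
        for year in (2019, 2020):
            for age in set(wide[year]):
                if not ((rates.age == age) & (rates.year == year)).any():
                    extra.append({"age": age, "year": year, "rate": 0.4})
        rates = pd.concat([rates, pd.DataFrame(extra)], ignore_index=True)
        E1 = expected_counts(small_system["areas"], narrow, rates, "2019-2020")
        E2 = expected_counts(small_system["areas"], wide, rates, "2019-2020")
        assert (E2["expected"].to_numpy() >= E1["expected"].to_numpy() - 1e-12).all()


class TestSPR:
    def test_observed_equal_expected_gives_unity(self):
        obs = ScreeningCounts(area=pd.DataFrame({
            "area_id": ["a", "b"], "period": ["p", "p"],
            "invitees": [200, 300], "screened": [100, 150]}))
        exp = pd.DataFrame({"area_id": ["a", "b"], "period": ["p", "p"],
                            "expected": [100.0, 150.0]})
        assert (compute_spr(obs, exp)["spr"] == 1.0).all()

    def test_simple_ratio(self):
        obs = ScreeningCounts(area=pd.DataFrame({
            "area_id": ["a"], "period": ["p"], "invitees": [500], "screened": [120]}))
        exp = pd.DataFrame({"area_id": ["a"], "period": ["p"], "expected": [100.0]})
        assert compute_spr(obs, exp)["spr"].iloc[0] == pytest.approx(1.2)

    def test_key_mismatch_reports_offending_ids(self):
        obs = ScreeningCounts(area=pd.DataFrame({
            "area_id": ["a"], "period": ["p"], "invitees": [10], "screened": [5]}))
        exp = pd.DataFrame({"area_id": ["b"], "period": ["p"], "expected": [5.0]})
        with pytest.raises(ValueError, match="mismatch"):
            compute_spr(obs, exp)

    def test_zero_expected_with_positive_observed_rejected(self):
        obs = ScreeningCounts(area=pd.DataFrame({
            "area_id": ["a"], "period": ["p"], "invitees": [10], "screened": [5]}))
        exp = pd.DataFrame({"area_id": ["a"], "period": ["p"], "expected": [0.0]})
        with pytest.raises(ValueError, match="zero expected"):
            compute_spr(obs, exp)

    def test_weighted_mean_spr_is_one_under_internal_rates(self, small_system):
        spr = small_system["spr"].set_index("area_id")
        E = small_system["expected"].set_index("area_id")["expected"]
        weighted = np.average(spr.loc[E.index, "spr"], weights=E)
        assert weighted == pytest.approx(1.0, abs=1e-3)


class TestExclusions:
    def test_all_large_areas_is_identity(self, small_system):
        areas, counts, log = apply_exclusions(
            small_system["areas"], small_system["counts"], min_mean_pop=5)
        assert len(areas) == len(small_system["areas"])
        assert log == []

    def test_small_population_area_removed_and_logged(self, small_system):
        areas = small_system["areas"].copy()
        victim = areas["area_id"].iloc[0]
        for col in [c for c in areas.columns if c.startswith("pop_")]:
            areas.loc[0, col] = 1
        kept, counts, log = apply_exclusions(areas, small_system["counts"])
        assert victim not in set(kept["area_id"])
        assert log[0]["reason"] == "small_population"
        assert victim in log[0]["area_ids"]

    def test_island_flag_removed(self, small_system):
        areas = small_system["areas"].copy()
        areas["island"] = False
        areas.loc[3, "island"] = True
        kept, _, log = apply_exclusions(areas, small_system["counts"])
        assert areas.loc[3, "area_id"] not in set(kept["area_id"])
        assert any(e["reason"] == "island" for e in log)

    def test_suppressed_fraction_below_half_percent(self, small_system):
        """Suppressing 0.4% of records excludes <0.5% of screened people."""
        rng = np.random.default_rng(9)
        area = small_system["counts"].area.copy()
        area["suppressed"] = rng.random(len(area)) < 0.004
        counts = ScreeningCounts(area=area, national=small_system["counts"].national)
        _, _, log = apply_exclusions(small_system["areas"], counts)
        entries = [e for e in log if e["reason"] == "suppressed_record"]
        if entries:
            assert entries[0]["screened_fraction"] < 0.005


class TestPublishedMargins:
    def test_margins_table_loads_with_all_periods(self):
        t = load_national_margins()
        assert set(t["period"]) == set(PERIODS)
        assert len(t) == 54

    def test_remoteness_margins_sum_to_total(self):
        """Remoteness rows partition the invitee population exactly."""
        t = load_national_margins()
        for period, sub in t.groupby("period"):
            total = sub.loc[sub.group_type == "total"]
            rem = sub.loc[sub.group_type == "remoteness"]
            assert rem["invitees"].sum() == total["invitees"].iloc[0]
            assert rem["screened"].sum() == total["screened"].iloc[0]
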