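import datetime as dt
import math

import pytest

from pre2dup import (
    AtcParams,
    GlobalParams,
    InstitutionalStay,
    PackageParams,
    ParameterSpace,
    Purchase,
)
from pre2dup.core import (
    Limit,
    build_periods,
    combined_two_purchase_reach,
    expected_refill_length,
    period_end,
    run_pipeline,
    single_purchase_duration,
    stockpiling_test,
    supply_days,
)
from pre2dup.io import merge_stays, sort_histories
from pre2dup.preprocess import preprocess_history
from pre2dup.synthetic import default_cohort_profiles, generate_cohort, matching_parameter_space

from helpers import START, assert_period_invariants, make_history

GLOB = GlobalParams()
EMPTY = ParameterSpace()

ATC = AtcParams(
    atc_prefix="N05A",
    min_ddd_per_day=0.1,
    common_ddd_per_day=1.0,
    min_period_days=15,
    max_refill_days=120,
)
PKG = PackageParams(
    vnr="141473",
    min_refill_days=5,
    max_refill_days=36,
    typical_refill_days=10,
    ddd_per_day_at_min=2.0,
    ddd_per_day_at_max=0.28,
    ddd_per_day_typical=1.0,
)
SPACE = ParameterSpace(atc_table={"N05A": ATC}, vnr_table={"141473": PKG})


def purchase(ddd=10.0, vnr=None, n_packages=1, date=START, atc="N05AH02"):
    return Purchase("P1", date, atc, vnr, n_packages, ddd)


class TestExpectedRefillLength:
    def test_plain_ratio(self):
        res = expected_refill_length(purchase(10.0), 0.8, 0.0, EMPTY)
        assert res.erfl_days == pytest.approx(12.5)
        assert res.limit_applied is Limit.NONE

    def test_regularity_multiplier(self):
        res = expected_refill_length(purchase(10.0), 1.0, 0.4, EMPTY)
        assert res.erfl_days == pytest.approx(12.0)  # 1 + 0.5·0.4 = 1.2

    def test_dose_below_atc_lower_limit_splits(self):
        res = expected_refill_length(purchase(10.0), 0.05, 0.0, ParameterSpace(atc_table={"N05A": ATC}))
        assert res.limit_applied is Limit.LOWER_DOSE_SPLIT
        # no package: fall back on the common ATC dose for the duration
        assert res.erfl_days == pytest.approx(10.0)

    def test_dose_below_package_lower_limit_uses_package_length(self):
        res = expected_refill_length(purchase(10.0, vnr="141473"), 0.2, 0.0, SPACE)
        assert res.limit_applied is Limit.LOWER_DOSE_SPLIT
        assert res.erfl_days == pytest.approx(10.0)  # typical 10 d × 1 pack

    def test_global_dose_cap(self):
        res = expected_refill_length(purchase(10.0), 25.0, 0.0, EMPTY)
        assert res.dose_used == pytest.approx(GLOB.max_ddd_per_day)
        assert res.limit_applied is Limit.GLOBAL_DOSE_CAP
        assert res.erfl_days == pytest.approx(1.0)

    def test_package_dose_ceiling_tightens_global_cap(self):
        res = expected_refill_length(purchase(10.0, vnr="141473"), 5.0, 0.0, SPACE)
        assert res.dose_used == pytest.approx(2.0)

    def test_package_maximum_truncates_long_lengths(self):
        res = expected_refill_length(purchase(200.0, vnr="141473"), 1.0, 0.0, SPACE)
        assert res.erfl_days == pytest.approx(36.0)
        assert res.limit_applied is Limit.PACKAGE_MAX

    def test_atc_maximum_when_no_package(self):
        res = expected_refill_length(purchase(200.0), 1.0, 0.0, ParameterSpace(atc_table={"N05A": ATC}))
        assert res.erfl_days == pytest.approx(120.0)
        assert res.limit_applied is Limit.ATC_MAX


class TestStockpilingTest:
    @pytest.mark.parametrize(
        "triple,expect",
        [
            ((1.33, 0.80, 0.92), True),
            ((0.8, 0.9, 1.0), False),
            ((1.0, 1.0, 1.0), False),  # strict inequality
            ((None, 0.8, 1.0), False),
            ((1.0, 0.8, None), False),
        ],
    )
    def test_local_minimum_rule(self, triple, expect):
        assert stockpiling_test(*triple) is expect

    def test_combined_reach_of_pooled_purchases(self):
        prev = purchase(10.0, date=START)
        cur = purchase(10.0, date=START + dt.timedelta(days=5))
        reach = combined_two_purchase_reach(prev, cur, 1.0, 0.0, EMPTY)
        assert reach == pytest.approx(20.0)  # covers 5 + 15 exactly


class TestSinglePurchaseDuration:
    def test_population_mode_times_packages(self):
        days, source = single_purchase_duration(
            purchase(30.0, vnr="010940"), {"010940": 98}, None, EMPTY
        )
        assert days == 98.0 and source == "refill_mode"

    def test_adherence_adjusted_amount_hits_the_cap(self):
        pkg = PackageParams("5", 30, 300, 200, 1.0, 0.3, 0.5)
        space = ParameterSpace(vnr_table={"5": pkg})
        days, source = single_purchase_duration(purchase(100.0, vnr="5"), {}, None, space)
        assert days == 150.0 and source == "typical_dose"  # 100·1.2/0.5 = 240 → cap

    def test_neighbor_period_dose_wins(self):
        days, source = single_purchase_duration(purchase(30.0), {}, 2.0, EMPTY)
        assert days == 15.0 and source == "neighbor_dose"

    def test_atc_minimum_length_fallback(self):
        days, source = single_purchase_duration(
            Purchase("P1", START, "N05AH02"), {}, None, ParameterSpace(atc_table={"N05A": ATC})
        )
        assert days == 15.0 and source == "atc_min_period"

    def test_nothing_known_flags_one_day(self):
        days, source = single_purchase_duration(Purchase("P1", START, "N05AH02"), {}, None, EMPTY)
        assert days == 1.0 and source == "unmodelled"


class TestPeriodEnd:
    def test_supply_matches_closed_form(self):
        for k in (1, 2, 5, 20):
            for cv in (0.0, 0.3):
                expect = 10.0 * (1 + 0.5 * cv) / (1.0 * (1 + math.exp(-k)))
                assert supply_days(10.0, 1.0, cv, k, GLOB) == pytest.approx(expect, rel=1e-12)

    def test_damping_vanishes_for_long_periods(self):
        assert supply_days(10.0, 1.0, 0.0, 60, GLOB) == pytest.approx(10.0, abs=1e-9)

    def test_end_date_rounds_down(self):
        end = period_end(purchase(10.0), 1.0, 0.0, 5, [], GLOB)
        assert end == START + dt.timedelta(days=9)  # 9.93 days → 9

    def test_short_stay_inside_extension_adds_days(self):
        stays = [(START + dt.timedelta(days=2), START + dt.timedelta(days=7))]
        end = period_end(purchase(10.0), 1.0, 0.0, 20, stays, GLOB)
        assert end == START + dt.timedelta(days=15)  # 10 supply + 5 hospital

    def test_long_stay_truncates_at_admission(self):
        stays = [(START + dt.timedelta(days=3), START + dt.timedelta(days=43))]
        end = period_end(purchase(100.0), 1.0, 0.0, 20, stays, GLOB)
        assert end == START + dt.timedelta(days=3)

    def test_hospital_days_found_by_the_growing_window(self):
        # the stay begins after the base supply ends but inside the
        # extension produced by an earlier stay
        stays = [
            (START + dt.timedelta(days=2), START + dt.timedelta(days=12)),
            (START + dt.timedelta(days=21), START + dt.timedelta(days=26)),
        ]
        end = period_end(purchase(20.0), 1.0, 0.0, 20, stays, GLOB)
        assert end == START + dt.timedelta(days=35)  # 20 + 10 + 5


class TestBuildPeriods:
    def _build(self, history, space, stays=None):
        merged = merge_stays(stays or [])
        gaps, profile = preprocess_history(history, merged, space.global_params)
        return build_periods(history, profile, gaps, {}, merged, space)

    def test_stockpiling_history_stays_one_period(self):
        h = make_history([10, 5, 15, 10], vnr="141473")
        (period,) = self._build(h, SPACE)
        assert period.n_purchases == 5
        assert period.start == START
        assert period.total_ddd == pytest.approx(50.0)
        assert period.mean_ddd_per_day == pytest.approx(1.0)

    def test_long_break_makes_two_single_periods(self):
        h = make_history([400], vnr="141473")
        periods = self._build(h, SPACE)
        assert [p.n_purchases for p in periods] == [1, 1]

    def test_two_purchases_join_within_package_reach(self):
        h = make_history([30], vnr="141473")
        (period,) = self._build(h, SPACE)  # 30 ≤ 36 = package max
        assert period.n_purchases == 2

    def test_two_purchases_beyond_reach_stay_single(self):
        h = make_history([50], vnr="141473")
        periods = self._build(h, SPACE)
        assert [p.n_purchases for p in periods] == [1, 1]

    def test_low_dose_split_closes_period(self):
        # steady 10-day refills, then a 90-day crawl: the sliding dose
        # sinks below the ATC lower limit of 0.1 and the period splits
        h = make_history([10, 10, 10, 90, 90, 90, 90], ddd=[10, 10, 10, 1, 1, 1, 1, 1])
        space = ParameterSpace(atc_table={"N05A": ATC})
        periods = self._build(h, space)
        assert len(periods) > 1

    def test_unbridgeable_stay_splits_connection(self):
        h = make_history([60], vnr="141473", ddd=60.0)
        stay = InstitutionalStay(
            "P1", START + dt.timedelta(days=10), START + dt.timedelta(days=50)
        )
        periods = self._build(h, SPACE, [stay])
        assert len(periods) == 2

    def test_single_purchase_borrows_dose_from_nearest_period(self):
        # five regular purchases, then a lone purchase two years later
        h = make_history([10, 10, 10, 10, 800], ddd=[10, 10, 10, 10, 10, 30])
        space = ParameterSpace(atc_table={"N05A": ATC})
        periods = self._build(h, space)
        assert [p.n_purchases for p in periods] == [5, 1]
        lone = periods[-1]
        assert any(f == "single:neighbor_dose" for f in lone.flags)
        assert lone.length_days == pytest.approx(30.0, abs=1)  # 30 DDD at ~1/day

    def test_extension_never_overlaps_next_period(self):
        # huge amount would extend past the restart purchase
        h = make_history([10, 10, 10, 310], ddd=[10, 10, 10, 200, 10])
        space = ParameterSpace(atc_table={"N05A": ATC})
        periods = self._build(h, space)
        for a, b in zip(periods, periods[1:]):
            assert a.end < b.start

    def test_span_does_not_shrink_when_a_purchase_is_added(self):
        # constant-dose refills: an extra mid-gap purchase adds stock
        base = make_history([30, 30, 30, 30], ddd=30.0)
        denser = make_history([30, 30, 15, 15, 30], ddd=30.0)
        space = ParameterSpace(atc_table={"N05A": ATC})
        (p1,) = self._build(base, space)
        (p2,) = self._build(denser, space)
        assert p2.length_days >= p1.length_days


class TestRunPipeline:
    def test_empty_input(self):
        result = run_pipeline([], [], EMPTY)
        assert result.periods == [] and result.n_iterations == 1 and result.converged

    def test_fixed_point_when_no_mode_reaches_threshold(self):
        h = make_history([10, 5, 15, 10], vnr="141473")
        result = run_pipeline(list(h.purchases), [], SPACE)
        assert result.n_iterations == 2 and result.converged
        assert result.modes == {}

    def test_learned_mode_overrides_expert_typical_length(self):
        profiles = [
            # an expert guessed 49 days; the population refills at 98
            p
            for i in range(25)
            for p in [
                __import__("pre2dup").PersonProfile(
                    person_id=f"M{i:03d}",
                    atc="C10AA01",
                    vnr="010940",
                    true_dose=0.33,
                    package_ddd=32.34,
                    n_purchases=8,
                    refill_jitter=0.05,
                )
            ]
        ]
        purchases, stays, _ = generate_cohort(
            profiles, dt.date(2002, 1, 1), dt.date(2009, 12, 31), seed=5
        )
        space = matching_parameter_space(profiles)
        # make one person a single buyer whose duration exposes the mode
        lone = Purchase("LONE", dt.date(2004, 1, 1), "C10AA01", "010940", 1, 32.34)
        result = run_pipeline(purchases + [lone], stays, space, max_iter=4)
        assert result.modes.get("010940") == 98
        lone_periods = [p for p in result.periods if p.person_id == "LONE"]
        assert lone_periods[0].length_days == 98

    def test_determinism(self):
        profiles = default_cohort_profiles(n_per_kind=3)
        purchases, stays, _ = generate_cohort(
            profiles, dt.date(2002, 1, 1), dt.date(2009, 12, 31), seed=3
        )
        space = matching_parameter_space(profiles)
        r1 = run_pipeline(purchases, stays, space)
        r2 = run_pipeline(purchases, stays, space)
        assert r1.periods == r2.periods and r1.modes == r2.modes


def test_structural_invariants_on_a_mixed_cohort():
    profiles = default_cohort_profiles(n_per_kind=10)
    purchases, stays, _ = generate_cohort(
        profiles, dt.date(2002, 1, 1), dt.date(2009, 12, 31), seed=7
    )
    space = matching_parameter_space(profiles)
    result = run_pipeline(purchases, stays, space)
    assert_period_invariants(result.periods, purchases, stays, space)
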