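import datetime as dt
import statistics

import pytest
from hypothesis import given, strategies as st

from pre2dup import GlobalParams, InstitutionalStay, Purchase
from pre2dup.io import sort_histories
from pre2dup.preprocess import (
    calculated_refill_times,
    compute_cv,
    compute_ddd_avg,
    compute_gaps,
    preprocess_history,
)

from helpers import START, eq1_reference, make_history

GLOB = GlobalParams()


class TestGaps:
    def test_hospital_days_subtract_from_raw_gap(self):
        h = make_history([30])
        stay = InstitutionalStay("P1", START + dt.timedelta(days=5), START + dt.timedelta(days=15))
        gaps = compute_gaps(h, [stay], GLOB)
        assert gaps.raw_gap_days == (30,)
        assert gaps.hospital_days_in_gap == (10,)
        assert gaps.net_gap_days == (20,)

    def test_long_gap_starts_new_segment(self):
        gaps = compute_gaps(make_history([400]), None, GLOB)
        assert gaps.segment_id == (0, 1)

    def test_gap_fully_in_hospital_floors_at_one_day(self):
        h = make_history([20])
        stay = InstitutionalStay("P1", START, START + dt.timedelta(days=25))
        gaps = compute_gaps(h, [stay], GLOB)
        assert gaps.net_gap_days == (1,)

    def test_segmentation_uses_net_not_raw_gap(self):
        # 400 raw days, 150 of them in hospital: net 250 < 300, no restart
        h = make_history([400])
        stay = InstitutionalStay("P1", START + dt.timedelta(days=10), START + dt.timedelta(days=160))
        gaps = compute_gaps(h, [stay], GLOB)
        assert gaps.segment_id == (0, 0)

    @given(
        st.lists(st.integers(1, 120), min_size=1, max_size=6),
        st.lists(
            st.tuples(st.integers(0, 400), st.integers(1, 60)), max_size=5
        ),
    )
    def test_hospital_count_matches_day_enumeration(self, gap_list, stay_spec):
        h = make_history(gap_list)
        stays = [
            InstitutionalStay(
                "P1",
                START + dt.timedelta(days=off),
                START + dt.timedelta(days=off + length),
            )
            for off, length in stay_spec
        ]
        gaps = compute_gaps(h, stays, GLOB)
        in_hospital = set()
        for s in stays:
            d = s.admission
            while d < s.discharge:
                in_hospital.add(d)
                d += dt.timedelta(days=1)
        for (a, b), counted in zip(
            zip(h.purchases, h.purchases[1:]), gaps.hospital_days_in_gap
        ):
            expect = sum(
                1
                for i in range((b.date - a.date).days)
                if a.date + dt.timedelta(days=i) in in_hospital
            )
            assert counted == expect


class TestSlidingAverage:
    def test_worked_stockpiling_example(self):
        h = make_history([10, 5, 15, 10])
        profile = compute_ddd_avg(h, compute_gaps(h, None, GLOB), GLOB)
        assert [round(v, 4) for v in profile.ddd_avg] == [
            1.0909,
            1.3333,
            0.8,
            0.9231,
            1.0,
        ]
        refill = calculated_refill_times(h, profile)
        assert [round(v, 2) for v in refill] == [9.17, 7.5, 12.5, 10.83, 10.0]

    def test_constant_dosing_gives_unit_average(self):
        h = make_history([20, 20, 20, 20], ddd=20.0)
        profile = compute_ddd_avg(h, compute_gaps(h, None, GLOB), GLOB)
        assert all(v == pytest.approx(1.0) for v in profile.ddd_avg)

    def test_too_few_purchases_skip_preprocessing(self):
        h = make_history([30])
        profile = compute_ddd_avg(h, compute_gaps(h, None, GLOB), GLOB)
        assert profile.ddd_avg == (None, None)

    def test_short_segment_left_unprocessed_longer_one_computed(self):
        h = make_history([30, 400, 30, 30, 30])
        profile = compute_ddd_avg(h, compute_gaps(h, None, GLOB), GLOB)
        assert profile.ddd_avg[0] is None and profile.ddd_avg[1] is None
        assert all(v is not None for v in profile.ddd_avg[2:])

    def test_missing_ddd_poisons_only_touching_windows(self):
        h = make_history([10, 10, 10, 10], ddd=[10, 10, None, 10, 10])
        profile = compute_ddd_avg(h, compute_gaps(h, None, GLOB), GLOB)
        assert profile.ddd_avg[1] is None and profile.ddd_avg[2] is None
        assert profile.ddd_avg[3] is None  # neighbour window touches
        assert profile.ddd_avg[0] is not None

    @given(
        st.integers(3, 9).flatmap(
            lambda n: st.tuples(
                st.lists(
                    st.floats(1.0, 200.0, allow_nan=False), min_size=n, max_size=n
                ),
                st.lists(st.integers(1, 250), min_size=n - 1, max_size=n - 1),
            )
        )
    )
    def test_agrees_with_independent_transcription(self, case):
        ddds, gap_list = case
        h = make_history(gap_list, ddd=ddds)
        profile = compute_ddd_avg(h, compute_gaps(h, None, GLOB), GLOB)
        expect = eq1_reference(ddds, gap_list)
        for got, want in zip(profile.ddd_avg, expect):
            assert got == pytest.approx(want, abs=1e-9)

    @given(st.floats(0.1, 50.0, allow_nan=False))
    def test_scale_equivariance(self, c):
        base = make_history([10, 5, 15, 10])
        scaled = make_history([10, 5, 15, 10], ddd=10.0 * c)
        p1 = compute_cv(compute_ddd_avg(base, compute_gaps(base, None, GLOB), GLOB))
        p2 = compute_cv(compute_ddd_avg(scaled, compute_gaps(scaled, None, GLOB), GLOB))
        for a, b in zip(p1.ddd_avg, p2.ddd_avg):
            assert b == pytest.approx(a * c, rel=1e-9)
        assert p2.ddd_avg_cv == pytest.approx(p1.ddd_avg_cv, rel=1e-9)

    def test_hospital_neutrality(self):
        # a stay of d days inside a gap lengthened by d leaves doses alone
        plain = make_history([10, 5, 15, 10])
        widened = make_history([10, 5, 15 + 12, 10])
        stay = InstitutionalStay(
            "P1",
            START + dt.timedelta(days=16),
            START + dt.timedelta(days=28),
        )
        p1 = compute_ddd_avg(plain, compute_gaps(plain, None, GLOB), GLOB)
        p2 = compute_ddd_avg(widened, compute_gaps(widened, [stay], GLOB), GLOB)
        for a, b in zip(p1.ddd_avg, p2.ddd_avg):
            assert b == pytest.approx(a, rel=1e-12)


class TestCoefficientOfVariation:
    def test_equal_averages_give_zero(self):
        h = make_history([10, 10, 10], ddd=10.0)
        profile = compute_cv(compute_ddd_avg(h, compute_gaps(h, None, GLOB), GLOB))
        assert profile.ddd_avg_cv == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_statistics_routine(self):
        h = make_history([10, 5, 15, 10])
        profile = compute_cv(compute_ddd_avg(h, compute_gaps(h, None, GLOB), GLOB))
        values = [v for v in profile.ddd_avg if v is not None]
        assert profile.ddd_avg_cv == pytest.approx(
            statistics.stdev(values) / statistics.fmean(values)
        )

    def test_missing_below_two_values(self):
        h = make_history([30])
        profile = compute_cv(compute_ddd_avg(h, compute_gaps(h, None, GLOB), GLOB))
        assert profile.ddd_avg_cv is None
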