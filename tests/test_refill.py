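import datetime as dt

import pytest
from hypothesis import given, strategies as st

from pre2dup import GlobalParams, Purchase
from pre2dup.core import run_pipeline
from pre2dup.refill import (
    build_refill_distributions,
    collect_refill_observations,
    join_to_local_maxima,
    read_mode_table,
    select_mode,
    write_mode_table,
)
from pre2dup.synthetic import PersonProfile, generate_cohort, matching_parameter_space

GLOB = GlobalParams()


def _period(n, gap_days=30, vnr="111", n_packages=1, dose_dispensing=False):
    """A stand-in period object carrying member purchases."""

    class P:
        pass

    p = P()
    p.purchases = tuple(
        Purchase(
            "P1",
            dt.date(2005, 1, 1) + dt.timedelta(days=gap_days * i),
            "N05AH02",
            vnr,
            n_packages,
            30.0,
            dose_dispensing,
        )
        for i in range(n)
    )
    return p


class TestCollect:
    def test_six_monthly_purchases_give_five_observations(self):
        obs = collect_refill_observations([_period(6)], GLOB)
        assert obs == {"111": {30: 5}}

    def test_five_purchase_period_contributes_nothing(self):
        assert collect_refill_observations([_period(5)], GLOB) == {}

    def test_multi_pack_purchase_normalised_per_package(self):
        obs = collect_refill_observations([_period(6, gap_days=60, n_packages=2)], GLOB)
        assert obs == {"111": {30: 5}}

    def test_dose_dispensing_excluded(self):
        assert collect_refill_observations([_period(6, dose_dispensing=True)], GLOB) == {}

    def test_mixed_vnr_rows_excluded(self):
        period = _period(6)
        mixed = Purchase(
            "P1", period.purchases[0].date, "N05AH02", None, 2, 30.0, vnr_mixed=True
        )
        period.purchases = (mixed,) + period.purchases[1:]
        obs = collect_refill_observations([period], GLOB)
        assert sum(obs["111"].values()) == 4  # first gap dropped


class TestJoining:
    def test_single_bin_unchanged(self):
        assert join_to_local_maxima({30: 7}) == {30: 7}

    def test_neighbouring_mass_climbs_to_the_peak(self):
        raw = {28: 5, 29: 10, 30: 100, 31: 8, 98: 50}
        assert join_to_local_maxima(raw) == {30: 123, 98: 50}

    def test_shoulder_can_beat_the_raw_peak(self):
        # a broad shoulder outweighs a narrow higher peak after joining
        raw = {90: 30, 91: 29, 92: 28, 98: 31}
        joined = join_to_local_maxima(raw)
        day, _ = max(joined.items(), key=lambda kv: kv[1])
        assert day == 90 and joined[90] == 87

    @given(
        st.dictionaries(st.integers(1, 120), st.integers(1, 60), min_size=1, max_size=25)
    )
    def test_conservation_and_idempotence(self, raw):
        joined = join_to_local_maxima(raw)
        assert sum(joined.values()) == sum(raw.values())
        assert join_to_local_maxima(joined) == joined


class TestModeSelection:
    def test_highest_joined_count_wins(self):
        assert select_mode({30: 123, 98: 50}, GLOB) == 30

    def test_threshold_is_strict(self):
        assert select_mode({30: 8}, GLOB) is None
        assert select_mode({30: 10}, GLOB) is None
        assert select_mode({30: 11}, GLOB) == 30

    def test_ties_break_toward_shorter_length(self):
        assert select_mode({98: 40, 30: 40}, GLOB) == 30


def test_mode_table_round_trip(tmp_path):
    dists = build_refill_distributions([_period(12)], GLOB)
    f = tmp_path / "modes.tsv"
    write_mode_table(dists, f)
    assert read_mode_table(f) == {"111": 30}


def test_mode_recovery_on_simulated_98_day_package():
    # ≥30 persons buying a 98-unit pack at one unit (0.33 DDD) per day:
    # the learned refill length is the pack size
    profiles = [
        PersonProfile(
            person_id=f"R{i:03d}",
            atc="C10AA01",
            vnr="010940",
            true_dose=0.33,
            package_ddd=32.34,
            refill_jitter=0.05,
            n_purchases=8,
        )
        for i in range(30)
    ]
    purchases, stays, _ = generate_cohort(
        profiles, dt.date(2002, 1, 1), dt.date(2009, 12, 31), seed=11
    )
    space = matching_parameter_space(profiles)
    result = run_pipeline(purchases, stays, space, max_iter=2)
    dists = build_refill_distributions(result.periods, GLOB)
    assert dists["010940"].mode_days == 98
    assert sum(dists["010940"].raw_hist.values()) >= 30
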