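"""Supply schedules, carry-over arithmetic, outcomes and censoring."""

from datetime import date, timedelta
from fractions import Fraction

import numpy as np
import pytest

import rxpersist as rx
from rxpersist.errors import (
    ConfigError,
    MalformedIntervalError,
    NoIndexTherapyError,
)

from conftest import BASE, mk_fill, schedule_for
from oracles import day_sim_outcome


def rel_end(schedule):
    return schedule.supply_end - BASE.toordinal()


class TestSupplySchedule:
    def test_single_fill_rate_one(self):
        s = schedule_for([mk_fill(0, 100)])
        assert rel_end(s) == 100

    def test_early_refill_carries_remaining_tablets(self):
        s = schedule_for([mk_fill(0, 100), mk_fill(90, 100)])
        assert rel_end(s) == 200  # 10 remaining tablets carried into day 90

    def test_same_day_fills_consumed_successively(self):
        s = schedule_for([mk_fill(0, 100), mk_fill(0, 100)])
        assert rel_end(s) == 200

    def test_carry_over_consumed_at_new_dose(self):
        s = schedule_for([mk_fill(0, 90), mk_fill(60, 90, "2 tablets daily")])
        assert rel_end(s) == 120  # 60 + (30 + 90) / 2

    def test_fractional_dose_duration_exact(self):
        s = schedule_for([mk_fill(0, 45, "1/2 tablet daily")])
        assert rel_end(s) == 90

    def test_gap_restarts_fresh_segment(self):
        s = schedule_for([mk_fill(0, 30), mk_fill(100, 30)])
        assert [(iv.start - BASE.toordinal(), iv.end - BASE.toordinal())
                for iv in s.intervals] == [(0, 30), (100, 130)]

    def test_tablet_conservation_after_carry_over(self):
        s = schedule_for(
            [mk_fill(0, 90), mk_fill(50, 90, "2 tablets daily"), mk_fill(80, 30)]
        )
        assert s.tablets_accounted() == s.total_tablets == 210

    def test_same_day_different_strength_logged_as_anomaly(self):
        fills = [mk_fill(0, 50, strength=25.0), mk_fill(0, 50, strength=50.0)]
        s = schedule_for(fills)
        assert rel_end(s) == 100
        assert len(s.anomalies) == 1

    def test_empty_fill_list_raises(self):
        with pytest.raises(NoIndexTherapyError):
            rx.build_supply_schedule([], [])

    def test_mixed_classes_rejected(self):
        fills = [mk_fill(0, 50), mk_fill(10, 50, atc="C09AA02")]
        with pytest.raises(ValueError):
            schedule_for(fills)


class TestDetermineOutcome:
    def test_refill_within_grace_continues_episode(self):
        fills = [mk_fill(0, 100), mk_fill(125, 100)]
        o = rx.determine_outcome(schedule_for(fills), fills)
        assert o.status is rx.Status.DISCONTINUED
        assert o.event_time_days == 225

    def test_refill_after_grace_cannot_rescue(self):
        fills = [mk_fill(0, 100), mk_fill(135, 100)]
        o = rx.determine_outcome(schedule_for(fills), fills)
        assert o.status is rx.Status.DISCONTINUED
        assert o.event_time_days == 100

    def test_other_class_fill_in_grace_window_is_switch(self):
        idx = [mk_fill(0, 100)]
        other = mk_fill(110, 100, atc="C09AA02")
        o = rx.determine_outcome(schedule_for(idx), idx + [other])
        assert o.status is rx.Status.SWITCHED
        assert o.event_time_days == 100
        assert o.switch_date == BASE + timedelta(days=110)
        assert o.switch_to_class is rx.DrugClass.ACE_INHIBITOR

    def test_other_class_fill_during_supply_is_addon_not_switch(self):
        idx = [mk_fill(100 * k, 100) for k in range(8)]
        other = mk_fill(50, 100, atc="C09AA02")
        o = rx.determine_outcome(schedule_for(idx), idx + [other])
        assert o.status is rx.Status.PERSISTENT
        assert o.addon
        assert o.event_time_days == 730

    def test_supply_within_grace_of_horizon_is_persistent(self):
        fills = [mk_fill(0, 100, "1 tablet daily")]
        o = rx.determine_outcome(schedule_for(fills), fills, followup_days=120)
        # supply ends day 100, 100 + 30 >= 120: cannot observe discontinuation
        assert o.status is rx.Status.PERSISTENT
        assert o.event_time_days == 120

    def test_event_at_supply_end_plus_grace(self):
        fills = [mk_fill(0, 100)]
        o = rx.determine_outcome(schedule_for(fills), fills, event_at="supply_end_plus_grace")
        assert o.event_time_days == 130

    def test_invalid_config_rejected(self):
        fills = [mk_fill(0, 100)]
        s = schedule_for(fills)
        with pytest.raises(ConfigError):
            rx.determine_outcome(s, fills, grace_days=-1)
        with pytest.raises(ConfigError):
            rx.determine_outcome(s, fills, followup_days=0)


class TestCensoring:
    def _discontinued(self):
        fills = [mk_fill(0, 100)]
        return rx.determine_outcome(schedule_for(fills), fills)

    def test_death_before_event_censors(self):
        o = rx.apply_censoring(self._discontinued(), death_date=BASE + timedelta(days=60))
        assert o.status is rx.Status.CENSORED
        assert o.censor_reason is rx.CensorReason.DEATH
        assert o.event_time_days == 60

    def test_death_after_event_leaves_event(self):
        o = rx.apply_censoring(self._discontinued(), death_date=BASE + timedelta(days=200))
        assert o.status is rx.Status.DISCONTINUED
        assert o.event_time_days == 100

    @pytest.mark.parametrize("length, censored", [(15, False), (21, False), (22, True)])
    def test_hospitalization_threshold(self, length, censored):
        hosp = [(BASE + timedelta(days=30), BASE + timedelta(days=30 + length))]
        o = rx.apply_censoring(self._discontinued(), hospitalizations=hosp)
        if censored:
            assert o.status is rx.Status.CENSORED
            assert o.censor_reason is rx.CensorReason.HOSPITALIZATION_GT21D
            assert o.event_time_days == 30
        else:
            assert o.status is rx.Status.DISCONTINUED

    def test_persistent_censored_at_end_of_followup(self):
        fills = [mk_fill(100 * k, 100) for k in range(8)]
        o = rx.determine_outcome(schedule_for(fills), fills)
        assert o.status is rx.Status.PERSISTENT
        c = rx.apply_censoring(o)
        assert c.status is rx.Status.CENSORED
        assert c.censor_reason is rx.CensorReason.END_OF_FOLLOWUP
        assert c.event_time_days == 730

    def test_tie_precedence_death_beats_hospitalization(self):
        day = BASE + timedelta(days=50)
        o = rx.apply_censoring(
            self._discontinued(),
            death_date=day,
            hospitalizations=[(day, day + timedelta(days=30))],
        )
        assert o.censor_reason is rx.CensorReason.DEATH

    def test_unit_bag_censor(self):
        o = rx.apply_censoring(self._discontinued(), unit_bag_start=BASE + timedelta(days=10))
        assert o.censor_reason is rx.CensorReason.UNIT_BAGS
        assert o.event_time_days == 10

    def test_malformed_hospitalization_rejected(self):
        with pytest.raises(MalformedIntervalError):
            rx.apply_censoring(
                self._discontinued(),
                hospitalizations=[(BASE + timedelta(days=10), BASE + timedelta(days=5))],
            )


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


def _random_history(rng, fractional=False):
    """Random single-patient history: index fills + other-class fills."""
    n = int(rng.integers(1, 7))
    doses = [Fraction(1, 2), Fraction(3, 2)] if fractional else [1, 2, 3]
    day = 0
    fills = []
    for _ in range(n):
        dose = doses[int(rng.integers(0, len(doses)))]
        tablets = int(rng.integers(5, 120))
        fills.append((day, tablets, dose))
        if rng.random() < 0.15:  # occasional same-day fill, same dose
            fills.append((day, int(rng.integers(5, 60)), dose))
        day += int(rng.integers(5, 160))
    others = [int(rng.integers(0, 500)) for _ in range(int(rng.integers(0, 3)))]
    return fills, others


_DOSE_TEXT = {
    1: "1 tablet daily", 2: "2 tablets daily", 3: "3 tablets daily",
    Fraction(1, 2): "1/2 tablet daily", Fraction(3, 2): "1.5 tablets daily",
}


def _run_pipeline(fills, others, grace=30, followup=730):
    recs = [mk_fill(d, n, _DOSE_TEXT[r]) for d, n, r in fills]
    other_recs = [mk_fill(d, 30, atc="C09AA02") for d in others]
    sched = schedule_for(recs)
    return rx.determine_outcome(sched, recs + other_recs,
                                grace_days=grace, followup_days=followup)


def test_matches_day_simulation_oracle():
    """Interval arithmetic agrees exactly with day-by-day consumption."""
    rng = np.random.default_rng(2024)
    for k in range(300):
        fractional = k % 3 == 0
        fills, others = _random_history(rng, fractional)
        o = _run_pipeline(fills, others)
        status, event, _ = day_sim_outcome(fills, others)
        assert (o.status.value, o.event_time_days) == (status, event), (fills, others)


def test_grace_monotonicity():
    """Longer grace never shortens an episode or revokes persistence."""
    rng = np.random.default_rng(7)
    for _ in range(80):
        fills, others = _random_history(rng)
        prev_time = -1
        prev_persistent = False
        for grace in (0, 10, 30, 60, 120):
            o = _run_pipeline(fills, [], grace=grace)
            assert o.event_time_days >= prev_time
            if prev_persistent:
                assert o.status is rx.Status.PERSISTENT
            prev_time = o.event_time_days
            prev_persistent = o.status is rx.Status.PERSISTENT


def test_conservation_property():
    rng = np.random.default_rng(11)
    for _ in range(100):
        fills, _ = _random_history(rng)
        recs = [mk_fill(d, n, _DOSE_TEXT[r]) for d, n, r in fills]
        s = schedule_for(recs)
        assert s.tablets_accounted() == s.total_tablets


def test_outcomes_deterministic():
    fills, others = _random_history(np.random.default_rng(3))
    a = _run_pipeline(fills, others)
    b = _run_pipeline(fills, others)
    assert a == b
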