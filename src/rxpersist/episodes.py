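"""Supply schedules and persistence episodes from dated fills.

Model
-----
Consumption of a fill starts on the fill day; a fill of ``n`` tablets
taken at ``r`` tablets/day covers ``n / r`` days.  Three rules knit the
fills of one drug class into a single coverage schedule:

* **Same-day fills** are consumed successively, each at its own parsed
  daily dose (the second starts where the first ends).
* **Early refills** (a fill strictly before the current supply end)
  trigger carry-over: the remaining tablets, computed exactly in
  rational arithmetic, are added to the new fill's count and consumed
  at the new fill's daily dose.
* **Late refills** start a fresh coverage segment on their fill day.

Durations are kept exact (:class:`fractions.Fraction`); whenever a
fractional supply end must be compared against calendar days it is
rounded *up* to the next whole day first, so a half-day remainder still
covers its final partial day.

A patient is **persistent** while every gap without supply is at most
``grace_days`` (default 30).  The episode ends at the first longer gap;
the event is dated at the end of supply (configurable to end of
supply + grace).  A fill of a *different* antihypertensive class in the
window from the first uncovered day through ``grace_days`` after it
classifies the episode as a **switch**; a different-class fill while
the index supply is still running is an **add-on**, never a switch.
Episodes are then censored at death, at admission of the first
hospitalization longer than 21 days, at the first unit-bag (multi-dose)
dispensing, or at end of follow-up, whichever comes first — earliest
candidate wins, ties broken death > hospitalization > unit bags > end
of follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from fractions import Fraction
from typing import Iterable, Optional, Sequence

from .atc import DrugClass, classify_atc
from .dosage import DosageParse
from .errors import (
    ConfigError,
    ContractViolationError,
    MalformedIntervalError,
    NoIndexTherapyError,
)


@dataclass(frozen=True)
class DispensingRecord:
    """One pharmacy fill event."""

    patient_id: str
    fill_date: date
    atc_code: str
    tablets: int
    strength_mg: float = 0.0
    dosage_text: str = ""
    unit_bag: bool = False

    def __post_init__(self) -> None:
        if self.tablets < 1:
            raise ValueError("tablets must be >= 1")
        if not self.atc_code:
            raise ValueError("atc_code must be non-empty")

    @property
    def day(self) -> int:
        return self.fill_date.toordinal()


@dataclass(frozen=True)
class SupplyInterval:
    """Half-open coverage interval [start, end) in ordinal-day units."""

    start: Fraction
    end: Fraction
    daily_dose: Fraction
    tablets: Fraction  # tablets consumed within this interval, incl. carried

    @property
    def length(self) -> Fraction:
        return self.end - self.start


@dataclass
class SupplySchedule:
    patient_id: str
    drug_class: DrugClass
    intervals: list[SupplyInterval]
    total_tablets: int
    anomalies: list[str] = field(default_factory=list)

    @property
    def index_day(self) -> int:
        return int(self.intervals[0].start)

    @property
    def supply_end(self) -> Fraction:
        return self.intervals[-1].end

    def tablets_accounted(self) -> Fraction:
        """Exact sum of length x dose over intervals (tablet conservation)."""
        return sum((iv.length * iv.daily_dose for iv in self.intervals), Fraction(0))


class Status(str, Enum):
    PERSISTENT = "persistent"
    DISCONTINUED = "discontinued"
    SWITCHED = "switched"
    CENSORED = "censored"


class CensorReason(str, Enum):
    NONE = "none"
    DEATH = "death"
    HOSPITALIZATION_GT21D = "hospitalization_gt21d"
    UNIT_BAGS = "unit_bags"
    END_OF_FOLLOWUP = "end_of_followup"


@dataclass(frozen=True)
class EpisodeOutcome:
    patient_id: str
    status: Status
    event_time_days: int
    index_date: date
    censor_reason: CensorReason = CensorReason.NONE
    switch_date: Optional[date] = None
    switch_to_class: Optional[DrugClass] = None
    addon_dates: tuple[date, ...] = ()

    @property
    def addon(self) -> bool:
        return len(self.addon_dates) > 0


def _ceil(x: Fraction) -> int:
    return math.ceil(x)


def build_supply_schedule(
    fills: Sequence[DispensingRecord],
    parses: Sequence[DosageParse],
) -> SupplySchedule:
    """Knit one drug class's fills into a coverage schedule.

    ``fills`` and ``parses`` are matched element-wise; input order is
    irrelevant (the operation sorts by fill date first, stably).
    """
    if not fills:
        raise NoIndexTherapyError("no fills: patient has no index therapy")
    if len(fills) != len(parses):
        raise ValueError("fills and parses must have equal length")
    classes = {classify_atc(f.atc_code) for f in fills}
    if len(classes) != 1:
        raise ValueError(f"fills span multiple drug classes: {sorted(c.value for c in classes)}")
    drug_class = classes.pop()

    pairs = sorted(zip(fills, parses), key=lambda fp: fp[0].day)
    intervals: list[SupplyInterval] = []
    anomalies: list[str] = []
    end: Fraction | None = None
    cur_dose: Fraction | None = None
    last_day: int | None = None
    last_fill: DispensingRecord | None = None

    for fill, parse in pairs:
        dose = parse.daily_dose
        if dose <= 0:
            raise ContractViolationError("non-positive daily dose")
        d = fill.day
        if end is None or Fraction(d) >= end:
            # fresh segment (first fill, or fill on/after exhaustion)
            start = Fraction(d)
            tablets = Fraction(fill.tablets)
        elif d == last_day:
            # same-day fill: consumed successively at its own dose
            if last_fill is not None and (
                fill.atc_code != last_fill.atc_code
                or fill.strength_mg != last_fill.strength_mg
            ):
                anomalies.append(
                    f"same-day fills of differing product on {fill.fill_date.isoformat()}: "
                    f"{last_fill.atc_code}/{last_fill.strength_mg} then "
                    f"{fill.atc_code}/{fill.strength_mg}"
                )
            start = end
            tablets = Fraction(fill.tablets)
        else:
            # early refill: carry remaining tablets into this fill
            carry = Fraction(0)
            cut = Fraction(d)
            while intervals and intervals[-1].end > cut:
                iv = intervals.pop()
                if iv.start >= cut:
                    carry += iv.length * iv.daily_dose
                else:
                    carry += (iv.end - cut) * iv.daily_dose
                    consumed = iv.tablets - (iv.end - cut) * iv.daily_dose
                    intervals.append(replace(iv, end=cut, tablets=consumed))
                    break
            start = cut
            tablets = Fraction(fill.tablets) + carry
        seg_end = start + tablets / dose
        intervals.append(SupplyInterval(start, seg_end, dose, tablets))
        end, cur_dose, last_day, last_fill = seg_end, dose, d, fill

    return SupplySchedule(
        patient_id=fills[0].patient_id,
        drug_class=drug_class,
        intervals=intervals,
        total_tablets=sum(f.tablets for f in fills),
        anomalies=anomalies,
    )


def determine_outcome(
    schedule: SupplySchedule,
    all_fills: Iterable[DispensingRecord] = (),
    grace_days: int = 30,
    followup_days: int = 730,
    event_at: str = "supply_end",
) -> EpisodeOutcome:
    """Classify the episode (pre-censoring) from the supply schedule.

    ``all_fills`` is the patient's full dispensing history; fills of the
    index class are already in the schedule, fills of other
    antihypertensive classes drive switch/add-on classification.
    """
    if grace_days < 0:
        raise ConfigError("grace_days must be >= 0")
    if followup_days <= 0:
        raise ConfigError("followup_days must be > 0")
    if event_at not in ("supply_end", "supply_end_plus_grace"):
        raise ConfigError(f"unknown event_at: {event_at!r}")

    idx = schedule.index_day
    # chain segments: a segment whose fill day is more than grace_days past
    # the (rounded-up) running supply end cannot rescue the episode
    final_end = schedule.intervals[0].end
    for iv in schedule.intervals[1:]:
        if iv.start > _ceil(final_end) + grace_days:
            break
        final_end = iv.end
    supply_end = _ceil(final_end) - idx  # first uncovered day, index-relative

    persistent = supply_end + grace_days >= followup_days

    addons: list[date] = []
    switch_candidates: list[tuple[int, DispensingRecord, DrugClass]] = []
    for fill in all_fills:
        cls = classify_atc(fill.atc_code)
        if cls in (DrugClass.OTHER, schedule.drug_class):
            continue
        rel = fill.day - idx
        if 0 <= rel < supply_end:
            addons.append(fill.fill_date)
        elif not persistent and supply_end <= rel <= supply_end + grace_days:
            switch_candidates.append((rel, fill, cls))
    addons.sort()

    if persistent:
        return EpisodeOutcome(
            patient_id=schedule.patient_id,
            status=Status.PERSISTENT,
            event_time_days=followup_days,
            index_date=date.fromordinal(idx),
            addon_dates=tuple(addons),
        )

    event_time = supply_end if event_at == "supply_end" else supply_end + grace_days
    if switch_candidates:
        rel, fill, cls = min(switch_candidates, key=lambda c: (c[0], c[2].value))
        return EpisodeOutcome(
            patient_id=schedule.patient_id,
            status=Status.SWITCHED,
            event_time_days=event_time,
            index_date=date.fromordinal(idx),
            switch_date=fill.fill_date,
            switch_to_class=cls,
            addon_dates=tuple(addons),
        )
    return EpisodeOutcome(
        patient_id=schedule.patient_id,
        status=Status.DISCONTINUED,
        event_time_days=event_time,
        index_date=date.fromordinal(idx),
        addon_dates=tuple(addons),
    )


_CENSOR_PRECEDENCE = {
    CensorReason.DEATH: 0,
    CensorReason.HOSPITALIZATION_GT21D: 1,
    CensorReason.UNIT_BAGS: 2,
    CensorReason.END_OF_FOLLOWUP: 3,
}


def apply_censoring(
    outcome: EpisodeOutcome,
    death_date: Optional[date] = None,
    hospitalizations: Iterable[tuple[date, date]] = (),
    unit_bag_start: Optional[date] = None,
    followup_end: Optional[date] = None,
    followup_days: int = 730,
    hospitalization_threshold_days: int = 21,
) -> EpisodeOutcome:
    """Censor the episode at the earliest qualifying candidate, if any.

    Candidates: death; admission of the first hospitalization longer
    than ``hospitalization_threshold_days``; first unit-bag dispensing;
    end of follow-up (the earlier of the patient's follow-up end and the
    study horizon).  A candidate strictly before the event censors the
    episode; a persistent episode is always censored (end of follow-up
    at the latest).
    """
    idx = outcome.index_date.toordinal()
    candidates: list[tuple[int, int, CensorReason]] = []

    def add(day: int, reason: CensorReason) -> None:
        candidates.append((max(day, 0), _CENSOR_PRECEDENCE[reason], reason))

    if death_date is not None:
        add(death_date.toordinal() - idx, CensorReason.DEATH)
    long_stays = []
    for admit, discharge in hospitalizations:
        if discharge < admit:
            raise MalformedIntervalError(
                f"hospitalization discharge {discharge} before admission {admit}"
            )
        if (discharge - admit).days > hospitalization_threshold_days:
            long_stays.append(admit)
    if long_stays:
        add(min(long_stays).toordinal() - idx, CensorReason.HOSPITALIZATION_GT21D)
    if unit_bag_start is not None:
        add(unit_bag_start.toordinal() - idx, CensorReason.UNIT_BAGS)
    eof = followup_days
    if followup_end is not None:
        eof = min(eof, followup_end.toordinal() - idx)
    add(eof, CensorReason.END_OF_FOLLOWUP)

    t, _, reason = min(candidates)
    persistent = outcome.status is Status.PERSISTENT
    if t < outcome.event_time_days or (persistent and t <= outcome.event_time_days):
        return EpisodeOutcome(
            patient_id=outcome.patient_id,
            status=Status.CENSORED,
            event_time_days=t,
            index_date=outcome.index_date,
            censor_reason=reason,
            addon_dates=outcome.addon_dates,
        )
    return outcome


def record_from_row(row) -> DispensingRecord:
    """Build a DispensingRecord from a dispensings-table row."""
    return DispensingRecord(
        patient_id=str(row["patient_id"]),
        fill_date=row["fill_date"],
        atc_code=str(row["atc_code"]),
        tablets=int(row["tablets"]),
        strength_mg=float(row.get("strength_mg", 0.0) or 0.0),
        dosage_text="" if row.get("dosage_text") is None else str(row.get("dosage_text", "")),
        unit_bag=bool(int(row.get("unit_bag", 0) or 0)),
    )
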