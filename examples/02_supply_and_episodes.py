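"""Build a supply schedule with carry-over and classify the episode.

A patient fills 100 tablets of a thiazide on day 0 and refills early on
day 90 (10 tablets remain and are carried over), then fills an ACE
inhibitor 12 days after the supply runs out — inside the 30-day grace
window, so the episode ends as a switch, dated at the end of supply.
"""

from datetime import date, timedelta

from rxpersist import (
    DispensingRecord,
    apply_censoring,
    build_supply_schedule,
    determine_outcome,
    parse_dosage,
)

base = date(2006, 3, 1)


def fill(day, atc, tablets, text="1 tablet daily"):
    return DispensingRecord("patient-1", base + timedelta(days=day), atc, tablets,
                            strength_mg=25.0, dosage_text=text)


index_fills = [fill(0, "C03AA03", 100), fill(90, "C03AA03", 100)]
other_fills = [fill(212, "C09AA02", 100)]  # different class, after supply end

parses = [parse_dosage(f.dosage_text) for f in index_fills]
schedule = build_supply_schedule(index_fills, parses)
print(f"supply runs {schedule.intervals[0].start - base.toordinal()} ->"
      f" {schedule.supply_end - base.toordinal()} days after the first fill")
print(f"tablets dispensed {schedule.total_tablets},"
      f" accounted for exactly: {schedule.tablets_accounted()}")

outcome = determine_outcome(schedule, index_fills + other_fills)
print(f"status: {outcome.status.value} at day {outcome.event_time_days}"
      f" (switched to {outcome.switch_to_class})")

censored = apply_censoring(outcome, death_date=base + timedelta(days=150))
print(f"with a death at day 150 the episode is instead: {censored.status.value}"
      f" ({censored.censor_reason.value}) at day {censored.event_time_days}")
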