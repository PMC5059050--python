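"""Parse free-text dosage instructions into daily tablet rates.

The daily rate is what turns a fill's tablet count into a supply
duration (tablets / rate = days covered).
"""

from rxpersist import parse_dosage

texts = [
    "1 tablet daily",
    "2 tablets twice daily",
    "1 tablet in the morning and 1/2 tablet in the evening",
    "1 tablet every other day",
    "",  # missing instruction
    "take as needed",  # outside the grammar
]

for text in texts:
    p = parse_dosage(text)
    print(f"{text!r:58} -> {str(p.daily_dose):>4} tablets/day  [{p.source.value}]")

print()
print("Missing or unparseable texts fall back to 1 tablet/day and are")
print("flagged, so a 100-tablet fill without instructions covers 100 days.")
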