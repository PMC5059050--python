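"""Free-text dosage instructions -> daily tablet consumption rate.

Dispensing registries carry the prescriber's dosage instruction as free
text ("1 tablet twice daily").  The supply duration of a fill is
``tablets / daily_dose``, so the text must be reduced to a daily rate.

The parser implements an explicit mini-grammar::

    instruction := clause (" and " clause)*
    clause      := <quantity> "tablet"|"tablets" [<frequency>]
    quantity    := decimal ("0.5", "1.5") or ASCII fraction ("1/2")
    frequency   := one of the rule table below (default: daily)

Frequencies multiply the clause quantity; clauses joined by "and" are
summed.  The default rule table:

    ============================  ==========
    frequency phrase              multiplier
    ============================  ==========
    daily                         1
    every other day               1/2
    twice daily                   2
    three times daily             3
    in the morning                1
    in the evening                1
    at night                      1
    ============================  ==========

Parsing is a *total* function: an empty/blank text defaults to 1
tablet/day (source ``defaulted_missing``), and any non-empty text the
grammar does not cover defaults to 1 tablet/day with source
``defaulted_unparseable`` and a logged warning.  Dose ranges
("1-2 tablets daily") and pro-re-nata phrasing ("as needed") carry no
single fixed rate and are deliberately left unparseable.

Deployments can extend the frequency table with a plain-text rule file
(one ``phrase<TAB>multiplier`` per line, multiplier a decimal or
fraction) passed to :func:`load_grammar`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from pathlib import Path

logger = logging.getLogger("rxpersist.dosage")

_QTY_RE = re.compile(r"^(?:(?P<num>\d+)/(?P<den>\d+)|(?P<dec>\d+(?:\.\d+)?))$")


class DosageSource(str, Enum):
    PARSED = "parsed"
    DEFAULTED_MISSING = "defaulted_missing"
    DEFAULTED_UNPARSEABLE = "defaulted_unparseable"


@dataclass(frozen=True)
class DosageParse:
    """Daily tablet rate extracted from one dosage text."""

    daily_dose: Fraction
    source: DosageSource
    raw_text: str

    def __post_init__(self) -> None:
        if self.daily_dose <= 0:
            raise ValueError("daily_dose must be positive")


DEFAULT_FREQUENCIES: dict[str, Fraction] = {
    "": Fraction(1),
    "daily": Fraction(1),
    "every other day": Fraction(1, 2),
    "twice daily": Fraction(2),
    "three times daily": Fraction(3),
    "in the morning": Fraction(1),
    "in the evening": Fraction(1),
    "at night": Fraction(1),
}


@dataclass(frozen=True)
class Grammar:
    """Frequency-phrase rule table used by :func:`parse_dosage`."""

    frequencies: tuple[tuple[str, Fraction], ...]

    def lookup(self, phrase: str) -> Fraction | None:
        for pat, mult in self.frequencies:
            if phrase == pat:
                return mult
        return None


DEFAULT_GRAMMAR = Grammar(frequencies=tuple(DEFAULT_FREQUENCIES.items()))


def load_grammar(path: str | Path) -> Grammar:
    """Extend the default grammar with rules from a plain-text file.

    Each non-comment line is ``phrase<TAB>multiplier`` where multiplier
    is a decimal or ``p/q`` fraction, e.g. ``with breakfast\t1``.
    """
    rules = dict(DEFAULT_FREQUENCIES)
    for line in Path(path).read_text("utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        phrase, mult = line.split("\t")
        rules[" ".join(phrase.lower().split())] = Fraction(mult.strip())
    return Grammar(frequencies=tuple(rules.items()))


def _parse_quantity(token: str) -> Fraction | None:
    m = _QTY_RE.match(token)
    if m is None:
        return None
    if m.group("num") is not None:
        den = int(m.group("den"))
        if den == 0:
            return None
        return Fraction(int(m.group("num")), den)
    return Fraction(m.group("dec"))


def _parse_clause(clause: str, grammar: Grammar) -> Fraction | None:
    words = clause.split()
    if len(words) < 2 or words[1] not in ("tablet", "tablets"):
        return None
    qty = _parse_quantity(words[0])
    if qty is None:
        return None
    mult = grammar.lookup(" ".join(words[2:]))
    if mult is None:
        return None
    return qty * mult


def parse_dosage(text: str, grammar: Grammar = DEFAULT_GRAMMAR) -> DosageParse:
    """Parse one dosage instruction into a :class:`DosageParse`.

    Never raises: missing text and grammar misses both degrade to the
    1-tablet/day default, distinguished by ``source``.
    """
    raw = text if isinstance(text, str) else ""
    if not raw.strip():
        return DosageParse(Fraction(1), DosageSource.DEFAULTED_MISSING, raw)
    normalized = " ".join(raw.lower().split())
    total = Fraction(0)
    for clause in normalized.split(" and "):
        part = _parse_clause(clause, grammar)
        if part is None:
            logger.warning("unparseable dosage text %r; defaulting to 1 tablet/day", raw)
            return DosageParse(Fraction(1), DosageSource.DEFAULTED_UNPARSEABLE, raw)
        total += part
    if total <= 0:
        logger.warning("dosage text %r implies a zero rate; defaulting to 1 tablet/day", raw)
        return DosageParse(Fraction(1), DosageSource.DEFAULTED_UNPARSEABLE, raw)
    return DosageParse(total, DosageSource.PARSED, raw)
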