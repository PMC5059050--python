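"""ATC-based antihypertensive drug classification.

The WHO Anatomical Therapeutic Chemical (ATC) system codes drugs
hierarchically (anatomical letter, two digits, then successively finer
levels).  Antihypertensive classes are identified by code prefixes:

* ACE inhibitors          C09A
* Angiotensin receptor blockers (ARBs)  C09C
* Beta blockers           C07
* Calcium channel blockers (CCBs)       C08
* Diuretics               C03A, C03B, C03D, C03E (thiazides, low-ceiling
  combinations, mineralocorticoid receptor antagonists, and
  potassium-sparing combinations such as amiloride products)
* Fixed-dose combinations C07FB02, C09BA, C09D

Classification is by longest-prefix match, so a fixed-combination code
such as C07FB02 beats the shorter beta-blocker prefix C07.  Every other
code maps to :attr:`DrugClass.OTHER`.  The prefix table ships as an
editable plain-text resource (``resources/atc_classes.tsv``).
"""

from __future__ import annotations

import functools
from enum import Enum
from importlib import resources


class DrugClass(str, Enum):
    """Antihypertensive drug class of a dispensed product."""

    ACE_INHIBITOR = "ACE_INHIBITOR"
    ARB = "ARB"
    BETA_BLOCKER = "BETA_BLOCKER"
    CCB = "CCB"
    DIURETIC = "DIURETIC"
    FIXED_COMBINATION = "FIXED_COMBINATION"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classes that count as antihypertensive therapy (everything but OTHER).
ANTIHYPERTENSIVE_CLASSES = tuple(c for c in DrugClass if c is not DrugClass.OTHER)


def _read_table(name: str) -> list[tuple[str, str]]:
    text = resources.files("rxpersist.resources").joinpath(name).read_text("utf-8")
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value = line.split("\t")
        rows.append((key.strip(), value.strip()))
    return rows


@functools.lru_cache(maxsize=1)
def atc_class_table() -> dict[str, DrugClass]:
    """Prefix -> class mapping loaded from the packaged resource."""
    return {prefix: DrugClass(value) for prefix, value in _read_table("atc_classes.tsv")}


@functools.lru_cache(maxsize=None)
def classify_atc(atc_code: str) -> DrugClass:
    """Map an ATC code to its antihypertensive drug class.

    Longest-prefix match against the packaged table; codes matching no
    prefix are :attr:`DrugClass.OTHER`.  Raises ``ValueError`` on an
    empty code.
    """
    if not isinstance(atc_code, str) or not atc_code.strip():
        raise ValueError("ATC code must be a non-empty string")
    code = atc_code.strip().upper()
    table = atc_class_table()
    best: DrugClass | None = None
    best_len = -1
    for prefix, cls in table.items():
        if code.startswith(prefix) and len(prefix) > best_len:
            best, best_len = cls, len(prefix)
    return best if best is not None else DrugClass.OTHER


# ---------------------------------------------------------------------------
# ICD-10 comorbidity mapping
# ---------------------------------------------------------------------------

COMORBIDITY_FLAGS = (
    "atrial_fibrillation",
    "heart_failure",
    "ischemic_heart_disease",
    "stroke_tia",
    "diabetes",
)


def _expand_range(spec: str) -> list[str]:
    # "I20-I25" -> I20..I25 ; single prefixes pass through
    if "-" not in spec:
        return [spec]
    lo, hi = spec.split("-")
    letter = lo[0]
    start, stop = int(lo[1:]), int(hi[1:])
    return [f"{letter}{i:02d}" for i in range(start, stop + 1)]


@functools.lru_cache(maxsize=1)
def icd10_flag_table() -> dict[str, str]:
    table: dict[str, str] = {}
    for spec, flag in _read_table("icd10_flags.tsv"):
        for prefix in _expand_range(spec):
            table[prefix] = flag
    return table


def map_comorbidity(icd10_codes) -> dict[str, bool]:
    """Set cardiovascular comorbidity flags from a list of ICD-10 codes.

    Unknown codes are ignored.  The derived ``no_cv_comorbidity``
    indicator is the negation of the union of the five flags.
    """
    flags = {flag: False for flag in COMORBIDITY_FLAGS}
    table = icd10_flag_table()
    for code in icd10_codes:
        code = str(code).strip().upper()
        for prefix, flag in table.items():
            if code.startswith(prefix):
                flags[flag] = True
    flags["no_cv_comorbidity"] = not any(flags[f] for f in COMORBIDITY_FLAGS)
    return flags
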