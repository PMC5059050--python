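"""Independent reference implementations used only to check the package.

These deliberately share no code with rxpersist: the dosage reference
is a word-list parser (regex-free), the supply/outcome reference is a
day-by-day tablet-consumption simulation, and the Cox reference is a
brute-force enumeration of the partial likelihood.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.optimize import minimize_scalar

# ---------------------------------------------------------------------------
# dosage grammar reference
# ---------------------------------------------------------------------------

_FREQ_WORDS = {
    (): Fraction(1),
    ("daily",): Fraction(1),
    ("every", "other", "day"): Fraction(1, 2),
    ("twice", "daily"): Fraction(2),
    ("three", "times", "daily"): Fraction(3),
    ("in", "the", "morning"): Fraction(1),
    ("in", "the", "evening"): Fraction(1),
    ("at", "night"): Fraction(1),
}


def ref_daily_dose(text: str):
    """Word-based reference parse; None when the grammar does not apply."""
    words_all = text.lower().split()
    clauses, cur = [], []
    for w in words_all:
        if w == "and":
            clauses.append(cur)
            cur = []
        else:
            cur.append(w)
    clauses.append(cur)
    total = Fraction(0)
    for words in clauses:
        if len(words) < 2 or words[1] not in ("tablet", "tablets"):
            return None
        q = words[0]
        try:
            if "/" in q:
                num, den = q.split("/")
                qty = Fraction(int(num), int(den))
            else:
                qty = Fraction(q)
        except (ValueError, ZeroDivisionError):
            return None
        mult = _FREQ_WORDS.get(tuple(words[2:]))
        if mult is None:
            return None
        total += qty * mult
    return total if total > 0 else None


# ---------------------------------------------------------------------------
# day-granularity consumption simulator
# ---------------------------------------------------------------------------


def day_sim_outcome(index_fills, other_days=(), grace=30, followup=730):
    """Brute-force episode classification by daily tablet decrement.

    ``index_fills``: [(day, tablets, daily_dose)], integer days; fills
    sharing a day must share a dose.  ``other_days``: days of
    different-class antihypertensive fills.  Returns
    (status, event_day_rel, supply_end_rel) with days relative to the
    first fill.
    """
    fills = sorted(index_fills)
    by_day: dict[int, list] = {}
    for day, n, r in fills:
        by_day.setdefault(day, []).append((n, Fraction(r)))
    start = fills[0][0]
    total = sum(n for _, n, _ in fills)
    horizon = max(d for d, _, _ in fills) + 2 * total + grace + followup + 10

    covered = set()
    stock = Fraction(0)
    dose = None
    for day in range(start, horizon + 1):
        if day in by_day:
            for n, r in by_day[day]:
                stock += n
                dose = r
        if stock > 0:
            covered.add(day)
            stock = max(Fraction(0), stock - dose)

    d = start
    while True:
        if d in covered:
            d += 1
            continue
        nxt = min((fd for fd in by_day if fd > d), default=None)
        if nxt is not None and nxt <= d + grace:
            d = nxt
            continue
        gap_start = d
        break
    rel = gap_start - start
    if rel + grace >= followup:
        return ("persistent", followup, rel)
    for od in sorted(other_days):
        if gap_start <= od <= gap_start + grace:
            return ("switched", rel, rel)
    return ("discontinued", rel, rel)


# ---------------------------------------------------------------------------
# Cox partial likelihood by enumeration (1 covariate, no ties)
# ---------------------------------------------------------------------------


def brute_cox_loglik_1d(beta, times, events, x):
    n = len(times)
    ll = 0.0
    for i in range(n):
        if events[i]:
            risk = [j for j in range(n) if times[j] >= times[i]]
            ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def brute_cox_mle_1d(times, events, x):
    res = minimize_scalar(
        lambda b: -brute_cox_loglik_1d(b, times, events, x),
        bounds=(-6, 6), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def ecdf_survivor(durations, t):
    """1 - empirical CDF (proportion of durations strictly greater than t)."""
    durations = np.asarray(durations, dtype=float)
    return float(np.mean(durations > t))
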