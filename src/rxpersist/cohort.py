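"""Cohort eligibility, covariate coding and the pre-switch BP audit.

Eligibility for the persistence analysis requires, at the index date
(first antihypertensive fill): age >= 30 years, a recorded hypertension
diagnosis (ICD-10 I10) strictly before the index fill, an index fill
inside the enrollment window, at least one filled antihypertensive
prescription, and exactly one antihypertensive product class on the
index date (a single fixed-combination product qualifies; two distinct
classes on the same day do not).  Exactly one exclusion reason is
logged per excluded patient, applied in the precedence order
age -> diagnosis (missing / not before index) -> no fill ->
index outside window -> multi-product initiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional

import numpy as np
import pandas as pd

from .atc import DrugClass, classify_atc, map_comorbidity
from .errors import ConfigError

logger = logging.getLogger("rxpersist.cohort")

EXCLUSION_REASONS = (
    "age_under_30",
    "no_hypertension_dx",
    "dx_after_index",
    "no_antihypertensive_fill",
    "index_outside_window",
    "multi_product_initiation",
)


def _classify_series(atc: pd.Series) -> pd.Series:
    mapping = {code: classify_atc(code).value for code in atc.unique()}
    return atc.map(mapping)


@dataclass
class EligibilityResult:
    eligible: pd.DataFrame  # patients + index_date, index_class
    exclusions: pd.DataFrame  # patient_id, reason


def apply_eligibility(
    patients: pd.DataFrame,
    dispensings: pd.DataFrame,
    diagnoses: pd.DataFrame,
    enrollment_start: Optional[date] = None,
    enrollment_end: Optional[date] = None,
) -> EligibilityResult:
    """Partition patients into the eligible cohort and an exclusion log.

    Every input patient lands in exactly one of the two outputs:
    ``len(patients) == len(eligible) + len(exclusions)``.
    """
    if diagnoses is None:
        raise ConfigError("diagnoses table is required for eligibility")

    disp = dispensings.copy()
    disp["drug_class"] = _classify_series(disp["atc_code"].astype(str))
    aht = disp[disp["drug_class"] != DrugClass.OTHER.value]

    index_date = aht.groupby("patient_id")["fill_date"].min()
    hyp = diagnoses[diagnoses["icd10_code"].astype(str).str.upper().str.startswith("I10")]
    first_dx = hyp.groupby("patient_id")["dx_date"].min()

    # distinct antihypertensive classes filled on the index date
    with_idx = aht.merge(index_date.rename("index_date"), on="patient_id")
    on_index = with_idx[with_idx["fill_date"] == with_idx["index_date"]]
    n_classes = on_index.groupby("patient_id")["drug_class"].nunique()
    index_class = on_index.groupby("patient_id")["drug_class"].first()

    rows = []
    for rec in patients.to_dict("records"):
        pid = rec["patient_id"]
        idx = index_date.get(pid)
        dx = first_dx.get(pid)
        reason = None
        if float(rec["age_at_index"]) < 30:
            reason = "age_under_30"
        elif dx is None or pd.isna(dx):
            reason = "no_hypertension_dx"
        elif idx is not None and not pd.isna(idx) and not dx < idx:
            reason = "dx_after_index"
        elif idx is None or pd.isna(idx):
            reason = "no_antihypertensive_fill"
        elif (enrollment_start is not None and idx < enrollment_start) or (
            enrollment_end is not None and idx > enrollment_end
        ):
            reason = "index_outside_window"
        elif int(n_classes.get(pid, 0)) > 1:
            reason = "multi_product_initiation"
        rows.append((pid, reason, idx, index_class.get(pid)))

    out = pd.DataFrame(rows, columns=["patient_id", "reason", "index_date", "index_class"])
    excl = out[out["reason"].notna()][["patient_id", "reason"]].reset_index(drop=True)
    keep = out[out["reason"].isna()]
    eligible = patients.merge(
        keep[["patient_id", "index_date", "index_class"]], on="patient_id", how="inner"
    )
    assert len(eligible) + len(excl) == len(patients)
    return EligibilityResult(eligible=eligible, exclusions=excl)


def build_cohort_table(
    eligible: pd.DataFrame,
    diagnoses: pd.DataFrame,
    dispensings: pd.DataFrame,
    bp_measurements: pd.DataFrame,
    n_other_drugs_window_days: int = 365,
) -> pd.DataFrame:
    """Code the covariates the adjusted hazard model expects.

    Adds comorbidity flags (diagnoses up to and including the index
    date), the derived no-CV-comorbidity indicator, the count of
    distinct non-antihypertensive substances (7-character ATC level)
    filled in the window before index, and the last blood pressure
    recorded strictly before the index fill (NaN when never recorded).
    """
    disp = dispensings.copy()
    disp["drug_class"] = _classify_series(disp["atc_code"].astype(str))

    dx_by_pid = {pid: g for pid, g in diagnoses.groupby("patient_id")}
    other = disp[disp["drug_class"] == DrugClass.OTHER.value]
    other_by_pid = {pid: g for pid, g in other.groupby("patient_id")}
    bp_by_pid = {pid: g for pid, g in bp_measurements.groupby("patient_id")}

    rows = []
    for rec in eligible.to_dict("records"):
        pid, idx = rec["patient_id"], rec["index_date"]
        g = dx_by_pid.get(pid)
        codes = [] if g is None else list(g[g["dx_date"] <= idx]["icd10_code"])
        flags = map_comorbidity(codes)

        og = other_by_pid.get(pid)
        if og is None:
            n_other = 0
        else:
            lo = idx - timedelta(days=n_other_drugs_window_days)
            win = og[(og["fill_date"] >= lo) & (og["fill_date"] < idx)]
            n_other = int(win["atc_code"].astype(str).str[:7].nunique())

        bg = bp_by_pid.get(pid)
        sbp = dbp = np.nan
        if bg is not None:
            before = bg[bg["measure_date"] < idx]
            if len(before):
                last = before.sort_values("measure_date").iloc[-1]
                sbp, dbp = float(last["sbp"]), float(last["dbp"])

        rows.append({**rec, **flags, "n_other_drugs": n_other,
                     "index_sbp": sbp, "index_dbp": dbp})
    return pd.DataFrame(rows)


def bp_before_switch(
    switch_date: date,
    bp_history: pd.DataFrame,
    window_days: int = 182,
) -> dict:
    """Audit the last BP in the half-open window before a switch.

    Window: ``switch_date - window_days <= measure_date < switch_date``
    (26 weeks by default; the switch day itself is excluded).
    ``uncontrolled`` follows the standard 140/90 mm Hg convention:
    systolic >= 140 *or* diastolic >= 90.
    """
    if window_days <= 0:
        raise ConfigError("window_days must be > 0")
    lo = switch_date - timedelta(days=window_days)
    win = bp_history[
        (bp_history["measure_date"] >= lo) & (bp_history["measure_date"] < switch_date)
    ]
    if not len(win):
        return {"recorded": False, "last_bp": None, "uncontrolled": None}
    last = win.sort_values("measure_date").iloc[-1]
    sbp, dbp = float(last["sbp"]), float(last["dbp"])
    return {
        "recorded": True,
        "last_bp": (last["measure_date"], sbp, dbp),
        "uncontrolled": bool(sbp >= 140 or dbp >= 90),
    }


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

AGE_CUTS_DEFAULT = (30, 50, 65, 80)

DESIGN_COLUMNS = (
    "male",
    "age_30_49",
    "age_65_79",
    "age_80_plus",
    "sbp",
    "dbp",
    "diabetes",
    "no_cv_comorbidity",
    "n_other_drugs",
    "income_below_median",
    "education_lower_secondary",
    "education_upper_secondary",
    "country_other_nordic",
    "country_europe_non_nordic",
    "country_other",
    "class_ace_inhibitor",
    "class_arb",
    "class_beta_blocker",
    "class_ccb",
    "class_fixed_combination",
)

#: crude hazard ratios are estimated one block at a time
COVARIATE_BLOCKS = {
    "sex": ["male"],
    "age_group": ["age_30_49", "age_65_79", "age_80_plus"],
    "sbp": ["sbp"],
    "dbp": ["dbp"],
    "diabetes": ["diabetes"],
    "no_cv_comorbidity": ["no_cv_comorbidity"],
    "n_other_drugs": ["n_other_drugs"],
    "income": ["income_below_median"],
    "education": ["education_lower_secondary", "education_upper_secondary"],
    "country_of_birth": ["country_other_nordic", "country_europe_non_nordic", "country_other"],
    "drug_class": [
        "class_ace_inhibitor",
        "class_arb",
        "class_beta_blocker",
        "class_ccb",
        "class_fixed_combination",
    ],
}

_CLASS_DUMMY = {
    DrugClass.ACE_INHIBITOR.value: "class_ace_inhibitor",
    DrugClass.ARB.value: "class_arb",
    DrugClass.BETA_BLOCKER.value: "class_beta_blocker",
    DrugClass.CCB.value: "class_ccb",
    DrugClass.FIXED_COMBINATION.value: "class_fixed_combination",
    # DIURETIC is the reference class and carries no dummy
}


def age_group(age: float, cuts=AGE_CUTS_DEFAULT) -> str:
    c1, c2, c3 = cuts[1], cuts[2], cuts[3]
    if age < c1:
        return f"{cuts[0]}_{c1 - 1}"
    if age < c2:
        return f"{c1}_{c2 - 1}"
    if age < c3:
        return f"{c2}_{c3 - 1}"
    return f"{c3}_plus"


def build_design(cohort: pd.DataFrame, age_cuts=AGE_CUTS_DEFAULT) -> pd.DataFrame:
    """Encode cohort covariates into the model design matrix.

    Reference categories (female; age 50-64; income at/above median;
    primary education; born in Sweden; diuretic initiation) carry no
    dummy column.  Continuous columns: sbp, dbp, n_other_drugs.
    """
    X = pd.DataFrame(index=cohort.index)
    age = cohort["age_at_index"].astype(float)
    X["male"] = (cohort["sex"] == "male").astype(float)
    X["age_30_49"] = (age < age_cuts[1]).astype(float)
    X["age_65_79"] = ((age >= age_cuts[2]) & (age < age_cuts[3])).astype(float)
    X["age_80_plus"] = (age >= age_cuts[3]).astype(float)
    X["sbp"] = cohort["index_sbp"].astype(float)
    X["dbp"] = cohort["index_dbp"].astype(float)
    X["diabetes"] = cohort["diabetes"].astype(float)
    X["no_cv_comorbidity"] = cohort["no_cv_comorbidity"].astype(float)
    X["n_other_drugs"] = cohort["n_other_drugs"].astype(float)
    X["income_below_median"] = (cohort["income_group"] == "below_median").astype(float)
    X["education_lower_secondary"] = (cohort["education"] == "lower_secondary").astype(float)
    X["education_upper_secondary"] = (cohort["education"] == "upper_secondary").astype(float)
    X["country_other_nordic"] = (cohort["country_of_birth"] == "other_nordic").astype(float)
    X["country_europe_non_nordic"] = (
        cohort["country_of_birth"] == "europe_non_nordic"
    ).astype(float)
    X["country_other"] = (cohort["country_of_birth"] == "other").astype(float)
    for cls, col in _CLASS_DUMMY.items():
        X[col] = (cohort["index_class"] == cls).astype(float)
    return X[list(DESIGN_COLUMNS)]
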