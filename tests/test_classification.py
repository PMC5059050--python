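"""ATC class mapping, comorbidity flags, eligibility, BP audit."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

import rxpersist as rx
from rxpersist.atc import atc_class_table
from rxpersist.cohort import apply_eligibility, bp_before_switch
from rxpersist.errors import ConfigError


@pytest.mark.parametrize(
    "code, expected",
    [
        ("C09AA02", rx.DrugClass.ACE_INHIBITOR),
        ("C09CA01", rx.DrugClass.ARB),
        ("C07AB02", rx.DrugClass.BETA_BLOCKER),
        ("C08CA01", rx.DrugClass.CCB),
        ("C03AA03", rx.DrugClass.DIURETIC),
        ("C03BA11", rx.DrugClass.DIURETIC),
        ("C03DA01", rx.DrugClass.DIURETIC),  # spironolactone counts as diuretic
        ("C03EA01", rx.DrugClass.DIURETIC),
        ("C09BA02", rx.DrugClass.FIXED_COMBINATION),
        ("C09DA01", rx.DrugClass.FIXED_COMBINATION),
        ("C07FB02", rx.DrugClass.FIXED_COMBINATION),  # beats the C07 prefix
        ("N02BE01", rx.DrugClass.OTHER),
        ("C03CA01", rx.DrugClass.OTHER),  # loop diuretics are not in the map
        ("C10AA01", rx.DrugClass.OTHER),
    ],
)
def test_classify_atc(code, expected):
    assert rx.classify_atc(code) is expected


def test_classify_atc_rejects_empty():
    with pytest.raises(ValueError):
        rx.classify_atc("")


def test_classify_partition_over_table_prefixes():
    """Every table prefix plus random suffixes maps to exactly its class;
    longest-prefix precedence is deterministic."""
    rng = np.random.default_rng(1)
    table = atc_class_table()
    for prefix, cls in table.items():
        for _ in range(20):
            suffix = "".join(
                rng.choice(list("ABCDEF0123456789"), size=rng.integers(0, 4))
            )
            code = prefix + suffix
            got = rx.classify_atc(code)
            # the expected class is that of the longest matching prefix
            best = max(
                (p for p in table if code.startswith(p)), key=len
            )
            assert got is table[best]


@pytest.mark.parametrize(
    "codes, expected_true",
    [
        (["I48"], {"atrial_fibrillation"}),
        (["I489"], {"atrial_fibrillation"}),
        (["I50"], {"heart_failure"}),
        (["I21", "E11"], {"ischemic_heart_disease", "diabetes"}),
        (["I20", "I25"], {"ischemic_heart_disease"}),
        (["I60", "I69", "G45"], {"stroke_tia"}),
        (["E10"], {"diabetes"}),
        (["I10", "Z99"], set()),  # unknown codes ignored
        ([], set()),
    ],
)
def test_map_comorbidity(codes, expected_true):
    flags = rx.map_comorbidity(codes)
    on = {k for k, v in flags.items() if v and k != "no_cv_comorbidity"}
    assert on == expected_true
    assert flags["no_cv_comorbidity"] == (not expected_true)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------


def _patients(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "sex", "age_at_index", "education", "income_group",
                 "country_of_birth", "death_date", "followup_end"],
    )


def _disp(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "fill_date", "atc_code", "tablets",
                 "strength_mg", "dosage_text", "unit_bag"],
    )


def _dx(rows):
    return pd.DataFrame(rows, columns=["patient_id", "icd10_code", "dx_date"])


def test_eligibility_reasons_and_reconciliation():
    d = date
    patients = _patients([
        ("ok", "female", 62, "primary", "below_median", "sweden", None, d(2008, 1, 1)),
        ("young", "male", 29, "primary", "below_median", "sweden", None, d(2008, 1, 1)),
        ("nodx", "male", 55, "primary", "below_median", "sweden", None, d(2008, 1, 1)),
        ("latedx", "male", 55, "primary", "below_median", "sweden", None, d(2008, 1, 1)),
        ("nofill", "male", 55, "primary", "below_median", "sweden", None, d(2008, 1, 1)),
        ("multi", "male", 55, "primary", "below_median", "sweden", None, d(2008, 1, 1)),
        ("fixedok", "male", 55, "primary", "below_median", "sweden", None, d(2008, 1, 1)),
    ])
    f = d(2006, 3, 1)
    disp = _disp([
        ("ok", f, "C03AA03", 100, 25.0, "1 tablet daily", 0),
        ("young", f, "C03AA03", 100, 25.0, "1 tablet daily", 0),
        ("nodx", f, "C03AA03", 100, 25.0, "1 tablet daily", 0),
        ("latedx", f, "C03AA03", 100, 25.0, "1 tablet daily", 0),
        ("multi", f, "C03AA03", 100, 25.0, "1 tablet daily", 0),
        ("multi", f, "C09AA02", 100, 10.0, "1 tablet daily", 0),
        # one fixed-combination product on the index day is eligible
        ("fixedok", f, "C09BA02", 100, 10.0, "1 tablet daily", 0),
        # same-class second product does not make a multi-product initiation
        ("ok", f, "C03AA03", 100, 25.0, "1 tablet daily", 0),
    ])
    dx_before = d(2005, 6, 1)
    dxs = _dx([
        ("ok", "I10", dx_before),
        ("young", "I10", dx_before),
        ("latedx", "I10", d(2006, 6, 1)),  # after index fill
        ("nofill", "I10", dx_before),
        ("multi", "I10", dx_before),
        ("fixedok", "I10", dx_before),
        ("nodx", "I48", dx_before),  # comorbidity only, no hypertension dx
    ])
    res = apply_eligibility(patients, disp, dxs)
    reasons = dict(zip(res.exclusions["patient_id"], res.exclusions["reason"]))
    assert reasons == {
        "young": "age_under_30",
        "nodx": "no_hypertension_dx",
        "latedx": "dx_after_index",
        "nofill": "no_antihypertensive_fill",
        "multi": "multi_product_initiation",
    }
    assert sorted(res.eligible["patient_id"]) == ["fixedok", "ok"]
    assert len(res.eligible) + len(res.exclusions) == len(patients)
    row = res.eligible.set_index("patient_id").loc["fixedok"]
    assert row["index_class"] == "FIXED_COMBINATION"


def test_eligibility_precedence_age_beats_dx():
    """A patient violating several rules is logged once, highest precedence."""
    patients = _patients([
        ("both", "male", 25, "primary", "below_median", "sweden", None, date(2008, 1, 1)),
    ])
    disp = _disp([
        ("both", date(2006, 3, 1), "C03AA03", 100, 25.0, "1 tablet daily", 0),
        ("both", date(2006, 3, 1), "C09AA02", 100, 10.0, "1 tablet daily", 0),
    ])
    dxs = _dx([("both", "I10", date(2006, 6, 1))])
    res = apply_eligibility(patients, disp, dxs)
    assert list(res.exclusions["reason"]) == ["age_under_30"]


def test_eligibility_requires_diagnoses_table():
    with pytest.raises(ConfigError):
        apply_eligibility(_patients([]), _disp([]), None)


# ---------------------------------------------------------------------------
# BP before switch
# ---------------------------------------------------------------------------


def _bp(rows):
    return pd.DataFrame(rows, columns=["patient_id", "measure_date", "sbp", "dbp"])


@pytest.mark.parametrize(
    "offset_days, recorded",
    [(183, False), (182, True), (1, True), (0, False)],  # switch day itself excluded
)
def test_bp_window_boundaries(offset_days, recorded):
    switch = date(2007, 1, 1)
    bp = _bp([("p", date.fromordinal(switch.toordinal() - offset_days), 150, 85)])
    res = bp_before_switch(switch, bp)
    assert res["recorded"] is recorded


@pytest.mark.parametrize(
    "sbp, dbp, uncontrolled",
    [(142, 85, True), (138, 92, True), (140, 90, True), (139, 89, False), (138, 88, False)],
)
def test_bp_control_threshold(sbp, dbp, uncontrolled):
    switch = date(2007, 1, 1)
    bp = _bp([("p", date(2006, 12, 1), sbp, dbp)])
    res = bp_before_switch(switch, bp)
    assert res["uncontrolled"] is uncontrolled


def test_bp_uses_latest_in_window():
    switch = date(2007, 1, 1)
    bp = _bp([
        ("p", date(2006, 9, 1), 170, 100),
        ("p", date(2006, 12, 20), 120, 70),
    ])
    res = bp_before_switch(switch, bp)
    assert res["uncontrolled"] is False
    assert res["last_bp"][1] == 120
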