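"""Synthetic primary-care dispensing cohort with known ground truth.

The generator emulates the structure of a Swedish-style primary-care
hypertension registry linked to national dispensing, hospitalization
and socioeconomic registers: patients aged 30+ with a recorded
hypertension diagnosis who initiate antihypertensive therapy, fill
roughly 3-month prescriptions, and discontinue, switch, or stay on
their initial drug class.  Every downstream rule of the analysis
pipeline is exercised by construction, and a ground-truth sidecar makes
parameter-recovery tests possible.

Event model
-----------
Each patient draws covariates from configurable marginals, an index
drug class from a (covariate-tilted) multinomial, and a latent
discontinuation time from an exponential proportional-hazards model:

.. math:: T \\sim \\mathrm{Exp}(\\lambda_0 e^{x^\\top \\beta}),

with the true log-hazard ratios ``beta`` taken from the config
(continuous covariates enter centered so the baseline rate keeps its
marginal meaning).  Refills are emitted every ~``refill_cycle_days``
until the next planned fill would land after :math:`T`; the patient
then stops collecting.  The *operational* ground-truth event day is the
(rounded-up) end of the final fill's supply — exactly what a claims
pipeline can observe — while the latent :math:`T` is also recorded for
distributional checks.  Refill jitter includes deliberate early refills
(stockpiling, which exercises tablet carry-over) and late refills
within the grace period.

Dosage texts are drawn from the parseable template dialect; a small
configurable fraction (0.6% by default, matching the missingness rate
typical of dispensing registries) is emitted blank, and those fills are
consumed at the 1-tablet/day default so the record stays internally
consistent.  Switching, add-on fills, death, hospitalizations, unit-bag
dispensing and planted eligibility violators are all superimposed at
configurable rates.

Determinism: each patient uses an independent RNG substream keyed by
``(seed, patient index)``, so outputs are byte-identical under a fixed
seed and adding patients never perturbs earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .atc import DrugClass
from .cohort import age_group
from .errors import ConfigError


#: parseable dosage-text templates, keyed by the daily dose they encode
DOSAGE_TEMPLATES: dict[Fraction, tuple[str, ...]] = {
    Fraction(1): ("1 tablet daily", "1 tablet in the morning", "1 tablet at night"),
    Fraction(2): (
        "2 tablets daily",
        "1 tablet twice daily",
        "1 tablet in the morning and 1 tablet in the evening",
    ),
    Fraction(1, 2): ("1/2 tablet daily", "0.5 tablets daily", "1 tablet every other day"),
    Fraction(3, 2): (
        "1.5 tablets daily",
        "1 tablet in the morning and 1/2 tablet in the evening",
    ),
}

_CLASS_ATC = {
    DrugClass.ACE_INHIBITOR: ("C09AA02", "C09AA05"),
    DrugClass.ARB: ("C09CA01", "C09CA06"),
    DrugClass.BETA_BLOCKER: ("C07AB02", "C07AB07"),
    DrugClass.CCB: ("C08CA01", "C08CA05"),
    DrugClass.DIURETIC: ("C03AA03", "C03DA01", "C03EA01"),
    DrugClass.FIXED_COMBINATION: ("C09BA02", "C09DA01", "C07FB02"),
}

_OTHER_ATC = (
    "N02BE01", "A02BC01", "C10AA01", "N05BA04", "M01AE01",
    "B01AC06", "A10BA02", "R03AC02", "H03AA01", "N06AB04",
)

_CLASSES = (
    DrugClass.ACE_INHIBITOR,
    DrugClass.ARB,
    DrugClass.BETA_BLOCKER,
    DrugClass.CCB,
    DrugClass.DIURETIC,
    DrugClass.FIXED_COMBINATION,
)


def default_class_probs() -> dict[str, float]:
    # initiation shares typical of mid-2000s Swedish primary care
    return {
        "ACE_INHIBITOR": 0.363,
        "ARB": 0.039,
        "BETA_BLOCKER": 0.206,
        "CCB": 0.078,
        "DIURETIC": 0.274,
        "FIXED_COMBINATION": 0.040,
    }


def default_class_tilts() -> dict[str, dict[str, float]]:
    # log-odds adjustments creating the initiation-by-covariate structure
    # (diabetics and men toward ACE inhibitors, women toward diuretics
    # and beta blockers, high income/education toward ARBs)
    return {
        "ACE_INHIBITOR": {"diabetes": 0.6, "male": 0.25},
        "DIURETIC": {"male": -0.15},
        "BETA_BLOCKER": {"male": -0.2},
        "ARB": {"income_below_median": -0.4, "education_upper_secondary": 0.3},
    }


def default_true_loghr() -> dict[str, float]:
    """True log-hazard ratios for discontinuation, by design column.

    Continuous covariates (sbp, dbp, n_other_drugs) apply to centered
    values (166 / 93 mm Hg, 2 drugs).  Positive = faster
    discontinuation.  Men, the young, those with milder systolic
    elevation and those born outside the Nordic countries discontinue
    faster; drug classes carry no true effect except a small one for
    fixed combinations.
    """
    return {
        "male": 0.25,
        "age_30_49": 0.40,
        "age_65_79": -0.10,
        "age_80_plus": 0.05,
        "sbp": -0.012,
        "dbp": 0.0,
        "diabetes": 0.20,
        "no_cv_comorbidity": 0.0,
        "n_other_drugs": 0.0,
        "income_below_median": 0.10,
        "education_lower_secondary": 0.0,
        "education_upper_secondary": 0.0,
        "country_other_nordic": 0.05,
        "country_europe_non_nordic": 0.30,
        "country_other": 0.35,
        "class_ace_inhibitor": 0.0,
        "class_arb": 0.0,
        "class_beta_blocker": 0.0,
        "class_ccb": 0.0,
        "class_fixed_combination": 0.15,
    }


@dataclass
class SimulationConfig:
    n_patients: int = 1000
    seed: int = 0
    enrollment_start: date = date(2006, 1, 1)
    enrollment_end: date = date(2007, 12, 31)
    followup_days: int = 730
    grace_days: int = 30
    class_probs: dict = field(default_factory=default_class_probs)
    class_tilts: dict = field(default_factory=default_class_tilts)
    true_loghr: dict = field(default_factory=default_true_loghr)
    #: piecewise-constant baseline hazard, ((start_day, rate/day), ...).
    #: Defaults give a latent survivor of ~57% at 1 year and ~43% at 2
    #: years at the reference covariate profile (discontinuation hazard
    #: is highest soon after initiation).  A bare float is accepted and
    #: treated as a single exponential rate.
    baseline_hazard: tuple = ((0, 0.001539), (365, 0.000772))
    refill_cycle_days: float = 90.0
    refill_jitter_sd: float = 3.0
    early_refill_prob: float = 0.25
    early_refill_max_days: int = 14
    late_refill_prob: float = 0.15
    missing_dosage_prob: float = 0.006
    switch_prob: float = 0.45  # of ended episodes, fraction followed by a switch fill
    addon_prob: float = 0.08
    death_prob: float = 0.005
    hosp_prob: float = 0.15
    hosp_length_lognorm_mu: float = 2.0
    hosp_length_lognorm_sigma: float = 0.9
    unit_bag_prob: float = 0.0054
    bp_index_prob: float = 0.96
    bp_pre_switch_prob: float = 0.21
    bp_uncontrolled_prob: float = 0.69
    violator_under30_prob: float = 0.005
    violator_dx_after_prob: float = 0.005
    violator_no_fill_prob: float = 0.012
    violator_multi_product_prob: float = 0.031
    dose_probs: dict = field(
        default_factory=lambda: {"1": 0.70, "2": 0.15, "1/2": 0.10, "3/2": 0.05}
    )
    male_prob: float = 0.47
    age_mean: float = 61.5
    age_sd: float = 12.5
    sbp_mean: float = 166.0
    sbp_sd: float = 19.0
    sbp_diabetes_shift: float = -8.0  # treated diabetics start at lower SBP
    dbp_mean: float = 93.0
    dbp_sd: float = 11.0
    diabetes_prob: float = 0.12
    af_prob: float = 0.05
    hf_prob: float = 0.03
    ihd_prob: float = 0.07
    stroke_prob: float = 0.04
    education_probs: tuple = (0.35, 0.35, 0.30)  # primary, lower sec., upper sec.
    income_below_prob: float = 0.50
    country_probs: tuple = (0.85, 0.05, 0.05, 0.05)  # sweden, nordic, europe, other
    n_other_drugs_mean: float = 2.0

    def validate(self) -> None:
        bad = []
        probs = {
            k: getattr(self, k)
            for k in (
                "missing_dosage_prob", "switch_prob", "addon_prob", "death_prob",
                "hosp_prob", "unit_bag_prob", "bp_index_prob", "bp_pre_switch_prob",
                "bp_uncontrolled_prob", "violator_under30_prob",
                "violator_dx_after_prob", "violator_no_fill_prob",
                "violator_multi_product_prob", "male_prob", "income_below_prob",
                "early_refill_prob", "late_refill_prob", "diabetes_prob",
                "af_prob", "hf_prob", "ihd_prob", "stroke_prob",
            )
        }
        for k, v in probs.items():
            if not 0.0 <= float(v) <= 1.0:
                bad.append(f"{k}={v} (must be in [0, 1])")
        try:
            pieces = self.hazard_pieces()
            if any(r <= 0 for _, r in pieces):
                bad.append("baseline_hazard (rates must be > 0)")
            if pieces[0][0] != 0 or any(
                pieces[i][0] >= pieces[i + 1][0] for i in range(len(pieces) - 1)
            ):
                bad.append("baseline_hazard (piece start days must ascend from 0)")
        except (TypeError, ValueError, IndexError):
            bad.append("baseline_hazard (scalar rate or ((day, rate), ...))")
        if self.n_patients < 1:
            bad.append("n_patients (must be >= 1)")
        if self.followup_days <= 0:
            bad.append("followup_days (must be > 0)")
        if self.grace_days < 0:
            bad.append("grace_days (must be >= 0)")
        if self.refill_cycle_days <= 0:
            bad.append("refill_cycle_days (must be > 0)")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-6:
            bad.append("class_probs (must sum to 1)")
        if abs(sum(float(v) for v in self.dose_probs.values()) - 1.0) > 1e-6:
            bad.append("dose_probs (must sum to 1)")
        if bad:
            raise ConfigError("invalid simulation config: " + "; ".join(bad))

    def hazard_pieces(self) -> tuple:
        """Baseline hazard as ((start_day, rate), ...); scalars become one piece."""
        bh = self.baseline_hazard
        if isinstance(bh, (int, float)):
            return ((0, float(bh)),)
        return tuple((float(d), float(r)) for d, r in bh)

    def survivor0(self, t: float) -> float:
        """Closed-form baseline survivor S0(t) of the latent event time."""
        return math.exp(-_cumhaz(self.hazard_pieces(), t))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("enrollment_start", "enrollment_end"):
            if key in d and isinstance(d[key], str):
                d[key] = date.fromisoformat(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SimulatedCohort:
    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    dispensings: pd.DataFrame
    hospitalizations: pd.DataFrame
    bp_measurements: pd.DataFrame
    ground_truth: pd.DataFrame
    ground_truth_fills: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir) -> dict:
        """Write the CSV tables; returns {table name: path}."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in (
            "patients", "diagnoses", "dispensings",
            "hospitalizations", "bp_measurements",
            "ground_truth", "ground_truth_fills",
        ):
            path = out / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


def _draw_categorical(rng, items, probs):
    return items[int(rng.choice(len(items), p=np.asarray(probs) / np.sum(probs)))]


def _cumhaz(pieces, t: float) -> float:
    """Cumulative baseline hazard of a piecewise-constant rate at time t."""
    total = 0.0
    for i, (start, rate) in enumerate(pieces):
        end = pieces[i + 1][0] if i + 1 < len(pieces) else math.inf
        if t <= start:
            break
        total += rate * (min(t, end) - start)
    return total


def _invert_cumhaz(pieces, target: float) -> float:
    """First t with cumulative baseline hazard equal to ``target``."""
    total = 0.0
    for i, (start, rate) in enumerate(pieces):
        end = pieces[i + 1][0] if i + 1 < len(pieces) else math.inf
        seg = rate * (end - start)
        if total + seg >= target or end is math.inf:
            return start + (target - total) / rate
        total += seg
    raise AssertionError("unreachable: last piece extends to infinity")


def _design_row(pt: dict) -> dict:
    """Encode one patient exactly as cohort.build_design would."""
    grp = age_group(pt["age_at_index"])
    return {
        "male": 1.0 * (pt["sex"] == "male"),
        "age_30_49": 1.0 * (grp == "30_49"),
        "age_65_79": 1.0 * (grp == "65_79"),
        "age_80_plus": 1.0 * (grp == "80_plus"),
        "sbp": pt["sbp"],
        "dbp": pt["dbp"],
        "diabetes": 1.0 * pt["diabetes"],
        "no_cv_comorbidity": 1.0 * pt["no_cv_comorbidity"],
        "n_other_drugs": pt["n_other_drugs"],
        "income_below_median": 1.0 * (pt["income_group"] == "below_median"),
        "education_lower_secondary": 1.0 * (pt["education"] == "lower_secondary"),
        "education_upper_secondary": 1.0 * (pt["education"] == "upper_secondary"),
        "country_other_nordic": 1.0 * (pt["country_of_birth"] == "other_nordic"),
        "country_europe_non_nordic": 1.0 * (pt["country_of_birth"] == "europe_non_nordic"),
        "country_other": 1.0 * (pt["country_of_birth"] == "other"),
        "class_ace_inhibitor": 1.0 * (pt["drug_class"] == "ACE_INHIBITOR"),
        "class_arb": 1.0 * (pt["drug_class"] == "ARB"),
        "class_beta_blocker": 1.0 * (pt["drug_class"] == "BETA_BLOCKER"),
        "class_ccb": 1.0 * (pt["drug_class"] == "CCB"),
        "class_fixed_combination": 1.0 * (pt["drug_class"] == "FIXED_COMBINATION"),
    }


def _linear_predictor(cfg: SimulationConfig, row: dict) -> float:
    centers = {"sbp": cfg.sbp_mean, "dbp": cfg.dbp_mean, "n_other_drugs": cfg.n_other_drugs_mean}
    lp = 0.0
    for name, beta in cfg.true_loghr.items():
        x = row.get(name, 0.0) - centers.get(name, 0.0)
        lp += beta * x
    return lp


def _sample_dose(cfg, rng) -> Fraction:
    keys = list(cfg.dose_probs)
    probs = [float(cfg.dose_probs[k]) for k in keys]
    return Fraction(_draw_categorical(rng, keys, probs))


def sample_dosage_text(rng, dose: Fraction) -> str:
    options = DOSAGE_TEMPLATES[dose]
    return options[int(rng.integers(0, len(options)))]


def _other_class(rng, index_class: DrugClass) -> DrugClass:
    options = [c for c in _CLASSES if c is not index_class]
    return options[int(rng.integers(0, len(options)))]


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate the full table set plus the ground-truth sidecar."""
    config.validate()
    cfg = config

    patients, diagnoses, dispensings = [], [], []
    hospitalizations, bp_rows, truth, truth_fills = [], [], [], []

    enroll_span = (cfg.enrollment_end - cfg.enrollment_start).days

    for i in range(cfg.n_patients):
        rng = np.random.default_rng([cfg.seed, i])
        pid = f"P{i:06d}"

        # --- planted eligibility violations --------------------------------
        u = rng.random()
        violation = "none"
        thresholds = (
            ("under30", cfg.violator_under30_prob),
            ("dx_after_index", cfg.violator_dx_after_prob),
            ("no_fill", cfg.violator_no_fill_prob),
            ("multi_product", cfg.violator_multi_product_prob),
        )
        acc = 0.0
        for name, p in thresholds:
            acc += p
            if u < acc:
                violation = name
                break

        # --- covariates ----------------------------------------------------
        sex = "male" if rng.random() < cfg.male_prob else "female"
        if violation == "under30":
            age = int(rng.integers(18, 30))
        else:
            age = int(np.clip(round(rng.normal(cfg.age_mean, cfg.age_sd)), 30, 98))
        diabetes = rng.random() < cfg.diabetes_prob
        af = rng.random() < cfg.af_prob
        hf = rng.random() < cfg.hf_prob
        ihd = rng.random() < cfg.ihd_prob
        stroke = rng.random() < cfg.stroke_prob
        sbp = round(rng.normal(cfg.sbp_mean + cfg.sbp_diabetes_shift * diabetes, cfg.sbp_sd))
        dbp = round(rng.normal(cfg.dbp_mean, cfg.dbp_sd))
        dbp = int(min(dbp, sbp - 30))
        sbp = int(sbp)
        education = _draw_categorical(
            rng, ["primary", "lower_secondary", "upper_secondary"], cfg.education_probs
        )
        income = "below_median" if rng.random() < cfg.income_below_prob else "at_or_above_median"
        country = _draw_categorical(
            rng, ["sweden", "other_nordic", "europe_non_nordic", "other"], cfg.country_probs
        )
        n_other = int(min(rng.poisson(cfg.n_other_drugs_mean), len(_OTHER_ATC)))

        index_date = cfg.enrollment_start + timedelta(days=int(rng.integers(0, enroll_span + 1)))
        followup_end = index_date + timedelta(days=cfg.followup_days)

        # --- index drug class (covariate-tilted multinomial) ----------------
        pt = {
            "sex": sex, "age_at_index": age, "diabetes": diabetes,
            "no_cv_comorbidity": not (diabetes or af or hf or ihd or stroke),
            "sbp": sbp, "dbp": dbp, "education": education, "income_group": income,
            "country_of_birth": country, "n_other_drugs": n_other, "drug_class": None,
        }
        base_row = _design_row(pt)
        logits = []
        for cls in _CLASSES:
            lo = math.log(max(cfg.class_probs.get(cls.value, 0.0), 1e-12))
            for cov, tilt in cfg.class_tilts.get(cls.value, {}).items():
                lo += tilt * base_row.get(cov, 0.0)
            logits.append(lo)
        w = np.exp(np.array(logits) - max(logits))
        drug_class = _CLASSES[int(rng.choice(len(_CLASSES), p=w / w.sum()))]
        pt["drug_class"] = drug_class.value

        # --- latent discontinuation time ------------------------------------
        # inverse-transform draw: T = H0^{-1}(E / e^lp) with E ~ Exp(1)
        lp = _linear_predictor(cfg, _design_row(pt))
        mult = math.exp(lp)
        t_latent = _invert_cumhaz(cfg.hazard_pieces(), float(rng.exponential(1.0)) / mult)

        # --- patient & diagnosis rows ---------------------------------------
        death_date = None
        if rng.random() < cfg.death_prob:
            death_date = index_date + timedelta(days=int(rng.integers(1, cfg.followup_days + 120)))

        dx_lag = int(rng.integers(30, 1000))
        if violation == "dx_after_index":
            dx_date = index_date + timedelta(days=int(rng.integers(1, 90)))
        else:
            dx_date = index_date - timedelta(days=dx_lag)
        diagnoses.append((pid, "I10", dx_date))
        for flag_val, code in (
            (af, "I48"), (hf, "I50"), (ihd, "I21"), (stroke, "I63"), (diabetes, "E11"),
        ):
            if flag_val:
                diagnoses.append((pid, code, index_date - timedelta(days=int(rng.integers(30, 2000)))))

        patients.append(
            (pid, sex, age, education, income, country,
             death_date, followup_end)
        )

        # --- non-antihypertensive fills before index (n_other_drugs proxy) --
        if n_other:
            other_codes = rng.choice(len(_OTHER_ATC), size=n_other, replace=False)
            for j in other_codes:
                d = index_date - timedelta(days=int(rng.integers(1, 365)))
                dispensings.append((pid, d, _OTHER_ATC[int(j)], 100, 0.0, "1 tablet daily", 0))

        # --- index blood pressure -------------------------------------------
        if rng.random() < cfg.bp_index_prob:
            bp_rows.append(
                (pid, index_date - timedelta(days=int(rng.integers(1, 366))), sbp, dbp)
            )

        if violation == "no_fill":
            truth.append((pid, violation, drug_class.value, "excluded", None, None,
                          None, None, None, mult, 0, None))
            continue

        # --- index-class fills ----------------------------------------------
        atc_pool = _CLASS_ATC[drug_class]
        atc = atc_pool[int(rng.integers(0, len(atc_pool)))]
        strength = float([5.0, 10.0, 25.0, 50.0][int(rng.integers(0, 4))])
        dose_patient = _sample_dose(cfg, rng)

        unit_bag_from = None
        if rng.random() < cfg.unit_bag_prob:
            unit_bag_from = int(rng.integers(1, 4))  # flagged from this fill onward

        end = Fraction(0)  # supply end, days since index
        cur_dose = None
        day = 0
        n_fills = 0
        addon_day = None
        horizon = cfg.followup_days + cfg.grace_days + 1
        death_day = (death_date - index_date).days if death_date else None
        while True:
            if n_fills > 0 and (day >= t_latent or day >= horizon):
                break
            if death_day is not None and n_fills > 0 and day >= death_day:
                break
            if rng.random() < cfg.missing_dosage_prob:
                dose_fill, text = Fraction(1), ""
            else:
                dose_fill = dose_patient
                text = sample_dosage_text(rng, dose_fill)
            duration = max(20.0, rng.normal(cfg.refill_cycle_days, cfg.refill_jitter_sd))
            tablets = max(1, int(round(duration * float(dose_fill))))
            if Fraction(day) < end:
                carry = (end - day) * cur_dose
                end = day + (tablets + carry) / dose_fill
            else:
                end = day + Fraction(tablets) / dose_fill
            cur_dose = dose_fill
            unit_flag = int(unit_bag_from is not None and n_fills >= unit_bag_from)
            dispensings.append(
                (pid, index_date + timedelta(days=day), atc, tablets, strength, text, unit_flag)
            )
            truth_fills.append((pid, n_fills, index_date + timedelta(days=day), str(dose_fill)))
            n_fills += 1
            # next planned fill around the supply end, sometimes early
            # (stockpiling) or late (still within the grace window)
            u2 = rng.random()
            if u2 < cfg.early_refill_prob:
                delta = -int(rng.integers(1, cfg.early_refill_max_days + 1))
            elif u2 < cfg.early_refill_prob + cfg.late_refill_prob:
                delta = int(rng.integers(1, cfg.grace_days + 1))
            else:
                delta = int(rng.integers(-3, 4))
            day = max(math.ceil(end) + delta, day + 1)

        supply_end = math.ceil(end)  # operational event day, index-relative

        if violation == "multi_product":
            alt = _other_class(rng, drug_class)
            alt_atc = _CLASS_ATC[alt][0]
            dispensings.append(
                (pid, index_date, alt_atc, 100, 10.0, "1 tablet daily", 0)
            )
            truth.append((pid, violation, drug_class.value, "excluded", None, None,
                          None, None, None, mult, n_fills, str(dose_patient)))
            continue

        persistent = supply_end + cfg.grace_days >= cfg.followup_days
        switch_day = switch_cls = None
        if persistent:
            status, event_day = "persistent", cfg.followup_days
        else:
            if rng.random() < cfg.switch_prob:
                status, event_day = "switched", supply_end
                switch_cls = _other_class(rng, drug_class)
                switch_day = supply_end + int(rng.integers(0, cfg.grace_days + 1))
                sw_atc = _CLASS_ATC[switch_cls][0]
                for k in range(int(rng.integers(1, 3))):
                    dispensings.append(
                        (pid, index_date + timedelta(days=switch_day + 92 * k),
                         sw_atc, 100, 10.0, "1 tablet daily", 0)
                    )
            else:
                status, event_day = "discontinued", supply_end

        if rng.random() < cfg.addon_prob and supply_end > 30:
            addon_day = int(rng.integers(1, min(supply_end, cfg.followup_days)))
            addon_cls = _other_class(rng, drug_class)
            # keep the add-on clear of the switch/rescue window
            if addon_day < supply_end:
                dispensings.append(
                    (pid, index_date + timedelta(days=addon_day),
                     _CLASS_ATC[addon_cls][0], 100, 10.0, "1 tablet daily", 0)
                )
            else:
                addon_day = None

        # --- pre-switch blood pressure --------------------------------------
        if status == "switched" and rng.random() < cfg.bp_pre_switch_prob:
            m_day = switch_day - int(rng.integers(1, 181))
            if m_day > 0:
                if rng.random() < cfg.bp_uncontrolled_prob:
                    m_sbp = int(rng.integers(140, 185))
                    m_dbp = int(rng.integers(70, 110))
                else:
                    m_sbp = int(rng.integers(115, 140))
                    m_dbp = int(rng.integers(65, 90))
                bp_rows.append((pid, index_date + timedelta(days=m_day), m_sbp, m_dbp))

        # --- hospitalizations ------------------------------------------------
        if rng.random() < cfg.hosp_prob:
            for _ in range(int(rng.integers(1, 3))):
                admit = index_date + timedelta(days=int(rng.integers(1, cfg.followup_days)))
                length = int(max(1, round(rng.lognormal(
                    cfg.hosp_length_lognorm_mu, cfg.hosp_length_lognorm_sigma))))
                hospitalizations.append((pid, admit, admit + timedelta(days=length)))

        truth.append((
            pid, violation, drug_class.value, status, event_day, round(t_latent, 3),
            switch_day, switch_cls.value if switch_cls else None, addon_day,
            mult, n_fills, str(dose_patient),
        ))

    patients_df = pd.DataFrame(
        patients,
        columns=["patient_id", "sex", "age_at_index", "education", "income_group",
                 "country_of_birth", "death_date", "followup_end"],
    )
    diagnoses_df = pd.DataFrame(diagnoses, columns=["patient_id", "icd10_code", "dx_date"])
    diagnoses_df = diagnoses_df.sort_values(
        ["patient_id", "dx_date", "icd10_code"], kind="stable"
    ).reset_index(drop=True)
    dispensings_df = pd.DataFrame(
        dispensings,
        columns=["patient_id", "fill_date", "atc_code", "tablets",
                 "strength_mg", "dosage_text", "unit_bag"],
    )
    dispensings_df = dispensings_df.sort_values(
        ["patient_id", "fill_date", "atc_code"], kind="stable"
    ).reset_index(drop=True)
    hosp_df = pd.DataFrame(
        hospitalizations, columns=["patient_id", "admit_date", "discharge_date"]
    ).sort_values(["patient_id", "admit_date"], kind="stable").reset_index(drop=True)
    bp_df = pd.DataFrame(
        bp_rows, columns=["patient_id", "measure_date", "sbp", "dbp"]
    ).sort_values(["patient_id", "measure_date"], kind="stable").reset_index(drop=True)
    truth_df = pd.DataFrame(
        truth,
        columns=["patient_id", "planted_violation", "drug_class", "true_status",
                 "true_event_day", "true_latent_day", "switch_day", "switch_class",
                 "addon_day", "true_hazard_multiplier", "n_fills", "daily_dose"],
    )
    truth_fills_df = pd.DataFrame(
        truth_fills, columns=["patient_id", "fill_seq", "fill_date", "true_daily_dose"]
    )
    return SimulatedCohort(
        patients=patients_df,
        diagnoses=diagnoses_df,
        dispensings=dispensings_df,
        hospitalizations=hosp_df,
        bp_measurements=bp_df,
        ground_truth=truth_df,
        ground_truth_fills=truth_fills_df,
        config=config,
    )


def simulate_survival_data(
    n: int,
    log_hrs,
    rng: np.random.Generator,
    baseline_rate: float = 0.002,
    censor_horizon: float = 730.0,
):
    """Continuous-time proportional-hazards draws for recovery tests.

    Balanced binary covariates, exponential baseline, administrative
    censoring at ``censor_horizon``.  Returns ``(X, durations, events)``.
    """
    betas = np.asarray(log_hrs, dtype=float)
    X = (rng.random((n, betas.size)) < 0.5).astype(float)
    rate = baseline_rate * np.exp(X @ betas)
    t = rng.exponential(1.0 / rate)
    durations = np.minimum(t, censor_horizon)
    events = t <= censor_horizon
    # guard against zero-duration pathologies in day-resolution consumers
    durations = np.maximum(durations, 1e-9)
    return X, durations, events


@dataclass
class RecoveryReport:
    n_compared: int
    n_status_match: int
    n_event_time_exact: int
    n_censor_excluded: int
    coef_z: dict

    @property
    def status_match_rate(self) -> float:
        return self.n_status_match / self.n_compared if self.n_compared else float("nan")

    @property
    def event_time_exact_rate(self) -> float:
        return self.n_event_time_exact / self.n_compared if self.n_compared else float("nan")


def recovery_check(
    cohort: SimulatedCohort,
    outcomes: pd.DataFrame,
    cox_fit=None,
    true_loghr: Optional[dict] = None,
) -> RecoveryReport:
    """Compare pipeline outcomes against the generator's ground truth.

    Statuses and event days must agree exactly for every patient whose
    episode was not cut short by a censoring process; Cox coefficients
    (when a fit is supplied) are scored as |beta_hat - beta| / se.
    """
    gt = cohort.ground_truth
    gt = gt[gt["planted_violation"] == "none"]
    merged = gt.merge(outcomes, on="patient_id", how="inner", suffixes=("_true", ""))
    # a persistent episode leaves the pipeline as an end-of-follow-up
    # censoring at the horizon; undo that mapping before comparing
    followup = cohort.config.followup_days
    eof = (merged["status"] == "censored") & (
        merged["censor_reason"] == "end_of_followup"
    ) & (merged["event_time_days"].astype(float) == float(followup))
    merged.loc[eof, "status"] = "persistent"
    # episodes cut short by a censoring process carry no comparable truth
    cut = merged["status"] == "censored"
    n_cut = int(cut.sum())
    merged = merged[~cut]
    n = len(merged)
    status_ok = int((merged["true_status"] == merged["status"]).sum())
    time_ok = int(
        (
            (merged["true_status"] == merged["status"])
            & (merged["true_event_day"].astype(float) == merged["event_time_days"].astype(float))
        ).sum()
    )
    coef_z = {}
    if cox_fit is not None and true_loghr is not None:
        for name, bhat, se in zip(cox_fit.names, cox_fit.coef, cox_fit.se):
            if name in true_loghr:
                coef_z[name] = float((bhat - true_loghr[name]) / se)
    return RecoveryReport(
        n_compared=n,
        n_status_match=status_ok,
        n_event_time_exact=time_ok,
        n_censor_excluded=n_cut,
        coef_z=coef_z,
    )
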