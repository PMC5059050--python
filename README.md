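# rxpersist

Medication persistence, switching and discontinuation from pharmacy
dispensing records — built for pharmacoepidemiologists analysing
claims/registry data on antihypertensive therapy, and for
methodologists who need a fully synthetic, ground-truthed cohort to
validate such pipelines end to end.

## What it computes

Longitudinal dispensing data are the standard way to measure
*persistence* — the time from initiation to discontinuation of a
therapy. For a patient initiating drug class *c*:

1. Each fill's free-text dosage instruction is parsed to a daily rate
   *r* (tablets/day), so a fill of *n* tablets covers *n / r* days;
   missing text defaults to 1 tablet/day. Same-day fills are consumed
   successively, and early refills carry remaining tablets forward
   (exact rational arithmetic, tablet-conserving).
2. The patient is persistent while every gap without supply is ≤ 30
   days (grace period). The episode ends at the first longer gap,
   dated at the end of supply *S*. A different-class antihypertensive
   fill in *(S, S + 30]* makes the patient a **switcher**; a
   different-class fill *during* supply is an **add-on**, never a
   switch. Episodes are censored at death, >21-day hospitalization,
   unit-bag dispensing, or end of follow-up (730 days).
3. Persistence curves are Kaplan–Meier product-limit estimates
   Ŝ(t) = ∏_{t_k ≤ t} (1 − d_k/n_k) with Greenwood standard errors;
   predictors of discontinuation are crude and adjusted hazard ratios
   from a from-scratch Cox proportional-hazards fit (Newton–Raphson
   on the Efron-corrected partial likelihood, Wald 95% CIs).

A synthetic-cohort generator emits every input table
(patients, diagnoses, dispensings, hospitalizations, BP measurements)
from a proportional-hazards ground truth, so the whole pipeline is
testable without access to any real registry.

## Worked example

`python examples/04_full_study.py` simulates 2000 patients and runs
the complete study. It prints (abridged):

```
eligible 1895 of 2000 (exclusions: {'multi_product_initiation': 72,
  'no_antihypertensive_fill': 18, 'dx_after_index': 8, 'age_under_30': 7})

KM persistence by stratum (proportion still on the initial class):
stratum_type           stratum    n  n_events  persist_365  persist_730
     overall               all 1895      1166        0.522        0.376
  drug_class          DIURETIC  452       277        0.549        0.374
  drug_class     ACE_INHIBITOR  787       490        0.511        0.370
         sex            female  954       551        0.563        0.413
         sex              male  941       615        0.481        0.337

Adjusted hazard ratios (selected rows):
  male                   crude 1.27  adj 1.28 (1.14-1.44)  p=0.000
  age_30_49              crude 1.29  adj 1.31 (1.12-1.54)  p=0.001
  sbp                    crude 0.99  adj 0.99 (0.98-0.99)  p=0.000
  class_ace_inhibitor    crude 1.00  adj 0.97 (0.83-1.13)  p=0.683

BP before switch: 22% of 542 switchers had a BP in the prior 26 weeks;
69% of those were still >= 140/90 mm Hg

ground-truth recovery: 100.0% of 1851 comparable episodes reproduced exactly
```

Reading the numbers: about half the cohort is still on its initial
class at 1 year; men and the young discontinue faster (HR > 1), higher
systolic pressure at initiation predicts better persistence (HR < 1
per mm Hg), and drug class carries no effect after adjustment — all
matching the generator's planted truth, with every episode's event day
reproduced exactly from the raw dispensing rows.

The other examples are smaller: `01_dosage_parsing.py` (text → daily
rate), `02_supply_and_episodes.py` (carry-over, switching, censoring),
`03_survival_analysis.py` (KM + Cox parameter recovery).

## Command line

```bash
rxpersist simulate --n-patients 2000 --seed 11 --out data/
rxpersist analyze  --data data/ --out results/
rxpersist full     --config examples/study_config.yaml --out results/
```

`full` = simulate + analyze. Outputs: `persistence.csv`,
`hazard_ratios.csv`, `switching.csv`, `km_curves.csv`,
`exclusions.csv`, `outcomes.csv` and a `manifest.json` whose stage
counts reconcile exactly; `--grace-days`, `--followup-days`,
`--switch-handling`, `--ties-method` override the config. A commented
config template ships in `examples/study_config.yaml`.

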