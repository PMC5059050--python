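# Methods

`rxpersist` estimates *class persistence* — how long patients stay on
the antihypertensive drug class they were started on — from pharmacy
dispensing records, and models predictors of discontinuation. This
note documents the model, the conventions and numerical choices, the
synthetic-data generator, and the limits of what the test suite shows.

## Episode model

**Supply arithmetic.** Consumption starts on the fill day. A fill of
`n` tablets at a parsed rate of `r` tablets/day covers `n / r` days.
Durations are exact rationals (`fractions.Fraction`); nothing is
rounded during accumulation. Three rules connect fills of one class:

* *Same-day fills* are consumed successively, each at its own parsed
  rate.
* *Early refills* (fill strictly before the running supply end)
  trigger carry-over: the remaining tablets — remaining covered days ×
  current rate, computed exactly — are added to the new fill and
  consumed at the new fill's rate. Tablet conservation (Σ interval
  length × rate = tablets dispensed) holds exactly after every
  carry-over and is property-tested.
* *Later fills* start a fresh coverage segment on their fill day.

**Day-resolution boundary.** When a fractional supply end `E` meets
calendar days it is rounded up: `S = ceil(E)` is the first uncovered
day, so a half-day remainder still covers its last partial day. All
gap comparisons use `S`.

**Gap rule.** The episode survives any gap of at most `grace_days`
(default 30): an index-class fill on day `S + 30` still continues the
episode; day `S + 31` does not, and a fill after the grace window
cannot retroactively rescue the episode. Discontinuation is dated at
the end of supply (`S`), not the end of grace — dating at `S` avoids
crediting uncovered days as exposure; `event_at:
supply_end_plus_grace` selects the alternative convention.

**Switching and add-ons.** A fill of a *different* antihypertensive
class in the window `[S, S + grace]` after the final supply end makes
the episode a *switch* (still an uncovered-time event dated at `S`,
with the switch date and destination class recorded). A
different-class fill on any covered day (`< S`) is an *add-on*: the
patient is combining classes, and the episode is never classified as a
switch on that account — add-ons are flagged and reported separately.
A fill on exactly day `S` (the first uncovered day) counts as a
switch: at day resolution it happens after the supply has ended.

**Censoring.** Episodes are censored at: death; admission date of the
first hospitalization longer than 21 days (exposure observation stops
at admission); the first unit-bag (machine-dose) dispensing, whose
refill records do not reflect prescriptions; or end of follow-up
(2 years = 730 days, non-leap convention). The earliest candidate
strictly before the event wins; ties break death > hospitalization >
unit bags > end of follow-up. Persistent episodes always end as
end-of-follow-up censorings.

**Estimand.** By default a switch counts as a discontinuation event of
the index class (class persistence = staying on the initial class);
`switch_handling: censor` treats switchers as censored instead. The
comparison of the two is itself tested (censoring switchers raises the
survivor curve).

## Dosage-text grammar

Prescription dosage instructions are free text. The parser implements
an explicit mini-grammar — `<quantity> tablet[s] [<frequency>]`,
clauses joined by `and` are summed, quantities are decimals or ASCII
fractions, frequencies from a data-driven rule table (`daily`, `every
other day` = ×1/2, `twice daily` = ×2, `three times daily` = ×3,
morning/evening/night = ×1) — extensible via a plain-text rule file.
Parsing is total: blank text defaults to 1 tablet/day (the standard
assumption for the ~0.6% of prescriptions without instructions), and
any non-matching text (dose ranges, pro-re-nata phrasing) defaults the
same way but is flagged and logged, surfacing in the pipeline QC
counts. Real Swedish prescription texts are out of scope; the grammar
is a reproducible, testable dialect that the synthetic generator emits
exclusively.

## Cohort and covariates

Eligibility: age ≥ 30 at index, hypertension diagnosis (ICD-10 I10)
strictly before the first antihypertensive fill, index fill inside the
enrollment window (when configured), at least one antihypertensive
fill, and exactly one product class on the index date (a single
fixed-combination product qualifies). One exclusion reason per
patient, precedence age → diagnosis → no fill → window →
multi-product; the log reconciles exactly (input = eligible +
excluded).

ATC classes: ACE inhibitors C09A, ARBs C09C, beta blockers C07, CCBs
C08, diuretics C03A/C03B/C03D/C03E (mineralocorticoid antagonists and
amiloride count as diuretics), fixed combinations C07FB02/C09BA/C09D;
longest-prefix match, everything else `OTHER`. Comorbidity flags from
ICD-10 prefixes: I48, I50, I20–I25, I60–I69 + G45, E10–E11, with
`no_cv_comorbidity` their negated union.

The adjusted Cox model uses: sex (female reference), age group 30–49 /
50–64 (reference) / 65–79 / ≥80 (cut-points configurable), systolic
and diastolic index BP (last measurement strictly before the index
fill, mm Hg, continuous), diabetes, no-CV-comorbidity, count of
distinct non-antihypertensive substances (7-character ATC) filled in
the 365 days before index — a reproducible proxy for "number of other
drugs" — income (at/above median reference), education (primary
reference), country of birth (Sweden reference), and initiated drug
class (diuretic reference). Patients without a recorded index BP
(~4% under generator defaults) are excluded from both crude and
adjusted fits (same analysis set, so crude-vs-adjusted contrasts are
comparable); the count is logged in the manifest. Crude hazard ratios
fit one covariate block at a time; adjusted ratios come from the joint
fit. Zero-variance dummy columns (e.g. an absent age group in a small
cohort) are dropped with a logged warning.

The BP-before-switch audit takes the latest measurement in the
half-open window `[switch − 182 days, switch)` (26 weeks, the switch
day excluded) and calls it uncontrolled when SBP ≥ 140 **or** DBP ≥ 90
mm Hg, the standard control convention.

## Survival estimation

**Kaplan–Meier.** Product-limit estimator with Greenwood standard
errors. The running product is accumulated in exact rational
arithmetic and converted to float per step, so small worked examples
reproduce exactly rather than to rounding error. With no censoring the
estimator reduces to 1 − ECDF (property-tested).

**Cox regression.** Newton–Raphson maximization of the log partial
likelihood, Efron tie correction by default (day-resolution
discontinuation times produce many ties; Breslow is available and
agrees exactly on tie-free data). Covariates are centered and scaled
internally — the partial likelihood is invariant to centering, and a
standardized design keeps the gradient tolerance meaningful —
then coefficients and standard errors are mapped back. Step-halving
guarantees a non-decreasing log-likelihood path; convergence requires
gradient max-norm < 1e-9 (standardized scale) or relative
log-likelihood change < 1e-12; non-convergence is flagged on the
result, never silent. Standard errors come from the inverse observed
information; confidence intervals are Wald intervals on the log scale;
P values are two-tailed Wald tests. The design matrix is checked for
rank via pivoted QR and rejected naming the collinear columns.
Correctness is established against brute-force enumeration of the
partial likelihood (1-D), an independent reference implementation to
1e-6 on 50 random datasets, a 4-parameter recovery study at n = 5000,
and 95% CI coverage within [93%, 97%] over 1000 replicates.

## Synthetic cohort generator

No suitable primary-care dispensing registry is publicly available, so
the generator emulates one with known ground truth. Defaults (all
overridable):

* **Scale and structure**: index dates uniform over a 2006–2007
  enrollment window; 730-day follow-up; ~90-day refill cycles with
  jitter; deliberate early refills (25%, exercising carry-over) and
  late-but-within-grace refills (15%).
* **Initiation shares**: ACE inhibitors 36%, ARBs 4%, beta blockers
  21%, CCBs 8%, diuretics 27%, fixed combinations 4%, tilted by
  covariates (diabetics and men toward ACE inhibitors, women toward
  diuretics/beta blockers, higher income and education toward ARBs).
* **Discontinuation**: latent event time from a proportional-hazards
  model with piecewise-constant baseline (0.001539/day in year 1,
  0.000772/day in year 2: latent survivor ≈ 57% at 1 year, 43% at 2),
  true log-hazard ratios per design column (men +0.25, age 30–49
  +0.40, SBP −0.012 per mm Hg, birth outside the Nordic countries
  +0.30/+0.35, diabetes +0.20, drug classes null except fixed
  combinations +0.15). Continuous covariates enter centered.
* **Covariate marginals** are plausible placeholders for a Swedish
  primary-care hypertension cohort (age ≈ 62 ± 12, SBP ≈ 166 ± 19 with
  treated diabetics 8 mm Hg lower — the correlation that produces the
  crude-vs-adjusted diabetes reversal — DBP ≈ 93 ± 11), **not**
  registry-derived, and fully overridable.
* **Processes**: switch fills in `[S, S+30]` after 45% of ended
  episodes; add-on fills mid-supply (8%); 0.6% blank dosage texts
  (those fills are consumed at the 1/day default, keeping record and
  truth consistent); death (0.5%, truncating further fills);
  hospitalizations (15% of patients, lognormal lengths, a minority
  exceeding 21 days); unit-bag onset (0.54%); pre-index BP recorded
  for 96% (dated up to a year before index), pre-switch BP for 21% of
  switchers, 69% of them uncontrolled.
* **Planted eligibility violators** (under-30, diagnosis after index,
  never-filled, multi-product initiation) at roughly the exclusion
  rates such cohorts report, each carrying its intended exclusion
  reason in the ground truth.

Determinism: every patient draws from an RNG substream keyed by
`(seed, patient_index)`, so output is byte-identical under a fixed
seed and extending the cohort never perturbs existing patients.

The ground truth records both the *latent* continuous event time (for
distributional checks against the closed-form survivor, via a DKW band
at α = 0.01) and the *operational* event day — the rounded-up end of
the final fill's supply, which is what any claims pipeline can
observe. The pipeline must reproduce operational statuses and event
days exactly for every episode not cut short by a censoring process;
this holds by construction and is asserted, not approximated.

**What the defaults do and do not show.** Observed KM readouts sit a
few points below the latent survivor targets (e.g. ≈51% vs 57% at
1 year) because the observed event day is the latent time rounded down
to the refill grid — an inherent property of claims-based persistence
measurement, not a calibration error. The generator emits only the
parseable dosage dialect, one product strength per patient, and no
post-initiation routine BP visits; passing tests therefore demonstrate
the correctness of the episode logic, survival estimation and
reporting on registry-*shaped* data, not robustness to real-world
free-text or coding noise.

## Numerical and degenerate-input choices

* Exact rational arithmetic end-to-end in supply construction; floats
  only enter at survival estimation.
* KM at a time where everyone at risk fails gives S = 0 with an
  undefined (NaN) Greenwood SE.
* Episodes with non-positive follow-up time (e.g. unit-bag initiation
  censored on the index day) cannot enter a risk set and are dropped
  from survival fits with a logged count.
* Same-day fills of different strength or product within one class are
  concatenated (consumed successively, each at its own rate) and
  logged as QC anomalies.
* Switch-candidate ties on the same day break deterministically by
  class name.
* Empty strata and zero-variance covariates are omitted with logged
  warnings rather than propagating singular fits.

## Known limitations

* Single-episode model: restarts after the first discontinuation are
  out of scope, as are PDC/MPR-style adherence metrics, dose-titration
  detection, time-varying covariates and competing-risks models.
* Hospitalizations do not pause the refill clock in the generator; in
  the analysis they only censor (when > 21 days).
* The baseline-characteristics tables of a real study (group
  comparisons at initiation) are not part of this pipeline.
* The crude-vs-adjusted diabetes reversal can only be demonstrated
  qualitatively on synthetic data built with the stated SBP–diabetes
  correlation; its magnitude in any real registry depends on that
  registry's covariate structure.
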