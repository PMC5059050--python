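"""End-to-end persistence study: eligibility -> episodes -> survival.

``analyze`` is the library entry point (tables in, result tables out);
``run_study`` wraps it with file I/O, logging and a run manifest whose
stage counts always reconcile (input = retained + excluded at every
stage).  Outputs are deterministic for a fixed seed and config, so
re-running a study yields checksum-identical files.

Output tables
-------------
persistence.csv    KM persistence by stratum (overall / drug class / sex)
                   at the configured readout days, with Greenwood SEs
hazard_ratios.csv  crude and adjusted hazard ratios for discontinuation
                   with 95% CIs and two-tailed Wald P values
switching.csv      switch proportions by initiated class
km_curves.csv      full KM step functions, long format
exclusions.csv     one row per excluded patient with the single reason
manifest.json      config snapshot, checksums, stage counts, QC tallies
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atc import DrugClass, classify_atc
from .cohort import (
    COVARIATE_BLOCKS,
    apply_eligibility,
    bp_before_switch,
    build_cohort_table,
    build_design,
)
from .dosage import DEFAULT_GRAMMAR, load_grammar, parse_dosage
from .episodes import (
    CensorReason,
    Status,
    apply_censoring,
    build_supply_schedule,
    determine_outcome,
    record_from_row,
)
from .errors import ConfigError
from .io import InputTables, load_inputs
from .simulate import SimulatedCohort, SimulationConfig, generate_cohort
from .survival import cox_fit, km_estimate

logger = logging.getLogger("rxpersist.pipeline")


@dataclass
class StudyConfig:
    grace_days: int = 30
    followup_days: int = 730
    event_at: str = "supply_end"  # or "supply_end_plus_grace"
    switch_handling: str = "event"  # or "censor"
    ties_method: str = "efron"
    readout_days: tuple = (365, 730)
    bp_switch_window_days: int = 182
    dosage_grammar_file: Optional[str] = None  # extra frequency rules (phrase\tmultiplier)
    n_other_drugs_window_days: int = 365
    enrollment_start: Optional[date] = None
    enrollment_end: Optional[date] = None
    km_plot: bool = False
    simulation: Optional[SimulationConfig] = None

    def validate(self) -> None:
        if self.grace_days < 0:
            raise ConfigError("grace_days must be >= 0")
        if self.followup_days <= 0:
            raise ConfigError("followup_days must be > 0")
        if self.event_at not in ("supply_end", "supply_end_plus_grace"):
            raise ConfigError(f"unknown event_at: {self.event_at!r}")
        if self.switch_handling not in ("event", "censor"):
            raise ConfigError(f"unknown switch_handling: {self.switch_handling!r}")
        if self.ties_method not in ("efron", "breslow"):
            raise ConfigError(f"unknown ties_method: {self.ties_method!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d or {})
        sim = d.pop("simulation", None)
        known = {f.name for f in dataclasses.fields(cls)} - {"simulation"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("enrollment_start", "enrollment_end"):
            if isinstance(d.get(key), str):
                d[key] = date.fromisoformat(d[key])
        if "readout_days" in d:
            d["readout_days"] = tuple(int(x) for x in d["readout_days"])
        cfg = cls(**d)
        if sim is not None:
            cfg.simulation = SimulationConfig.from_dict(sim)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in list(d.items()):
            if isinstance(v, date):
                d[k] = v.isoformat()
        sim = d.get("simulation")
        if sim:
            for k, v in list(sim.items()):
                if isinstance(v, date):
                    sim[k] = v.isoformat()
        return d


@dataclass
class StudyResult:
    cohort: pd.DataFrame
    outcomes: pd.DataFrame
    persistence: pd.DataFrame
    hazard_ratios: pd.DataFrame
    switching: pd.DataFrame
    km_curves: pd.DataFrame
    bp_audit: dict
    exclusions: pd.DataFrame
    manifest: dict
    adjusted_fit: object = None
    km_overall: object = None


# ---------------------------------------------------------------------------
# episode construction
# ---------------------------------------------------------------------------


def build_outcomes(tables: InputTables, eligible: pd.DataFrame, config: StudyConfig):
    """Supply schedules -> pre-censoring outcomes -> censored outcomes."""
    grammar = (
        load_grammar(config.dosage_grammar_file)
        if config.dosage_grammar_file
        else DEFAULT_GRAMMAR
    )
    disp = tables.dispensings
    qc = {"parsed": 0, "defaulted_missing": 0, "defaulted_unparseable": 0, "same_day_anomalies": 0}
    rows = []
    death_by_pid = dict(zip(tables.patients["patient_id"], tables.patients["death_date"]))
    fup_by_pid = dict(zip(tables.patients["patient_id"], tables.patients["followup_end"]))
    hosp_by_pid = {
        pid: list(zip(g["admit_date"], g["discharge_date"]))
        for pid, g in tables.hospitalizations.groupby("patient_id")
    }
    disp_by_pid = {pid: g for pid, g in disp.groupby("patient_id")}

    for rec in eligible.to_dict("records"):
        pid = rec["patient_id"]
        g = disp_by_pid.get(pid)
        records = [record_from_row(r) for r in g.to_dict("records")]
        index_class = DrugClass(rec["index_class"])
        index_fills = [r for r in records if classify_atc(r.atc_code) is index_class]
        parses = [parse_dosage(r.dosage_text, grammar=grammar) for r in index_fills]
        for p in parses:
            qc[p.source.value] += 1
        schedule = build_supply_schedule(index_fills, parses)
        qc["same_day_anomalies"] += len(schedule.anomalies)
        outcome = determine_outcome(
            schedule,
            records,
            grace_days=config.grace_days,
            followup_days=config.followup_days,
            event_at=config.event_at,
        )
        unit_bag_dates = [r.fill_date for r in records if r.unit_bag]
        outcome = apply_censoring(
            outcome,
            death_date=death_by_pid.get(pid),
            hospitalizations=hosp_by_pid.get(pid, []),
            unit_bag_start=min(unit_bag_dates) if unit_bag_dates else None,
            followup_end=fup_by_pid.get(pid),
            followup_days=config.followup_days,
        )
        rows.append(
            {
                "patient_id": pid,
                "index_class": index_class.value,
                "status": outcome.status.value,
                "event_time_days": outcome.event_time_days,
                "censor_reason": outcome.censor_reason.value,
                "switch_date": outcome.switch_date,
                "switch_to_class": (
                    outcome.switch_to_class.value if outcome.switch_to_class else None
                ),
                "addon": outcome.addon,
                "n_addons": len(outcome.addon_dates),
            }
        )
    return pd.DataFrame(rows), qc


def _to_survival(outcomes: pd.DataFrame, switch_handling: str):
    """Map outcome statuses to (duration, event) pairs.

    Discontinuation is the event; switching counts as discontinuation
    of the index class by default (``switch_handling="event"``) or as
    censoring (``"censor"``).  Censored episodes contribute their
    censor time.  Episodes with non-positive times (e.g. unit-bag
    initiation censored on the index day) cannot enter the risk set
    and are dropped with a logged count.
    """
    df = outcomes.copy()
    event = df["status"].eq(Status.DISCONTINUED.value)
    if switch_handling == "event":
        event |= df["status"].eq(Status.SWITCHED.value)
    keep = df["event_time_days"] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d episodes with non-positive follow-up time", n_dropped)
    return df[keep], event[keep].to_numpy(), df.loc[keep, "event_time_days"].to_numpy(float), n_dropped


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def persistence_report(outcomes: pd.DataFrame, cohort: pd.DataFrame, config: StudyConfig):
    """KM persistence by stratum, HR tables, switching, KM curves."""
    merged = outcomes.merge(
        cohort.drop(columns=["index_class"]), on="patient_id", how="left"
    )
    kept, events, durations, n_dropped = _to_survival(merged, config.switch_handling)

    strata = [("overall", "all", np.ones(len(kept), dtype=bool))]
    for cls in sorted(kept["index_class"].unique()):
        strata.append(("drug_class", cls, (kept["index_class"] == cls).to_numpy()))
    for sex in sorted(kept["sex"].dropna().unique()):
        strata.append(("sex", sex, (kept["sex"] == sex).to_numpy()))

    persist_rows, curve_rows = [], []
    km_overall = None
    for stype, sname, mask in strata:
        if mask.sum() == 0:
            logger.warning("stratum %s=%s has no patients; omitted", stype, sname)
            continue
        curve = km_estimate(durations[mask], events[mask])
        if stype == "overall":
            km_overall = curve
        row = {
            "stratum_type": stype,
            "stratum": sname,
            "n": int(mask.sum()),
            "n_events": int(events[mask].sum()),
        }
        for t in config.readout_days:
            row[f"persist_{t}"] = curve.survival_at(t)
        persist_rows.append(row)
        cf = curve.to_frame()
        cf.insert(0, "stratum", sname)
        cf.insert(0, "stratum_type", stype)
        curve_rows.append(cf)

    persistence = pd.DataFrame(persist_rows)
    km_curves = pd.concat(curve_rows, ignore_index=True)

    # --- Cox fits: complete-case on recorded index blood pressure ---------
    has_bp = kept["index_sbp"].notna() & kept["index_dbp"].notna()
    n_bp_missing = int((~has_bp).sum())
    sub = kept[has_bp].reset_index(drop=True)
    ev = events[has_bp.to_numpy()]
    dur = durations[has_bp.to_numpy()]
    X = build_design(sub)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        logger.warning("dropping constant design columns: %s", ", ".join(constant))
        X = X.drop(columns=constant)

    adjusted = cox_fit(X, dur, ev, ties_method=config.ties_method)
    adj = adjusted.summary()

    hr_rows = []
    for block, cols in COVARIATE_BLOCKS.items():
        cols = [c for c in cols if c in X.columns]
        if not cols:
            logger.warning("covariate block %r has no varying columns; omitted", block)
            continue
        crude = cox_fit(X[cols], dur, ev, ties_method=config.ties_method).summary()
        for c in cols:
            hr_rows.append(
                {
                    "covariate": block,
                    "level": c,
                    "crude_hr": crude.loc[c, "hr"],
                    "crude_ci_lower": crude.loc[c, "hr_ci_lower"],
                    "crude_ci_upper": crude.loc[c, "hr_ci_upper"],
                    "crude_p": crude.loc[c, "p"],
                    "adj_hr": adj.loc[c, "hr"],
                    "adj_ci_lower": adj.loc[c, "hr_ci_lower"],
                    "adj_ci_upper": adj.loc[c, "hr_ci_upper"],
                    "adj_p": adj.loc[c, "p"],
                }
            )
    hazard_ratios = pd.DataFrame(hr_rows)

    # --- switching ----------------------------------------------------------
    sw_rows = []
    switched = merged["status"].eq(Status.SWITCHED.value)
    for cls, grp in merged.groupby("index_class"):
        sw_rows.append(
            {
                "drug_class": cls,
                "n_initiated": len(grp),
                "n_switched": int(grp["status"].eq(Status.SWITCHED.value).sum()),
            }
        )
    sw_rows.append(
        {"drug_class": "all", "n_initiated": len(merged), "n_switched": int(switched.sum())}
    )
    switching = pd.DataFrame(sw_rows)
    switching["pct_switched"] = 100.0 * switching["n_switched"] / switching["n_initiated"]

    extras = {
        "n_dropped_nonpositive_time": n_dropped,
        "n_missing_index_bp": n_bp_missing,
        "n_cox_sample": int(len(sub)),
    }
    return persistence, hazard_ratios, switching, km_curves, adjusted, km_overall, extras


def bp_switch_audit(
    outcomes: pd.DataFrame, bp_measurements: pd.DataFrame, window_days: int = 182
) -> dict:
    """How often was a BP recorded in the 26 weeks before a switch, and
    how often was that last BP still >= 140/90 mm Hg?"""
    sw = outcomes[outcomes["status"] == Status.SWITCHED.value]
    bp_by_pid = {pid: g for pid, g in bp_measurements.groupby("patient_id")}
    n_recorded = n_uncontrolled = 0
    empty = bp_measurements.iloc[0:0]
    for rec in sw.to_dict("records"):
        res = bp_before_switch(
            rec["switch_date"], bp_by_pid.get(rec["patient_id"], empty), window_days
        )
        if res["recorded"]:
            n_recorded += 1
            if res["uncontrolled"]:
                n_uncontrolled += 1
    n = len(sw)
    return {
        "n_switchers": n,
        "n_bp_recorded": n_recorded,
        "pct_bp_recorded": 100.0 * n_recorded / n if n else float("nan"),
        "n_uncontrolled": n_uncontrolled,
        "pct_uncontrolled": 100.0 * n_uncontrolled / n_recorded if n_recorded else float("nan"),
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def tables_from_simulation(sim: SimulatedCohort) -> InputTables:
    return InputTables(
        patients=sim.patients,
        dispensings=sim.dispensings,
        diagnoses=sim.diagnoses,
        hospitalizations=sim.hospitalizations,
        bp_measurements=sim.bp_measurements,
        checksums={},
    )


def analyze(tables: InputTables, config: StudyConfig) -> StudyResult:
    """Run the full analysis on loaded tables."""
    config.validate()
    elig = apply_eligibility(
        tables.patients,
        tables.dispensings,
        tables.diagnoses,
        enrollment_start=config.enrollment_start,
        enrollment_end=config.enrollment_end,
    )
    logger.info(
        "eligibility: %d in, %d eligible, %d excluded",
        len(tables.patients), len(elig.eligible), len(elig.exclusions),
    )
    cohort = build_cohort_table(
        elig.eligible,
        tables.diagnoses,
        tables.dispensings,
        tables.bp_measurements,
        n_other_drugs_window_days=config.n_other_drugs_window_days,
    )
    outcomes, qc = build_outcomes(tables, elig.eligible, config)
    (persistence, hazard_ratios, switching, km_curves,
     adjusted, km_overall, extras) = persistence_report(outcomes, cohort, config)
    audit = bp_switch_audit(outcomes, tables.bp_measurements, config.bp_switch_window_days)

    status_tally = outcomes["status"].value_counts().to_dict()
    censor_tally = (
        outcomes.loc[outcomes["censor_reason"] != CensorReason.NONE.value, "censor_reason"]
        .value_counts()
        .to_dict()
    )
    exclusion_tally = elig.exclusions["reason"].value_counts().to_dict()
    manifest = {
        "software_version": __version__,
        "config": config.to_jsonable(),
        "input_checksums": tables.checksums,
        "counts": {
            "patients_in": int(len(tables.patients)),
            "eligible": int(len(elig.eligible)),
            "excluded": int(len(elig.exclusions)),
            "outcomes": int(len(outcomes)),
            "exclusion_reasons": exclusion_tally,
            "status": status_tally,
            "censor_reasons": censor_tally,
            "dosage_qc": qc,
            **extras,
        },
        "bp_switch_audit": audit,
    }
    assert manifest["counts"]["patients_in"] == (
        manifest["counts"]["eligible"] + manifest["counts"]["excluded"]
    )
    return StudyResult(
        cohort=cohort,
        outcomes=outcomes,
        persistence=persistence,
        hazard_ratios=hazard_ratios,
        switching=switching,
        km_curves=km_curves,
        bp_audit=audit,
        exclusions=elig.exclusions,
        manifest=manifest,
        adjusted_fit=adjusted,
        km_overall=km_overall,
    )


def _write_result(result: StudyResult, out_dir: Path, km_plot: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    result.persistence.to_csv(out_dir / "persistence.csv", index=False, float_format=fmt)
    result.hazard_ratios.to_csv(out_dir / "hazard_ratios.csv", index=False, float_format=fmt)
    result.switching.to_csv(out_dir / "switching.csv", index=False, float_format=fmt)
    result.km_curves.to_csv(out_dir / "km_curves.csv", index=False, float_format=fmt)
    result.exclusions.to_csv(out_dir / "exclusions.csv", index=False)
    result.outcomes.to_csv(out_dir / "outcomes.csv", index=False, float_format=fmt)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    if km_plot:
        plot_km_curves(result.km_curves, out_dir / "km_curves.png")


def plot_km_curves(km_curves: pd.DataFrame, path) -> None:
    """Step plot of per-class persistence curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    sub = km_curves[km_curves["stratum_type"] == "drug_class"]
    for cls, grp in sub.groupby("stratum"):
        ax.step(
            np.concatenate([[0.0], grp["time"].to_numpy()]),
            np.concatenate([[1.0], grp["survival"].to_numpy()]),
            where="post", label=cls,
        )
    ax.set_xlabel("days since first fill")
    ax.set_ylabel("proportion persistent")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_study(
    config: StudyConfig,
    out_dir,
    data_dir=None,
    seed: Optional[int] = None,
) -> StudyResult:
    """Run (and optionally simulate) a complete study into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("rxpersist")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        if data_dir is not None:
            tables = load_inputs(data_dir)
        else:
            if config.simulation is None:
                raise ConfigError("no data_dir given and no simulation config present")
            if seed is not None:
                config.simulation.seed = seed
            sim = generate_cohort(config.simulation)
            sim_dir = out_dir / "data"
            paths = sim.write(sim_dir)
            tables = load_inputs(sim_dir)
            logger.info("simulated %d patients into %s", config.simulation.n_patients, sim_dir)
        result = analyze(tables, config)
        result.manifest["seed"] = seed if seed is not None else (
            config.simulation.seed if config.simulation else None
        )
        _write_result(result, out_dir, config.km_plot)
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
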