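"""CSV input schemas and validated loading.

All tables are plain CSV, one row per event, dates in ISO 8601
(YYYY-MM-DD).  Validation failures name the file, the 1-based data row
and the column so malformed registry extracts fail loudly and early.

Schemas::

    patients.csv          patient_id, sex, age_at_index, education,
                          income_group, country_of_birth,
                          death_date (optional), followup_end
    dispensings.csv       patient_id, fill_date, atc_code, tablets,
                          strength_mg, dosage_text, unit_bag {0,1}
    diagnoses.csv         patient_id, icd10_code, dx_date
    hospitalizations.csv  patient_id, admit_date, discharge_date
    bp_measurements.csv   patient_id, measure_date, sbp, dbp
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import SchemaError

REQUIRED_COLUMNS = {
    "patients": [
        "patient_id", "sex", "age_at_index", "education",
        "income_group", "country_of_birth", "death_date", "followup_end",
    ],
    "dispensings": [
        "patient_id", "fill_date", "atc_code", "tablets",
        "strength_mg", "dosage_text", "unit_bag",
    ],
    "diagnoses": ["patient_id", "icd10_code", "dx_date"],
    "hospitalizations": ["patient_id", "admit_date", "discharge_date"],
    "bp_measurements": ["patient_id", "measure_date", "sbp", "dbp"],
}

DATE_COLUMNS = {
    "patients": ["death_date", "followup_end"],
    "dispensings": ["fill_date"],
    "diagnoses": ["dx_date"],
    "hospitalizations": ["admit_date", "discharge_date"],
    "bp_measurements": ["measure_date"],
}

OPTIONAL_DATE_COLUMNS = {"death_date"}


@dataclass
class InputTables:
    patients: pd.DataFrame
    dispensings: pd.DataFrame
    diagnoses: pd.DataFrame
    hospitalizations: pd.DataFrame
    bp_measurements: pd.DataFrame
    checksums: dict


def _parse_date_column(df: pd.DataFrame, col: str, fname: str, optional: bool) -> None:
    raw = df[col].astype("string")
    blank = raw.isna() | (raw.str.strip() == "")
    parsed = pd.to_datetime(raw.where(~blank), format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & ~blank
    if bad.any():
        pos = int(bad.to_numpy().argmax())
        raise SchemaError(
            f"{fname}, row {pos + 1}, column {col}: invalid date {raw.iloc[pos]!r}"
        )
    if not optional and blank.any():
        pos = int(blank.to_numpy().argmax())
        raise SchemaError(f"{fname}, row {pos + 1}, column {col}: missing date")
    df[col] = [ts.date() if isinstance(ts, pd.Timestamp) else None for ts in parsed]


def load_table(path: str | Path, name: str) -> pd.DataFrame:
    """Load and validate one input table."""
    path = Path(path)
    fname = path.name
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing required columns: {', '.join(missing)}")
    for col in DATE_COLUMNS[name]:
        _parse_date_column(df, col, fname, optional=col in OPTIONAL_DATE_COLUMNS)
    if name == "dispensings":
        df["dosage_text"] = df["dosage_text"].fillna("").astype(str)
        for col in ("tablets", "unit_bag"):
            if not pd.api.types.is_numeric_dtype(df[col]):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna()
                if bad.any():
                    pos = int(bad.to_numpy().argmax())
                    raise SchemaError(
                        f"{fname}, row {pos + 1}, column {col}: "
                        f"non-numeric value {df[col].iloc[pos]!r}"
                    )
                df[col] = coerced
        df["tablets"] = df["tablets"].astype(int)
        df["unit_bag"] = df["unit_bag"].astype(int)
    return df


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_inputs(data_dir: str | Path) -> InputTables:
    """Load the five study tables from a directory of CSVs."""
    data_dir = Path(data_dir)
    frames = {}
    checksums = {}
    for name in REQUIRED_COLUMNS:
        path = data_dir / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing input file: {path}")
        frames[name] = load_table(path, name)
        checksums[f"{name}.csv"] = sha256_of(path)
    return InputTables(checksums=checksums, **frames)
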