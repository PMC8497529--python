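"""Flat-file EHR data model.

A cohort is exchanged as a directory of UTF-8, comma-delimited tables with a
header row and ISO-8601 dates:

    patients.csv     patient_id,birth_date,race,sex
    diagnoses.csv    patient_id,date,code,system,clinic
    medications.csv  patient_id,date,drug_name,drug_code,med_class
    encounters.csv   patient_id,date,has_coded_dx
    notes.csv        patient_id,date,note_type,text
    spirometry.csv   patient_id,date,ratio,phase,source   (optional)

Tables are held in memory as pandas DataFrames inside a :class:`Cohort`.
Rows that cannot be parsed (bad dates, non-numeric ratios, blank keys) are
routed to a :class:`ReadReport` rather than silently dropped; referential
problems (events whose patient_id has no patient row) are flagged as warnings
because real extracts contain them and downstream filters are keyed per
patient anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ISO_DATE = "%Y-%m-%d"

#: table name -> (filename, columns, date columns, required)
SCHEMAS: dict[str, tuple[str, list[str], list[str], bool]] = {
    "patients": ("patients.csv", ["patient_id", "birth_date", "race", "sex"], ["birth_date"], True),
    "diagnoses": ("diagnoses.csv", ["patient_id", "date", "code", "system", "clinic"], ["date"], True),
    "medications": ("medications.csv", ["patient_id", "date", "drug_name", "drug_code", "med_class"], ["date"], True),
    "encounters": ("encounters.csv", ["patient_id", "date", "has_coded_dx"], ["date"], True),
    "notes": ("notes.csv", ["patient_id", "date", "note_type", "text"], ["date"], True),
    "spirometry": ("spirometry.csv", ["patient_id", "date", "ratio", "phase", "source"], ["date"], False),
}

_BOOL_MAP = {"true": True, "1": True, "false": False, "0": False}


def _empty_table(name: str) -> pd.DataFrame:
    """A zero-row frame with the canonical dtypes for ``name``."""
    _, cols, date_cols, _ = SCHEMAS[name]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    for c in date_cols:
        df[c] = pd.Series(dtype="datetime64[ns]")
    if name == "spirometry":
        df["ratio"] = pd.Series(dtype=float)
    if name == "encounters":
        df["has_coded_dx"] = pd.Series(dtype=bool)
    return df


@dataclass
class ReadReport:
    """Parse problems collected while reading a cohort directory."""

    bad_rows: dict[str, pd.DataFrame] = field(default_factory=dict)
    orphan_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_bad_rows(self) -> int:
        return int(sum(len(df) for df in self.bad_rows.values()))


@dataclass
class Cohort:
    """Keyed event collections for one EHR extract."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    medications: pd.DataFrame
    encounters: pd.DataFrame
    notes: pd.DataFrame
    spirometry: pd.DataFrame

    @classmethod
    def empty(cls) -> "Cohort":
        return cls(**{name: _empty_table(name) for name in SCHEMAS})

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    @property
    def patient_ids(self) -> pd.Index:
        return pd.Index(self.patients["patient_id"])

    def events_for(self, table: str, patient_id: str) -> pd.DataFrame:
        df = self.table(table)
        return df[df["patient_id"] == patient_id]

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when clean)."""
        problems: list[str] = []
        ids = self.patients["patient_id"]
        if ids.duplicated().any():
            problems.append("duplicate patient_id in patients table")
        known = set(ids)
        for name in ("diagnoses", "medications", "encounters", "notes", "spirometry"):
            orphans = ~self.table(name)["patient_id"].isin(known)
            if orphans.any():
                problems.append(f"{name}: {int(orphans.sum())} rows with unknown patient_id")
        if len(self.spirometry) and (self.spirometry["ratio"] <= 0).any():
            problems.append("spirometry: non-positive ratio")
        return problems


def _parse_table(name: str, path: Path, report: ReadReport) -> pd.DataFrame:
    _, cols, date_cols, _ = SCHEMAS[name]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in raw.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required columns {missing}")
    raw = raw[cols].copy()

    bad = pd.Series(False, index=raw.index)
    reasons = pd.Series("", index=raw.index, dtype=object)

    blank_key = raw["patient_id"].str.strip() == ""
    bad |= blank_key
    reasons[blank_key] = "blank patient_id"

    parsed_dates = {}
    for c in date_cols:
        dt = pd.to_datetime(raw[c], format=ISO_DATE, errors="coerce", exact=True)
        invalid = dt.isna()
        reasons[invalid & ~bad] = f"unparseable date in {c!r}"
        bad |= invalid
        parsed_dates[c] = dt

    if name == "spirometry":
        ratio = pd.to_numeric(raw["ratio"], errors="coerce")
        invalid = ratio.isna() | (ratio <= 0) | (ratio > 2)
        reasons[invalid & ~bad] = "ratio not a number in (0, 2]"
        bad |= invalid
    if name == "encounters":
        flag = raw["has_coded_dx"].str.strip().str.lower().map(_BOOL_MAP)
        invalid = flag.isna()
        reasons[invalid & ~bad] = "has_coded_dx not boolean"
        bad |= invalid

    if bad.any():
        rej = raw[bad].copy()
        rej["reason"] = reasons[bad]
        report.bad_rows[name] = rej.reset_index(drop=True)

    df = raw[~bad].copy()
    for c, dt in parsed_dates.items():
        df[c] = dt[~bad]
    if name == "spirometry":
        df["ratio"] = pd.to_numeric(df["ratio"])
    if name == "encounters":
        df["has_coded_dx"] = df["has_coded_dx"].str.strip().str.lower().map(_BOOL_MAP).astype(bool)
    df = df.reset_index(drop=True)
    return df if len(df) else _empty_table(name)


def read_cohort(directory: str | Path) -> tuple[Cohort, ReadReport]:
    """Read a cohort directory; unparseable rows go to the report, not the bin.

    Raises ``FileNotFoundError`` if a required table file is absent.  The
    optional ``spirometry.csv`` defaults to an empty table.
    """
    directory = Path(directory)
    report = ReadReport()
    tables: dict[str, pd.DataFrame] = {}
    for name, (fname, _, _, required) in SCHEMAS.items():
        path = directory / fname
        if not path.exists():
            if required:
                raise FileNotFoundError(f"required cohort file missing: {path}")
            tables[name] = _empty_table(name)
            continue
        tables[name] = _parse_table(name, path, report)

    cohort = Cohort(**tables)

    known = set(cohort.patients["patient_id"])
    for name in ("diagnoses", "medications", "encounters", "notes", "spirometry"):
        n_orphan = int((~cohort.table(name)["patient_id"].isin(known)).sum())
        if n_orphan:
            report.orphan_counts[name] = n_orphan
            report.warnings.append(f"{name}: {n_orphan} event rows reference unknown patients")

    # birth-before-event is flagged, not fatal: source extracts can be dirty
    births = cohort.patients.set_index("patient_id")["birth_date"]
    for name in ("diagnoses", "medications", "encounters", "notes", "spirometry"):
        df = cohort.table(name)
        if not len(df):
            continue
        b = df["patient_id"].map(births)
        n_before = int((df["date"] < b).sum())
        if n_before:
            report.warnings.append(f"{name}: {n_before} events dated before patient birth")
    return cohort, report


def write_cohort(cohort: Cohort, directory: str | Path) -> list[Path]:
    """Write all six canonical files (header-only when empty); return manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for name, (fname, cols, date_cols, _) in SCHEMAS.items():
        df = cohort.table(name)[cols].copy()
        for c in date_cols:
            df[c] = pd.to_datetime(df[c]).dt.strftime(ISO_DATE)
        if name == "encounters" and len(df):
            df["has_coded_dx"] = np.where(df["has_coded_dx"], "true", "false")
        path = directory / fname
        df.to_csv(path, index=False)
        manifest.append(path)
    return manifest
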