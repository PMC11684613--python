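"""Reading, writing and validating claims bundles.

The on-disk form of a :class:`~asa_persistence.model.ClaimsBundle` is
five UTF-8, comma-separated CSV files with mandatory header rows and
ISO-8601 dates:

* ``patients.csv``:    patient_id,sex,birth_month,enrollment_start
* ``dispensings.csv``: patient_id,date,institution_id,drug_code,drug_class,route,subtype,days_supply
* ``diagnoses.csv``:   patient_id,date,institution_id,disease_code,is_uc,suspected,principal,claim_type
* ``visits.csv``:      patient_id,date,institution_id
* ``deaths.csv``:      patient_id,date

Writing is deterministic: fixed column order, rows sorted by
(patient_id, date, remaining columns), ``\\n`` line endings — the same
bundle always produces byte-identical files.

A code map (YAML) can stand in for national drug/disease code
dictionaries: it maps each drug_code to (drug_class, route, subtype)
and each disease_code to a UC flag, letting bundles whose dispensing
and diagnosis tables carry bare codes be annotated at ingestion.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .model import (
    CLAIM_TYPES,
    DRUG_CLASSES,
    ROUTES,
    SEXES,
    SUBTYPES,
    TABLE_COLUMNS,
    ClaimsBundle,
    IntegrityError,
    SchemaError,
    parse_date,
)

__all__ = [
    "read_bundle",
    "write_bundle",
    "validate_bundle",
    "load_code_map",
    "annotate_with_code_map",
    "DEFAULT_CODE_MAP",
]

_BOOL_COLUMNS = {"is_uc", "suspected", "principal"}
_DATE_COLUMNS = {"date", "enrollment_start"}
_ENUM_COLUMNS = {
    "sex": SEXES,
    "drug_class": DRUG_CLASSES,
    "route": ROUTES,
    "subtype": SUBTYPES,
    "claim_type": CLAIM_TYPES,
}

#: Synthetic stand-in for the national drug/disease code dictionaries.
DEFAULT_CODE_MAP: Mapping[str, Mapping] = {
    "drugs": {
        "A5T01": {"drug_class": "ASA5", "route": "oral", "subtype": "time_dependent"},
        "A5P01": {"drug_class": "ASA5", "route": "oral", "subtype": "ph_dependent"},
        "A5M01": {"drug_class": "ASA5", "route": "oral", "subtype": "mmx"},
        "A5TOP1": {"drug_class": "ASA5", "route": "topical", "subtype": "not_applicable"},
        "SASP01": {"drug_class": "SASP", "route": "oral", "subtype": "not_applicable"},
        "OTH01": {"drug_class": "OTHER", "route": "oral", "subtype": "not_applicable"},
    },
    "diseases": {
        "UC01": {"is_uc": True},
        "K51X": {"is_uc": True},
        "OTHDX": {"is_uc": False},
    },
}


def load_code_map(path: str | Path) -> dict:
    """Load a YAML code map with ``drugs`` and ``diseases`` sections."""
    with open(path, "r", encoding="utf-8") as fh:
        cm = yaml.safe_load(fh)
    if not isinstance(cm, dict) or "drugs" not in cm or "diseases" not in cm:
        raise SchemaError(f"code map {path} must contain 'drugs' and 'diseases' sections")
    return cm


def annotate_with_code_map(bundle: ClaimsBundle, code_map: Mapping) -> ClaimsBundle:
    """Fill drug/disease attribute columns from bare codes.

    Unknown codes raise :class:`SchemaError`; columns already present
    are overwritten so the code map is authoritative.
    """
    disp = bundle.dispensings.copy()
    drugs = code_map["drugs"]
    unknown = set(disp["drug_code"]) - set(drugs)
    if unknown:
        raise SchemaError(f"dispensings: unknown drug codes {sorted(unknown)[:5]}")
    for col in ("drug_class", "route", "subtype"):
        disp[col] = disp["drug_code"].map(lambda c: drugs[c][col])
    dx = bundle.diagnoses.copy()
    diseases = code_map["diseases"]
    unknown = set(dx["disease_code"]) - set(diseases)
    if unknown:
        raise SchemaError(f"diagnoses: unknown disease codes {sorted(unknown)[:5]}")
    dx["is_uc"] = dx["disease_code"].map(lambda c: bool(diseases[c]["is_uc"]))
    out = ClaimsBundle(
        patients=bundle.patients,
        dispensings=disp,
        diagnoses=dx,
        visits=bundle.visits,
        deaths=bundle.deaths,
        db_start=bundle.db_start,
        db_end=bundle.db_end,
    )
    validate_bundle(out)
    return out


def _parse_table(name: str, df: pd.DataFrame, source: str) -> pd.DataFrame:
    expected = TABLE_COLUMNS[name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing columns {missing}")
    df = df.loc[:, list(expected)].copy()
    for col in expected:
        if col in _DATE_COLUMNS:
            try:
                df[col] = pd.to_datetime(df[col], format="%Y-%m-%d").dt.date
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{source}: unparseable date in column {col}: {exc}") from exc
        elif col in _BOOL_COLUMNS:
            bad = ~df[col].astype(str).str.lower().isin(["true", "false"])
            if bad.any():
                row = int(df.index[bad][0])
                raise SchemaError(f"{source}: row {row}: column {col} must be true/false")
            df[col] = df[col].astype(str).str.lower() == "true"
        elif col in _ENUM_COLUMNS:
            allowed = _ENUM_COLUMNS[col]
            bad = ~df[col].isin(allowed)
            if bad.any():
                row = int(df.index[bad][0])
                raise SchemaError(
                    f"{source}: row {row}: {col}={df[col].iloc[row]!r} not in {allowed}"
                )
        elif col == "days_supply":
            try:
                df[col] = df[col].astype(int)
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{source}: days_supply must be integer: {exc}") from exc
        else:
            df[col] = df[col].astype(str)
    return df


def read_bundle(
    paths: Mapping[str, str | Path] | str | Path,
    db_start: dt.date | str = dt.date(2013, 4, 1),
    db_end: dt.date | str = dt.date(2021, 6, 30),
    code_map: Mapping | str | Path | None = None,
) -> ClaimsBundle:
    """Read and validate a claims bundle.

    ``paths`` is either a directory containing the five canonically
    named CSVs or a mapping table-name -> file path.  Row order in the
    files never affects downstream results.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {name: base / f"{name}.csv" for name in TABLE_COLUMNS}
    tables = {}
    for name in TABLE_COLUMNS:
        path = Path(paths[name])
        if not path.exists():
            raise SchemaError(f"missing input file: {path}")
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        tables[name] = _parse_table(name, raw, str(path))
    bundle = ClaimsBundle(
        db_start=parse_date(db_start), db_end=parse_date(db_end), **tables
    )
    if code_map is not None:
        if isinstance(code_map, (str, Path)):
            code_map = load_code_map(code_map)
        return annotate_with_code_map(bundle, code_map)
    validate_bundle(bundle)
    return bundle


def validate_bundle(bundle: ClaimsBundle) -> None:
    """Check referential and temporal integrity; raise on violation."""
    patients = bundle.patients
    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise IntegrityError(f"patients: duplicate patient_id {dup!r}")
    known = set(patients["patient_id"])

    disp = bundle.dispensings
    if (disp["days_supply"] < 1).any():
        row = int(disp.index[disp["days_supply"] < 1][0])
        raise SchemaError(f"dispensings: row {row}: days_supply must be >= 1")
    oral_asa5 = (disp["drug_class"] == "ASA5") & (disp["route"] == "oral")
    bad = oral_asa5 != (disp["subtype"] != "not_applicable")
    if bad.any():
        row = int(disp.index[bad][0])
        raise SchemaError(
            f"dispensings: row {row}: subtype must be set exactly for oral ASA5 products"
        )

    for name, df in bundle.tables().items():
        if name == "patients":
            continue
        orphans = set(df["patient_id"]) - known
        if orphans:
            raise IntegrityError(f"{name}: unknown patient_id {sorted(orphans)[:5]}")
        dates = df["date"]
        out = (dates < bundle.db_start) | (dates > bundle.db_end)
        if out.any():
            row = int(df.index[out][0])
            raise IntegrityError(
                f"{name}: row {row}: date {dates.iloc[row]} outside "
                f"[{bundle.db_start}, {bundle.db_end}]"
            )

    deaths = bundle.deaths
    if deaths["patient_id"].duplicated().any():
        dup = deaths.loc[deaths["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise IntegrityError(f"deaths: more than one death record for {dup!r}")
    if len(deaths):
        death_by_pid = deaths.set_index("patient_id")["date"]
        for name in ("dispensings", "diagnoses", "visits"):
            df = bundle.tables()[name]
            dd = df["patient_id"].map(death_by_pid)
            late = dd.notna() & (df["date"] > dd)
            if late.any():
                pid = df.loc[late, "patient_id"].iloc[0]
                raise IntegrityError(f"{name}: event after death date for {pid!r}")

    # enrollment_start must not postdate any event of the patient
    events = pd.concat(
        [bundle.tables()[n][["patient_id", "date"]] for n in TABLE_COLUMNS if n != "patients"],
        ignore_index=True,
    )
    if len(events):
        first = events.groupby("patient_id")["date"].min()
        enr = patients.set_index("patient_id")["enrollment_start"]
        joined = pd.concat([first.rename("first"), enr.rename("enr")], axis=1).dropna()
        bad = joined["enr"] > joined["first"]
        if bad.any():
            pid = joined.index[bad][0]
            raise IntegrityError(f"patients: enrollment_start after first event for {pid!r}")


def write_bundle(bundle: ClaimsBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the five CSVs deterministically; returns the file paths."""
    validate_bundle(bundle)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in bundle.tables().items():
        cols = list(TABLE_COLUMNS[name])
        frame = df.loc[:, cols].copy()
        for col in cols:
            if col in _DATE_COLUMNS:
                frame[col] = frame[col].map(lambda d: d.isoformat())
            elif col in _BOOL_COLUMNS:
                frame[col] = frame[col].map(lambda b: "true" if b else "false")
        frame = frame.sort_values(cols, kind="mergesort").reset_index(drop=True)
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def write_code_map(code_map: Mapping, path: str | Path) -> Path:
    """Serialise a code map to YAML (sorted keys, deterministic)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {k: dict(v) for k, v in code_map.items()}, fh, sort_keys=True, allow_unicode=True
        )
    return path
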