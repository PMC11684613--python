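"""Shared fixtures: hand-built tiny claims bundles and generator output."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from asa_persistence.model import ClaimsBundle, StudyConfig, TABLE_COLUMNS
from asa_persistence.simulate import SimParams, generate

D = dt.date


def empty_frames() -> dict[str, pd.DataFrame]:
    return {name: pd.DataFrame(columns=list(cols)) for name, cols in TABLE_COLUMNS.items()}


def make_bundle(
    patients=(),
    dispensings=(),
    diagnoses=(),
    visits=(),
    deaths=(),
    db_start=D(2013, 4, 1),
    db_end=D(2021, 6, 30),
) -> ClaimsBundle:
    """Build a bundle from row dicts, filling schema defaults."""
    defaults = {
        "patients": {"sex": "male", "birth_month": "1980-01"},
        "dispensings": {
            "institution_id": "H1",
            "drug_code": "A5T01",
            "drug_class": "ASA5",
            "route": "oral",
            "subtype": "time_dependent",
            "days_supply": 30,
        },
        "diagnoses": {
            "institution_id": "H1",
            "disease_code": "UC01",
            "is_uc": True,
            "suspected": False,
            "principal": True,
            "claim_type": "regular",
        },
        "visits": {"institution_id": "H1"},
        "deaths": {},
    }
    frames = {}
    data = {
        "patients": patients,
        "dispensings": dispensings,
        "diagnoses": diagnoses,
        "visits": visits,
        "deaths": deaths,
    }
    for name, rows in data.items():
        cols = list(TABLE_COLUMNS[name])
        filled = [{**defaults[name], **row} for row in rows]
        frames[name] = pd.DataFrame(filled, columns=cols) if filled else pd.DataFrame(columns=cols)
    # patients table needs enrollment_start <= first event
    pts = frames["patients"]
    if len(pts) and pts["enrollment_start"].isna().all():
        events = pd.concat(
            [frames[n][["patient_id", "date"]] for n in data if n != "patients"],
            ignore_index=True,
        )
        first = events.groupby("patient_id")["date"].min() if len(events) else {}
        pts["enrollment_start"] = pts["patient_id"].map(first).fillna(db_start)
    return ClaimsBundle(db_start=db_start, db_end=db_end, **frames)


def eligible_patient_rows(
    pid="X1",
    index=D(2016, 6, 1),
    subtype="time_dependent",
    institution="H1",
    birth_month="1980-01",
    sex="male",
):
    """Rows for one textbook-eligible patient (all four criteria met)."""
    code = {"time_dependent": "A5T01", "ph_dependent": "A5P01", "mmx": "A5M01"}[subtype]
    return {
        "patients": [{"patient_id": pid, "sex": sex, "birth_month": birth_month}],
        "dispensings": [
            {
                "patient_id": pid,
                "date": index,
                "institution_id": institution,
                "drug_code": code,
                "subtype": subtype,
            }
        ],
        "diagnoses": [{"patient_id": pid, "date": index, "institution_id": institution}],
        "visits": [
            {"patient_id": pid, "date": index - dt.timedelta(days=400), "institution_id": institution},
            {"patient_id": pid, "date": index, "institution_id": institution},
        ],
    }


@pytest.fixture(scope="session")
def config() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def labelled_sim():
    """Generator output with all contamination classes present (seed 11)."""
    params = SimParams(n_patients=400, seed=11)
    bundle, truth = generate(params)
    return params, bundle, truth
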