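"""New-user cohort extraction for oral 5-ASA in ulcerative colitis.

A patient enters the cohort when all four criteria hold:

1. at least one *oral* 5-ASA dispensing during the accrual window; the
   earliest such dispensing sets the index date (day 0) and the index
   subtype;
2. a UC diagnosis carried as principal (never as "suspected") at the
   institution that dispensed the index prescription, dated within the
   symmetric diagnosis window (day -28 .. day +28 by default);
3. a clean washout: no oral or topical 5-ASA and no salazosulfapyridine
   dispensing on days -365 .. -1 (new-user guarantee);
4. verifiable prior enrollment: at least one visit of any kind between
   the database start and day -366.

All window endpoints are inclusive.  The funnel is applied in the order
above and an attrition report records the count remaining after each
step.  Same-day ties for the index dispensing are broken
lexicographically by (subtype, drug_code) — deterministic and
order-insensitive.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import pandas as pd

from .model import (
    ClaimsBundle,
    IntegrityError,
    StudyConfig,
    age_group_of,
    age_years,
    fiscal_year_of,
)

__all__ = [
    "find_index",
    "check_uc_diagnosis",
    "check_washout",
    "check_enrollment",
    "build_cohort",
    "ATTRITION_LABELS",
    "COHORT_COLUMNS",
]

ATTRITION_LABELS = (
    "patients in database",
    "oral 5-ASA prescribed during study period (index date assigned)",
    "principal UC diagnosis within diagnosis window at prescribing institution",
    "no prior 5-ASA/SASP during washout (newly prescribed)",
    "enrollment verified by visit before lookback boundary",
)

COHORT_COLUMNS = (
    "patient_id",
    "index_date",
    "index_subtype",
    "age_at_index",
    "age_group",
    "fiscal_year",
    "sex",
)


def _index_table(dispensings: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """One row per patient with an index dispensing, columns
    patient_id/index_date/index_subtype/index_institution_id/drug_code."""
    d = dispensings
    mask = (
        (d["drug_class"] == "ASA5")
        & (d["route"] == "oral")
        & (d["date"] >= config.accrual_start)
        & (d["date"] <= config.accrual_end)
    )
    cand = d.loc[mask, ["patient_id", "date", "subtype", "drug_code", "institution_id"]]
    if cand.empty:
        return pd.DataFrame(
            columns=["patient_id", "index_date", "index_subtype", "index_institution_id", "drug_code"]
        )
    cand = cand.sort_values(
        ["patient_id", "date", "subtype", "drug_code"], kind="mergesort"
    )
    first = cand.groupby("patient_id", as_index=False).first()
    return first.rename(
        columns={"date": "index_date", "subtype": "index_subtype", "institution_id": "index_institution_id"}
    )


def find_index(
    dispensings: pd.DataFrame, config: StudyConfig
) -> Optional[dict]:
    """Index dispensing for a single patient's dispensing table, or None.

    Returns a dict with index_date, index_subtype, index_institution_id
    and drug_code of the earliest qualifying oral 5-ASA dispensing in
    the accrual window.
    """
    table = _index_table(dispensings, config)
    if table.empty:
        return None
    if table["patient_id"].nunique() > 1:
        raise ValueError("find_index expects dispensings of a single patient")
    row = table.iloc[0]
    return {
        "index_date": row["index_date"],
        "index_subtype": row["index_subtype"],
        "index_institution_id": row["index_institution_id"],
        "drug_code": row["drug_code"],
    }


def _dx_qualifies(index_tab: pd.DataFrame, diagnoses: pd.DataFrame, config: StudyConfig) -> pd.Series:
    """Boolean per index-table row: principal non-suspected UC diagnosis
    at the prescribing institution within the diagnosis window."""
    if index_tab.empty:
        return pd.Series(dtype=bool)
    dx = diagnoses.loc[
        diagnoses["is_uc"] & diagnoses["principal"] & ~diagnoses["suspected"],
        ["patient_id", "date", "institution_id"],
    ]
    merged = index_tab[["patient_id", "index_date", "index_institution_id"]].merge(
        dx, on="patient_id", how="left"
    )
    offset = (
        pd.to_datetime(merged["date"]) - pd.to_datetime(merged["index_date"])
    ).dt.days
    ok = (
        merged["date"].notna()
        & (merged["institution_id"] == merged["index_institution_id"])
        & (offset >= -config.dx_window_days)
        & (offset <= config.dx_window_days)
    )
    hit = merged.loc[ok, "patient_id"].unique()
    return index_tab["patient_id"].isin(hit)


def check_uc_diagnosis(
    index_info: dict, patient_id: str, diagnoses: pd.DataFrame, config: StudyConfig
) -> bool:
    """Criterion 2 for a single candidate."""
    tab = pd.DataFrame(
        [
            {
                "patient_id": patient_id,
                "index_date": index_info["index_date"],
                "index_institution_id": index_info["index_institution_id"],
            }
        ]
    )
    return bool(_dx_qualifies(tab, diagnoses, config).iloc[0])


def _washout_clean(index_tab: pd.DataFrame, dispensings: pd.DataFrame, config: StudyConfig) -> pd.Series:
    if index_tab.empty:
        return pd.Series(dtype=bool)
    washout_drugs = dispensings.loc[
        dispensings["drug_class"].isin(["ASA5", "SASP"]), ["patient_id", "date"]
    ]
    merged = index_tab[["patient_id", "index_date"]].merge(
        washout_drugs, on="patient_id", how="left"
    )
    offset = (
        pd.to_datetime(merged["date"]) - pd.to_datetime(merged["index_date"])
    ).dt.days
    dirty = merged["date"].notna() & (offset >= -config.washout_days) & (offset <= -1)
    bad = merged.loc[dirty, "patient_id"].unique()
    return ~index_tab["patient_id"].isin(bad)


def check_washout(
    index_info: dict, patient_id: str, dispensings: pd.DataFrame, config: StudyConfig
) -> bool:
    """Criterion 3 for a single candidate."""
    tab = pd.DataFrame([{"patient_id": patient_id, "index_date": index_info["index_date"]}])
    return bool(_washout_clean(tab, dispensings, config).iloc[0])


def _enrollment_ok(
    index_tab: pd.DataFrame, visits: pd.DataFrame, config: StudyConfig, db_start: dt.date
) -> pd.Series:
    if index_tab.empty:
        return pd.Series(dtype=bool)
    merged = index_tab[["patient_id", "index_date"]].merge(
        visits[["patient_id", "date"]], on="patient_id", how="left"
    )
    boundary = pd.to_datetime(merged["index_date"]) - pd.Timedelta(
        days=config.enrollment_lookback_boundary_days
    )
    ok = (
        merged["date"].notna()
        & (pd.to_datetime(merged["date"]) >= pd.Timestamp(db_start))
        & (pd.to_datetime(merged["date"]) <= boundary)
    )
    hit = merged.loc[ok, "patient_id"].unique()
    return index_tab["patient_id"].isin(hit)


def check_enrollment(
    index_info: dict, patient_id: str, visits: pd.DataFrame, config: StudyConfig,
    db_start: dt.date = dt.date(2013, 4, 1),
) -> bool:
    """Criterion 4 for a single candidate."""
    tab = pd.DataFrame([{"patient_id": patient_id, "index_date": index_info["index_date"]}])
    return bool(_enrollment_ok(tab, visits, config, db_start).iloc[0])


def build_cohort(
    bundle: ClaimsBundle, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four-criterion funnel; return (cohort, attrition).

    The cohort frame carries, per included patient, the index date,
    index subtype, the prescribing institution (used downstream only
    internally), age at index, age group, fiscal year of index, and
    sex.  The attrition frame has columns step/label/n_remaining with
    weakly decreasing counts.
    """
    counts = [bundle.n_patients]

    index_tab = _index_table(bundle.dispensings, config)

    # a death dated before the index dispensing is a data defect
    if len(bundle.deaths) and len(index_tab):
        death = bundle.deaths.set_index("patient_id")["date"]
        dd = index_tab["patient_id"].map(death)
        early = dd.notna() & (dd < index_tab["index_date"])
        if early.any():
            pid = index_tab.loc[early, "patient_id"].iloc[0]
            raise IntegrityError(f"death before index dispensing for patient {pid!r}")

    counts.append(len(index_tab))

    keep = _dx_qualifies(index_tab, bundle.diagnoses, config)
    index_tab = index_tab.loc[list(keep)] if len(index_tab) else index_tab
    counts.append(len(index_tab))

    keep = _washout_clean(index_tab, bundle.dispensings, config)
    index_tab = index_tab.loc[list(keep)] if len(index_tab) else index_tab
    counts.append(len(index_tab))

    keep = _enrollment_ok(index_tab, bundle.visits, config, bundle.db_start)
    index_tab = index_tab.loc[list(keep)] if len(index_tab) else index_tab
    counts.append(len(index_tab))

    attrition = pd.DataFrame(
        {
            "step": range(len(ATTRITION_LABELS)),
            "label": ATTRITION_LABELS,
            "n_remaining": counts,
        }
    )

    if index_tab.empty:
        cohort = pd.DataFrame(columns=list(COHORT_COLUMNS) + ["index_institution_id"])
        return cohort, attrition

    members = index_tab.merge(
        bundle.patients[["patient_id", "sex", "birth_month"]], on="patient_id", how="left"
    )
    members["age_at_index"] = [
        age_years(bm, d) for bm, d in zip(members["birth_month"], members["index_date"])
    ]
    members["age_group"] = [
        age_group_of(bm, d, config.age_bins)
        for bm, d in zip(members["birth_month"], members["index_date"])
    ]
    members["fiscal_year"] = [
        fiscal_year_of(d, config.fiscal_year_start_month) for d in members["index_date"]
    ]
    cohort = members[
        list(COHORT_COLUMNS) + ["index_institution_id"]
    ].sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    return cohort, attrition


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write cohort.csv with the documented columns, deterministically."""
    out = cohort.loc[:, list(COHORT_COLUMNS)].copy()
    out["index_date"] = out["index_date"].map(lambda d: d.isoformat())
    out = out.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    out.to_csv(path, index=False, lineterminator="\n")


def write_attrition(attrition: pd.DataFrame, path) -> None:
    attrition.to_csv(path, index=False, lineterminator="\n")
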