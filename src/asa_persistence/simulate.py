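"""Synthetic claims generator with known ground truth.

Emulates the structure of a nationwide claims database for studying
oral 5-ASA persistence in ulcerative colitis: per-patient dispensing
streams with days-supply, principal/suspected diagnosis flags attached
to institutions, regular and DPC claim types, fiscal-year accrual, a
three-subtype oral 5-ASA market in which the MMX product only exists
from November 2016, washout-relevant topical 5-ASA and SASP products,
and death events.

The discontinuation process is a discrete refill-cycle hazard: each
cycle dispenses a days-supply drawn from a small discrete set; after
exhausting a cycle the patient stops with a per-cycle probability
(elevated on the first cycle, mimicking early intolerance); otherwise
the next fill occurs at the supply frontier plus a random delay.  The
day on which a stopping patient's supply runs out is the true
discontinuation day, and :func:`true_persistence` computes its exact
distribution by convolving the cycle-length distributions — the
closed-form recovery target for the whole pipeline.

Contamination classes each violate exactly one inclusion criterion:
``prior_user`` (washout), ``suspected_only`` (diagnosis flagged
suspected), ``no_principal_dx`` (no qualifying principal diagnosis),
``unenrolled`` (no visit before the lookback boundary).  Deaths are
drawn post-index and truncate the patient's event stream.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import ClaimsBundle, ORAL_ASA5_SUBTYPES, fiscal_year_of, parse_date
from .io import DEFAULT_CODE_MAP, validate_bundle

__all__ = ["SimParams", "generate", "true_persistence", "GROUND_TRUTH_COLUMNS", "LABELS"]

LABELS = ("eligible", "prior_user", "suspected_only", "no_principal_dx", "unenrolled")

GROUND_TRUTH_COLUMNS = (
    "patient_id",
    "label",
    "index_date",
    "true_subtype",
    "true_stop_day",
    "death_day",
)

_SUBTYPE_CODE = {
    "time_dependent": "A5T01",
    "ph_dependent": "A5P01",
    "mmx": "A5M01",
}

#: Index-subtype market mixture per fiscal year (time, pH, MMX).  The
#: pH-dependent product leads in FY2015 and MMX grows steadily after
#: its November 2016 market entry.
_DEFAULT_MIXTURE = {
    2015: {"time_dependent": 0.468, "ph_dependent": 0.532, "mmx": 0.0},
    2016: {"time_dependent": 0.46, "ph_dependent": 0.49, "mmx": 0.05},
    2017: {"time_dependent": 0.43, "ph_dependent": 0.43, "mmx": 0.14},
    2018: {"time_dependent": 0.41, "ph_dependent": 0.41, "mmx": 0.18},
    2019: {"time_dependent": 0.40, "ph_dependent": 0.38, "mmx": 0.22},
}


def _normalize(probs: Mapping) -> dict:
    total = float(sum(probs.values()))
    if total <= 0:
        raise ValueError("probability mass must be positive")
    return {k: v / total for k, v in probs.items()}


@dataclass
class SimParams:
    """Generator knobs; defaults describe the emulated study population."""

    n_patients: int = 1000
    seed: int = 0
    accrual_start: dt.date = dt.date(2015, 4, 1)
    accrual_end: dt.date = dt.date(2019, 9, 30)
    db_start: dt.date = dt.date(2013, 4, 1)
    db_end: dt.date = dt.date(2021, 6, 30)
    mmx_market_entry: dt.date = dt.date(2016, 11, 1)
    subtype_mixture_by_fy: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {fy: dict(m) for fy, m in _DEFAULT_MIXTURE.items()}
    )
    #: days-supply distribution per refill cycle
    supply_probs: Mapping[int, float] = field(
        default_factory=lambda: {14: 0.05, 28: 0.15, 30: 0.55, 56: 0.15, 90: 0.10}
    )
    #: uncovered days between supply exhaustion and the next fill; the
    #: long tail (40, 75 days) creates refills that only survive the
    #: wider grace periods
    delay_probs: Mapping[int, float] = field(
        default_factory=lambda: {
            0: 0.40, 1: 0.15, 2: 0.10, 3: 0.10, 5: 0.021,
            7: 0.10, 14: 0.05, 21: 0.05, 40: 0.022, 75: 0.007,
        }
    )
    first_cycle_hazard: float = 0.14
    hazard_per_cycle: float = 0.055
    prior_user_frac: float = 0.50
    suspected_only_frac: float = 0.04
    no_principal_dx_frac: float = 0.06
    unenrolled_frac: float = 0.05
    death_rate_per_year: float = 0.002
    age_mean: float = 43.2
    age_sd: float = 16.7
    male_frac: float = 0.565
    subtype_switch_prob: float = 0.02
    dpc_claim_frac: float = 0.10
    multi_institution: bool = False
    #: generate refills until the supply frontier passes this offset
    max_followup_days: int = 620

    def __post_init__(self):
        for name in ("accrual_start", "accrual_end", "db_start", "db_end", "mmx_market_entry"):
            setattr(self, name, parse_date(getattr(self, name)))
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        window = (self.accrual_end - self.accrual_start).days
        if window < min(self.supply_probs):
            raise ValueError("accrual window shorter than one refill cycle")
        self.supply_probs = _normalize({int(k): float(v) for k, v in self.supply_probs.items()})
        self.delay_probs = _normalize({int(k): float(v) for k, v in self.delay_probs.items()})
        if any(k < 1 for k in self.supply_probs):
            raise ValueError("days_supply values must be >= 1")
        if any(k < 0 for k in self.delay_probs):
            raise ValueError("refill delays must be non-negative")
        for h in (self.first_cycle_hazard, self.hazard_per_cycle):
            if not 0.0 <= h <= 1.0:
                raise ValueError("hazards must lie in [0, 1]")
        fracs = (
            self.prior_user_frac,
            self.suspected_only_frac,
            self.no_principal_dx_frac,
            self.unenrolled_frac,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) >= 1.0 + 1e-12:
            raise ValueError("contamination fractions must lie in [0,1] and sum below 1")
        self.subtype_mixture_by_fy = {
            int(fy): _normalize({s: float(p) for s, p in mix.items()})
            for fy, mix in self.subtype_mixture_by_fy.items()
        }

    def label_probs(self) -> dict:
        eligible = 1.0 - (
            self.prior_user_frac
            + self.suspected_only_frac
            + self.no_principal_dx_frac
            + self.unenrolled_frac
        )
        return {
            "eligible": eligible,
            "prior_user": self.prior_user_frac,
            "suspected_only": self.suspected_only_frac,
            "no_principal_dx": self.no_principal_dx_frac,
            "unenrolled": self.unenrolled_frac,
        }

    def mixture_for(self, index_date: dt.date) -> dict:
        fy = fiscal_year_of(index_date)
        years = sorted(self.subtype_mixture_by_fy)
        key = min(max(fy, years[0]), years[-1])
        mix = dict(self.subtype_mixture_by_fy[key])
        if index_date < self.mmx_market_entry:
            mix["mmx"] = 0.0
        return _normalize(mix)

    def to_mapping(self) -> dict:
        out = {}
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if isinstance(value, dt.date):
                value = value.isoformat()
            elif isinstance(value, Mapping):
                value = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in value.items()}
            out[name] = value
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SimParams":
        unknown = set(mapping) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown SimParams keys: {sorted(unknown)}")
        return cls(**dict(mapping))


def _choice(rng: np.random.Generator, probs: Mapping):
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def _refill_stream(rng: np.random.Generator, params: SimParams):
    """Fill (offset, supply) pairs plus the true stop day (None = still
    on therapy when generation stops past max_followup_days)."""
    supply = _choice(rng, params.supply_probs)
    fills = [(0, supply)]
    frontier = supply
    cycle = 1
    while True:
        hazard = params.first_cycle_hazard if cycle == 1 else params.hazard_per_cycle
        if rng.random() < hazard:
            return fills, frontier
        if frontier > params.max_followup_days:
            return fills, None
        delay = _choice(rng, params.delay_probs)
        offset = frontier + delay
        supply = _choice(rng, params.supply_probs)
        fills.append((offset, supply))
        frontier = offset + supply
        cycle += 1


def generate(params: SimParams) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Generate a claims bundle and its ground-truth table.

    Reproducible for a given seed; every contamination class violates
    exactly one inclusion criterion while satisfying the rest.
    """
    rng = np.random.default_rng(params.seed)
    accrual_days = (params.accrual_end - params.accrual_start).days + 1
    label_probs = params.label_probs()

    patients, dispensings, diagnoses, visits, deaths, truth = [], [], [], [], [], []

    for i in range(params.n_patients):
        pid = f"P{i:07d}"
        home = f"H{i:05d}"
        other = f"G{i:05d}"
        label = _choice(rng, label_probs)
        sex = "male" if rng.random() < params.male_frac else "female"
        age = max(0, int(round(rng.normal(params.age_mean, params.age_sd))))
        index_date = params.accrual_start + dt.timedelta(days=int(rng.integers(accrual_days)))

        # birth month: exact completed-years age at index, random month
        shift = int(rng.integers(12))
        bm = index_date.month - shift
        by = index_date.year - age
        if bm < 1:
            bm += 12
            by -= 1
        birth_month = f"{by:04d}-{bm:02d}"

        subtype = _choice(rng, params.mixture_for(index_date))

        fills, true_stop = _refill_stream(rng, params)

        # deaths are drawn post-index, past the diagnosis window so the
        # qualifying diagnosis always survives truncation
        death_day: Optional[int] = None
        if rng.random() < min(1.0, params.death_rate_per_year * 2.0):
            max_offset = (params.db_end - index_date).days
            death_day = 29 + int(rng.integers(min(730, max_offset) - 28))

        def alive(date: dt.date) -> bool:
            return death_day is None or (date - index_date).days <= death_day

        # dispensing stream (oral 5-ASA; subtype may switch at a refill)
        current = subtype
        for offset, supply in fills:
            date = index_date + dt.timedelta(days=int(offset))
            if date > params.db_end or not alive(date):
                break
            if offset > 0 and rng.random() < params.subtype_switch_prob:
                options = [s for s in ORAL_ASA5_SUBTYPES if s != current]
                if date < params.mmx_market_entry:
                    options = [s for s in options if s != "mmx"]
                current = _choice(rng, {s: 1.0 for s in options})
            dispensings.append(
                (pid, date, home, _SUBTYPE_CODE[current], "ASA5", "oral", current, int(supply))
            )
            visits.append((pid, date, home))

        # diagnosis within the +/-28-day window
        dx_date = index_date + dt.timedelta(days=int(rng.integers(-28, 29)))
        dx_date = min(max(dx_date, params.db_start), params.db_end)
        claim_type = "dpc" if rng.random() < params.dpc_claim_frac else "regular"
        if label == "suspected_only":
            diagnoses.append((pid, dx_date, home, "UC01", True, True, True, claim_type))
        elif label == "no_principal_dx":
            if params.multi_institution:
                diagnoses.append((pid, dx_date, other, "UC01", True, False, True, claim_type))
            else:
                diagnoses.append((pid, dx_date, home, "UC01", True, False, False, claim_type))
        else:
            diagnoses.append((pid, dx_date, home, "UC01", True, False, True, claim_type))

        # washout violation for prior users; an oral prior fill is kept
        # clear of the diagnosis window so it can never itself qualify
        # as an index prescription with a matching diagnosis
        if label == "prior_user":
            code = _choice(rng, {"A5T01": 1.0, "A5TOP1": 1.0, "SASP01": 1.0})
            if code == "A5T01":
                prior_date = index_date - dt.timedelta(days=57 + int(rng.integers(309)))
            else:
                prior_date = index_date - dt.timedelta(days=1 + int(rng.integers(365)))
            drug_class = "SASP" if code == "SASP01" else "ASA5"
            route = "topical" if code == "A5TOP1" else "oral"
            sub = "time_dependent" if code == "A5T01" else "not_applicable"
            dispensings.append((pid, prior_date, home, code, drug_class, route, sub, 30))
            visits.append((pid, prior_date, home))

        # enrollment history
        if label == "unenrolled":
            recent = index_date - dt.timedelta(days=int(rng.integers(300)))
            visits.append((pid, max(recent, params.db_start), home))
        else:
            lookback = 366 + int(rng.integers(301))
            enroll = max(index_date - dt.timedelta(days=lookback), params.db_start)
            visits.append((pid, enroll, home))
            if rng.random() < 0.3:
                diagnoses.append((pid, enroll, home, "OTHDX", False, False, False, "regular"))

        if death_day is not None:
            deaths.append((pid, index_date + dt.timedelta(days=death_day)))

        truth.append(
            (
                pid,
                label,
                index_date,
                subtype,
                true_stop,
                death_day,
            )
        )
        patients.append((pid, sex, birth_month, None))

    disp_df = pd.DataFrame(
        dispensings,
        columns=[
            "patient_id", "date", "institution_id", "drug_code",
            "drug_class", "route", "subtype", "days_supply",
        ],
    )
    dx_df = pd.DataFrame(
        diagnoses,
        columns=[
            "patient_id", "date", "institution_id", "disease_code",
            "is_uc", "suspected", "principal", "claim_type",
        ],
    )
    visit_df = pd.DataFrame(visits, columns=["patient_id", "date", "institution_id"])
    visit_df = visit_df.drop_duplicates(ignore_index=True)
    death_df = pd.DataFrame(deaths, columns=["patient_id", "date"])

    # truncate any events recorded after a death date
    if len(death_df):
        dmap = death_df.set_index("patient_id")["date"]
        for name, df in (("d", disp_df), ("x", dx_df), ("v", visit_df)):
            dd = df["patient_id"].map(dmap)
            keep = dd.isna() | (df["date"] <= dd)
            df.drop(index=df.index[~keep], inplace=True)
            df.reset_index(drop=True, inplace=True)

    patient_df = pd.DataFrame(patients, columns=["patient_id", "sex", "birth_month", "enrollment_start"])
    events = pd.concat(
        [disp_df[["patient_id", "date"]], dx_df[["patient_id", "date"]],
         visit_df[["patient_id", "date"]], death_df[["patient_id", "date"]]],
        ignore_index=True,
    )
    first_event = events.groupby("patient_id")["date"].min()
    patient_df["enrollment_start"] = patient_df["patient_id"].map(first_event)

    bundle = ClaimsBundle(
        patients=patient_df,
        dispensings=disp_df,
        diagnoses=dx_df,
        visits=visit_df,
        deaths=death_df,
        db_start=params.db_start,
        db_end=params.db_end,
    )
    validate_bundle(bundle)

    truth_df = pd.DataFrame(truth, columns=list(GROUND_TRUTH_COLUMNS))
    truth_df["true_stop_day"] = truth_df["true_stop_day"].astype("Int64")
    truth_df["death_day"] = truth_df["death_day"].astype("Int64")
    return bundle, truth_df


def true_persistence(params: SimParams, t: int) -> float:
    """Exact probability that the true discontinuation day exceeds ``t``.

    Computed by convolving the per-cycle (delay + supply) distributions
    and accumulating the stop-day mass cycle by cycle; deaths are not
    part of this closed form.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    stop_mass_le_t = 0.0
    # pmf over the supply frontier entering each stop decision
    current = {int(s): p for s, p in params.supply_probs.items()}
    cycle = 1
    while current:
        hazard = params.first_cycle_hazard if cycle == 1 else params.hazard_per_cycle
        nxt: dict[int, float] = defaultdict(float)
        for frontier, mass in current.items():
            stop = mass * hazard
            if frontier <= t:
                stop_mass_le_t += stop
            cont = mass - stop
            if cont <= 1e-15 or frontier > t:
                continue  # frontiers beyond t can never stop at or before t
            for delay, pd_ in params.delay_probs.items():
                for supply, ps in params.supply_probs.items():
                    nxt[frontier + delay + supply] += cont * pd_ * ps
        current = dict(nxt)
        cycle += 1
        if cycle > 10000:  # pragma: no cover - safety valve
            break
    return 1.0 - stop_mass_le_t


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    out["index_date"] = out["index_date"].map(lambda d: d.isoformat())
    out = out.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    out.to_csv(path, index=False, lineterminator="\n")
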