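"""Treatment-episode construction and persistence estimation.

An episode starts at the index dispensing and is extended by every
subsequent *oral* 5-ASA dispensing, regardless of subtype (switches
between time-dependent, pH-dependent and MMX products never interrupt
treatment).  Coverage is tracked as a supply frontier: the running
first uncovered day implied by dispensing dates plus days-supply, with
overlapping fills absorbed by a max rule (no stockpile summing).

Discontinuation under a grace period g:

* if the next fill starts more than g days after the current frontier,
  the episode ends; the discontinuation day is the frontier itself
  (discontinuation is backdated to the end of continuously supplied
  treatment, not to the day the grace expires);
* if no further fill exists and the frontier plus g falls on or before
  the monitoring horizon, the episode likewise ends at the frontier;
  if the grace window extends past the horizon, the patient counts as
  persistent (the refill may simply lie beyond observation);
* death before any gap ends the episode at the death offset (ties on
  the same day resolve to death as the earlier cause).

Persistence at evaluation day t is the fraction of the day-0 cohort
whose episode has not ended on or before t; denominators stay fixed at
the day-0 cohort size (patients who die remain in the denominator).
Confidence intervals are Wald intervals on the percent scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import ClaimsBundle, StudyConfig, age_bin_labels

__all__ = [
    "EpisodeResult",
    "coverage_end",
    "discontinuation_day",
    "brute_force_oracle",
    "build_episodes",
    "wald_ci",
    "round_half_away",
    "persistence_table",
    "grace_sensitivity",
    "OVERALL_STRATUM",
]

logger = logging.getLogger(__name__)

OVERALL_STRATUM = "ALL"


@dataclass(frozen=True)
class EpisodeResult:
    """Outcome of one patient's treatment episode.

    ``discontinuation_day`` is a day offset from index (None means the
    patient stayed persistent through the horizon); ``reason`` is one
    of gap/death/horizon_reached.
    """

    patient_id: str
    discontinuation_day: Optional[int]
    reason: str

    def persistent_at(self, day: int) -> bool:
        return self.discontinuation_day is None or self.discontinuation_day > day


def coverage_end(fill_offset: int, days_supply: int) -> int:
    """First uncovered day offset implied by a single fill."""
    return int(fill_offset) + int(days_supply)


def discontinuation_day(
    fills: Sequence[tuple[int, int]],
    death_offset: Optional[int],
    config: StudyConfig,
    patient_id: str = "",
) -> EpisodeResult:
    """Scan (offset, days_supply) fills from index; apply the gap rule.

    ``fills`` must be sorted by offset with the index fill first at
    offset 0.  Fills dated after the data window may extend beyond the
    horizon; they still inform the gap decision.
    """
    if not fills or fills[0][0] != 0:
        raise ValueError("episode must start with the index fill at offset 0")
    grace = config.grace_days
    horizon = config.horizon_days

    frontier = 0
    gap_day: Optional[int] = None
    for offset, supply in fills:
        if offset < 0:
            raise ValueError("dispensing before index date")
        if supply < 1:
            raise ValueError("days_supply must be >= 1")
        if offset > frontier + grace:
            gap_day = frontier
            break
        frontier = max(frontier, coverage_end(offset, supply))
    else:
        if frontier + grace <= horizon:
            gap_day = frontier
    if gap_day is not None and gap_day > horizon:
        gap_day = None  # supplied beyond the horizon; the gap is unobserved

    if death_offset is not None and 0 <= death_offset <= horizon:
        if gap_day is None or death_offset <= gap_day:
            return EpisodeResult(patient_id, int(death_offset), "death")
    if gap_day is not None:
        return EpisodeResult(patient_id, int(gap_day), "gap")
    return EpisodeResult(patient_id, None, "horizon_reached")


def brute_force_oracle(
    fills: Sequence[tuple[int, int]],
    death_offset: Optional[int],
    config: StudyConfig,
    patient_id: str = "",
) -> EpisodeResult:
    """Day-by-day reference implementation of the episode rules.

    Walks calendar days one at a time, maintaining the first uncovered
    day; a day is alive while covered by supply or within the grace
    window after the last supplied day, provided a rescue fill arrives
    before the grace expires.  Intended for testing only.
    """
    if not fills or fills[0][0] != 0:
        raise ValueError("episode must start with the index fill at offset 0")
    grace, horizon = config.grace_days, config.horizon_days
    fills = sorted((int(o), int(s)) for o, s in fills)
    last_fill_day = fills[-1][0]

    pill_end = 0  # first uncovered day so far
    i = 0
    gap_day: Optional[int] = None
    day = 0
    while day <= max(horizon, last_fill_day) + grace + 1:
        while i < len(fills) and fills[i][0] == day:
            pill_end = max(pill_end, day + fills[i][1])
            i += 1
        if day >= pill_end + grace:
            # grace expired on this day without a rescue fill
            observed = day <= horizon or i < len(fills)
            if pill_end <= horizon and observed:
                gap_day = pill_end
            break
        day += 1

    if death_offset is not None and 0 <= death_offset <= horizon:
        if gap_day is None or death_offset <= gap_day:
            return EpisodeResult(patient_id, int(death_offset), "death")
    if gap_day is not None:
        return EpisodeResult(patient_id, int(gap_day), "gap")
    return EpisodeResult(patient_id, None, "horizon_reached")


def build_episodes(
    bundle: ClaimsBundle, cohort: pd.DataFrame, config: StudyConfig
) -> pd.DataFrame:
    """One episode per cohort member; returns patient_id /
    discontinuation_day (nullable Int64) / reason.

    Members whose potential follow-up is truncated by the end of the
    data window are logged (their late evaluation days may undercount
    refills); they are not silently censored.
    """
    disp = bundle.dispensings
    oral = disp.loc[
        (disp["drug_class"] == "ASA5") & (disp["route"] == "oral"),
        ["patient_id", "date", "days_supply"],
    ]
    idx = cohort.set_index("patient_id")["index_date"]
    oral = oral[oral["patient_id"].isin(idx.index)].copy()
    oral["offset"] = (
        pd.to_datetime(oral["date"]) - pd.to_datetime(oral["patient_id"].map(idx))
    ).dt.days
    oral = oral[oral["offset"] >= 0].sort_values(["patient_id", "offset"], kind="mergesort")
    fills_by_pid = {
        pid: list(zip(grp["offset"].tolist(), grp["days_supply"].tolist()))
        for pid, grp in oral.groupby("patient_id")
    }
    death_by_pid = bundle.deaths.set_index("patient_id")["date"].to_dict()

    n_truncated = sum(
        1
        for d in cohort["index_date"]
        if (bundle.db_end - d).days < config.horizon_days
    )
    if n_truncated:
        logger.warning(
            "%d cohort member(s) have follow-up truncated by the data window end %s",
            n_truncated,
            bundle.db_end,
        )

    records = []
    for pid, index_date in zip(cohort["patient_id"], cohort["index_date"]):
        fills = fills_by_pid.get(pid)
        death = death_by_pid.get(pid)
        death_offset = (death - index_date).days if death is not None else None
        res = discontinuation_day(fills, death_offset, config, patient_id=pid)
        records.append((pid, res.discontinuation_day, res.reason))
    out = pd.DataFrame(records, columns=["patient_id", "discontinuation_day", "reason"])
    out["discontinuation_day"] = out["discontinuation_day"].astype("Int64")
    return out


def wald_ci(k: int, n: int, ci_level: float = 0.95) -> tuple[float, float]:
    """Wald interval for a binomial proportion, on the percent scale.

    Returns (low, high) as unrounded percentages clipped to [0, 100].
    """
    if n < 1:
        raise ValueError("wald_ci undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    p = k / n
    z = norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / n)
    return (
        float(np.clip(100.0 * (p - half), 0.0, 100.0)),
        float(np.clip(100.0 * (p + half), 0.0, 100.0)),
    )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the tables' display convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _table_for_group(
    episodes: pd.DataFrame, stratum: str, config: StudyConfig
) -> pd.DataFrame:
    n0 = len(episodes)
    days = np.asarray(config.evaluation_days)
    disc = episodes["discontinuation_day"]
    finite = disc.dropna().to_numpy(dtype=float)
    rows = []
    for t in days:
        n_persistent = int(n0 - np.count_nonzero(finite <= t))
        prop = 100.0 * n_persistent / n0
        lo, hi = wald_ci(n_persistent, n0, config.ci_level)
        rows.append(
            {
                "stratum": stratum,
                "day": int(t),
                "n_persistent": n_persistent,
                "proportion": round_half_away(prop),
                "ci_low": round_half_away(lo),
                "ci_high": round_half_away(hi),
                "n0": n0,
                "proportion_raw": prop,
                "ci_low_raw": lo,
                "ci_high_raw": hi,
            }
        )
    return pd.DataFrame(rows)


def persistence_table(
    episodes: pd.DataFrame,
    cohort: pd.DataFrame,
    config: StudyConfig,
    stratify_by: Optional[str] = None,
) -> pd.DataFrame:
    """Persistence counts, proportions and Wald CIs at evaluation days.

    ``stratify_by`` is None (single "ALL" stratum) or one of
    ``"subtype"``/``"age_group"``/``"fiscal_year"``.  Each stratum uses
    its own fixed day-0 denominator.  Proportions and CI bounds are
    displayed to one decimal (half away from zero); ``*_raw`` columns
    keep full precision.
    """
    merged = episodes.merge(cohort, on="patient_id", how="inner")
    if len(merged) != len(episodes) or len(merged) != len(cohort):
        raise ValueError("episodes and cohort must describe the same patients")

    if stratify_by is None:
        groups: Iterable[tuple[str, pd.DataFrame]] = [(OVERALL_STRATUM, merged)]
    else:
        column = {
            "subtype": "index_subtype",
            "age_group": "age_group",
            "fiscal_year": "fiscal_year",
        }.get(stratify_by)
        if column is None:
            raise ValueError(f"unknown stratification {stratify_by!r}")
        order: Sequence = sorted(merged[column].unique())
        if stratify_by == "age_group":
            labels = age_bin_labels(config.age_bins)
            order = [lab for lab in labels if lab in set(merged[column])]
        groups = [(str(key), merged[merged[column] == key]) for key in order]

    tables = []
    for stratum, grp in groups:
        if grp.empty:
            logger.warning("stratum %r is empty; omitted from the table", stratum)
            continue
        tables.append(_table_for_group(grp, stratum, config))
    if not tables:
        raise ValueError("no non-empty strata to tabulate")
    return pd.concat(tables, ignore_index=True)


def grace_sensitivity(
    bundle: ClaimsBundle,
    cohort: pd.DataFrame,
    config: StudyConfig,
    grace_list: Sequence[int],
    stratify_by: Optional[str] = None,
) -> dict[int, pd.DataFrame]:
    """Re-run episode construction per grace value (e.g. 30/60/90 days)."""
    if not grace_list or any(g <= 0 for g in grace_list):
        raise ValueError("grace_list must be non-empty and positive")
    out = {}
    for grace in grace_list:
        cfg = config.with_grace(grace)
        episodes = build_episodes(bundle, cohort, cfg)
        out[int(grace)] = persistence_table(episodes, cohort, cfg, stratify_by)
    return out


def write_episodes(episodes: pd.DataFrame, path) -> None:
    out = episodes.sort_values("patient_id", kind="mergesort").reset_index(drop=True)
    out.to_csv(path, index=False, lineterminator="\n")


def write_persistence(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
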