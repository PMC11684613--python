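"""Descriptive outputs and the end-to-end pipeline.

Produces the study's descriptive artifacts — cohort attributes
(size, mean age, percent male, per-fiscal-year accrual), the
subtype-share-by-fiscal-year table, the attrition funnel — alongside
the persistence tables, and wires them into a single deterministic
run: identical inputs and configuration always produce byte-identical
artifact files.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import episodes as episodes_mod
from .episodes import round_half_away
from .io import read_bundle
from .model import ClaimsBundle, StudyConfig, parse_date
from .simulate import SimParams

__all__ = [
    "DescriptiveSummary",
    "summarize_cohort",
    "subtype_share_by_fy",
    "PipelineConfig",
    "load_config",
    "dump_config",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptiveSummary:
    n_total: int
    mean_age: float
    sd_age: float
    pct_male: float
    fy_counts: Mapping[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_total", self.n_total),
            ("mean_age", round_half_away(self.mean_age)),
            ("sd_age", round_half_away(self.sd_age)),
            ("pct_male", round_half_away(self.pct_male)),
        ]
        rows += [(f"fy_{fy}", n) for fy, n in sorted(self.fy_counts.items())]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def summarize_cohort(cohort: pd.DataFrame) -> DescriptiveSummary:
    """Basic cohort attributes, computed at the index date."""
    if cohort.empty:
        raise ValueError("cannot summarize an empty cohort")
    ages = cohort["age_at_index"].to_numpy(dtype=float)
    fy_counts = cohort["fiscal_year"].value_counts().sort_index()
    return DescriptiveSummary(
        n_total=len(cohort),
        mean_age=float(ages.mean()),
        sd_age=float(ages.std(ddof=0)),
        pct_male=float(100.0 * (cohort["sex"] == "male").mean()),
        fy_counts={int(fy): int(n) for fy, n in fy_counts.items()},
    )


def subtype_share_by_fy(cohort: pd.DataFrame) -> pd.DataFrame:
    """Percent of index prescriptions per subtype, by fiscal year.

    Columns: fiscal_year, subtype, n, share_pct (one decimal),
    share_raw.  Shares within a fiscal year sum to 100% up to rounding.
    """
    if cohort.empty:
        return pd.DataFrame(columns=["fiscal_year", "subtype", "n", "share_pct", "share_raw"])
    counts = (
        cohort.groupby(["fiscal_year", "index_subtype"], as_index=False)
        .size()
        .rename(columns={"index_subtype": "subtype", "size": "n"})
    )
    totals = counts.groupby("fiscal_year")["n"].transform("sum")
    counts["share_raw"] = 100.0 * counts["n"] / totals
    counts["share_pct"] = counts["share_raw"].map(round_half_away)
    return counts.sort_values(["fiscal_year", "subtype"], kind="mergesort").reset_index(
        drop=True
    )[["fiscal_year", "subtype", "n", "share_pct", "share_raw"]]


@dataclass
class PipelineConfig:
    """Study design plus optional generator and run settings."""

    study: StudyConfig
    sim: Optional[SimParams] = None
    db_start: dt.date = dt.date(2013, 4, 1)
    db_end: dt.date = dt.date(2021, 6, 30)
    strata: Sequence[str] = ("subtype", "age_group", "fiscal_year")
    grace_sensitivity: Sequence[int] = ()

    def to_mapping(self) -> dict:
        out = {
            "study": self.study.to_mapping(),
            "db_start": self.db_start.isoformat(),
            "db_end": self.db_end.isoformat(),
            "strata": list(self.strata),
            "grace_sensitivity": list(self.grace_sensitivity),
        }
        if self.sim is not None:
            out["sim"] = self.sim.to_mapping()
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "PipelineConfig":
        study = StudyConfig.from_mapping(mapping.get("study", {}))
        sim = SimParams.from_mapping(mapping["sim"]) if "sim" in mapping else None
        return cls(
            study=study,
            sim=sim,
            db_start=parse_date(mapping.get("db_start", "2013-04-01")),
            db_end=parse_date(mapping.get("db_end", "2021-06-30")),
            strata=tuple(mapping.get("strata", ("subtype", "age_group", "fiscal_year"))),
            grace_sensitivity=tuple(mapping.get("grace_sensitivity", ())),
        )

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_mapping(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh) or {}
    return PipelineConfig.from_mapping(mapping)


def dump_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_mapping(), fh, sort_keys=True)
    return path


def run_pipeline(
    config: PipelineConfig | str | Path,
    input_dir: str | Path,
    out_dir: str | Path,
    bundle: Optional[ClaimsBundle] = None,
) -> dict[str, Path]:
    """Cohort extraction, episodes, persistence and descriptives.

    Writes cohort.csv, attrition.csv, episodes.csv, persistence.csv
    (overall plus each requested stratification), summary.csv,
    subtype_share.csv and run_log.json to ``out_dir``.  Reruns on the
    same inputs produce byte-identical artifacts.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = read_bundle(input_dir, db_start=config.db_start, db_end=config.db_end)

    study = config.study
    cohort, attrition = cohort_mod.build_cohort(bundle, study)
    logger.info("attrition: %s", attrition.to_dict("records"))
    if cohort.empty:
        raise ValueError("cohort is empty; nothing to analyse")
    episodes = episodes_mod.build_episodes(bundle, cohort, study)

    tables = [episodes_mod.persistence_table(episodes, cohort, study, None)]
    for stratum in config.strata:
        tables.append(episodes_mod.persistence_table(episodes, cohort, study, stratum))
    persistence = pd.concat(tables, ignore_index=True)

    summary = summarize_cohort(cohort)
    shares = subtype_share_by_fy(cohort)

    paths: dict[str, Path] = {}
    cohort_mod.write_cohort(cohort, out / "cohort.csv")
    paths["cohort"] = out / "cohort.csv"
    cohort_mod.write_attrition(attrition, out / "attrition.csv")
    paths["attrition"] = out / "attrition.csv"
    episodes_mod.write_episodes(episodes, out / "episodes.csv")
    paths["episodes"] = out / "episodes.csv"
    episodes_mod.write_persistence(persistence, out / "persistence.csv")
    paths["persistence"] = out / "persistence.csv"
    summary.to_frame().to_csv(out / "summary.csv", index=False, lineterminator="\n")
    paths["summary"] = out / "summary.csv"
    shares.to_csv(out / "subtype_share.csv", index=False, lineterminator="\n", float_format="%.10g")
    paths["subtype_share"] = out / "subtype_share.csv"

    if config.grace_sensitivity:
        frames = []
        for grace, table in episodes_mod.grace_sensitivity(
            bundle, cohort, study, list(config.grace_sensitivity)
        ).items():
            table = table.copy()
            table.insert(0, "grace_days", grace)
            frames.append(table)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "grace_sensitivity.csv", index=False, lineterminator="\n", float_format="%.10g"
        )
        paths["grace_sensitivity"] = out / "grace_sensitivity.csv"

    run_log = {
        "config_hash": config.config_hash(),
        "config": config.to_mapping(),
        "n_patients_in": int(bundle.n_patients),
        "attrition": [
            {"step": int(s), "label": l, "n_remaining": int(n)}
            for s, l, n in attrition.itertuples(index=False)
        ],
        "n_cohort": int(len(cohort)),
        "n_episodes": int(len(episodes)),
        "rows": {k: int(len(pd.read_csv(v))) for k, v in paths.items()},
    }
    with open(out / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["run_log"] = out / "run_log.json"
    return paths
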