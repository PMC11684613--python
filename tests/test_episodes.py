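"""Episode construction, the gap rule, Wald intervals and tables."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from asa_persistence.episodes import (
    brute_force_oracle,
    build_episodes,
    coverage_end,
    discontinuation_day,
    grace_sensitivity,
    persistence_table,
    round_half_away,
    wald_ci,
)
from asa_persistence.model import StudyConfig

from conftest import eligible_patient_rows, make_bundle

D = dt.date


def cfg(grace=90, horizon=500, days=(0, 30, 90, 180, 365, 500)):
    return StudyConfig(grace_days=grace, horizon_days=horizon, evaluation_days=days)


def round1(pair):
    return tuple(round_half_away(v) for v in pair)


class TestGapRule:
    def test_coverage_end_is_first_uncovered_day(self):
        assert coverage_end(0, 30) == 30
        assert coverage_end(10, 1) == 11

    def test_short_supply_without_refill_backdates_to_frontier(self):
        # 30-day index supply, next fill 95 days after supply ran out
        res = discontinuation_day([(0, 30), (125, 30)], None, cfg())
        assert (res.discontinuation_day, res.reason) == (30, "gap")

    def test_regular_refills_reach_horizon(self):
        fills = [(d, 30) for d in range(0, 361, 30)]
        res = discontinuation_day(fills, None, cfg(horizon=365, days=(0, 365)))
        assert res.discontinuation_day is None and res.reason == "horizon_reached"

    def test_fill_at_exact_grace_boundary_rescues(self):
        # gap equal to the grace period is still continuous
        res = discontinuation_day([(0, 30), (120, 300), (430, 200)], None, cfg())
        assert res.reason == "horizon_reached"

    def test_single_fill_closed_form(self):
        for supply in (1, 30, 300):
            res = discontinuation_day([(0, supply)], None, cfg())
            if supply + 90 <= 500:
                assert (res.discontinuation_day, res.reason) == (supply, "gap")
            else:
                assert res.reason == "horizon_reached"

    def test_death_before_gap_wins_ties_to_death(self):
        res = discontinuation_day([(0, 30)], 20, cfg())
        assert (res.discontinuation_day, res.reason) == (20, "death")
        res = discontinuation_day([(0, 30)], 30, cfg())
        assert (res.discontinuation_day, res.reason) == (30, "death")
        # gap at 30 precedes death at 200
        res = discontinuation_day([(0, 30)], 200, cfg())
        assert (res.discontinuation_day, res.reason) == (30, "gap")

    def test_requires_index_fill_first(self):
        with pytest.raises(ValueError):
            discontinuation_day([], None, cfg())
        with pytest.raises(ValueError):
            discontinuation_day([(5, 30)], None, cfg())

    def test_subtype_switches_do_not_interrupt(self, config):
        rows = eligible_patient_rows(index=D(2016, 1, 4))
        rows["dispensings"] += [
            {
                "patient_id": "X1",
                "date": D(2016, 1, 4) + dt.timedelta(days=off),
                "drug_code": "A5M01",
                "subtype": "mmx",
                "days_supply": 60,
            }
            for off in (30, 90, 150, 210, 270, 330, 390, 450)
        ]
        bundle = make_bundle(**rows)
        from asa_persistence.cohort import build_cohort

        cohort, _ = build_cohort(bundle, config)
        eps = build_episodes(bundle, cohort, config)
        assert eps["reason"].iloc[0] == "horizon_reached"

    def test_switch_counted_as_stop_only_lowers_persistence(self):
        """Ignoring fills after a subtype switch can only end episodes sooner."""
        fills = [(0, 30), (30, 30), (65, 30), (100, 30)]
        whole = discontinuation_day(fills, None, cfg())
        truncated = discontinuation_day(fills[:2], None, cfg())  # switch after 2nd fill
        whole_day = whole.discontinuation_day or 10**9
        trunc_day = truncated.discontinuation_day or 10**9
        assert trunc_day <= whole_day


class TestOracleEquivalence:
    def test_randomized_instances_agree_everywhere(self):
        rng = np.random.default_rng(13)
        disagreements = 0
        for _ in range(1000):
            n_fills = int(rng.integers(1, 11))
            offsets = np.unique(rng.integers(0, 600, size=n_fills))
            offsets[0] = 0
            offsets = np.unique(offsets)
            fills = [(int(o), int(rng.integers(1, 120))) for o in offsets]
            death = int(rng.integers(0, 700)) if rng.random() < 0.3 else None
            c = cfg(
                grace=int(rng.integers(1, 120)),
                horizon=int(rng.integers(30, 600)),
                days=(0,),
            )
            a = discontinuation_day(fills, death, c)
            b = brute_force_oracle(fills, death, c)
            if (a.discontinuation_day, a.reason) != (b.discontinuation_day, b.reason):
                disagreements += 1
        assert disagreements == 0


class TestWaldCI:
    def test_reproduces_published_intervals(self):
        assert round1(wald_ci(59481, 68234)) == (86.9, 87.4)
        assert round1(wald_ci(5506, 9557)) == (56.6, 58.6)

    def test_degenerate_proportions_clip(self):
        lo, hi = wald_ci(100, 100)
        assert hi == 100.0 and lo <= 100.0
        lo, hi = wald_ci(0, 100)
        assert lo == 0.0

    def test_width_shrinks_as_root_n_and_contains_estimate(self):
        k, n = 300, 1000
        lo1, hi1 = wald_ci(k, n)
        lo4, hi4 = wald_ci(4 * k, 4 * n)
        assert (hi4 - lo4) == pytest.approx((hi1 - lo1) / 2, rel=1e-9)
        p = 100 * k / n
        assert lo1 < p < hi1
        assert hi1 - p == pytest.approx(p - lo1, rel=1e-9)  # symmetric before clipping

    def test_empty_denominator_rejected(self):
        with pytest.raises(ValueError):
            wald_ci(0, 0)


def episodes_frame(disc_days):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(disc_days))],
            "discontinuation_day": pd.array(disc_days, dtype="Int64"),
            "reason": ["gap" if d is not None else "horizon_reached" for d in disc_days],
        }
    )


def cohort_frame(n, subtype=None):
    subtypes = subtype or ["time_dependent" if i % 2 else "ph_dependent" for i in range(n)]
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "index_date": [D(2016, 1, 1)] * n,
            "index_subtype": subtypes,
            "age_at_index": [40] * n,
            "age_group": ["40-64"] * n,
            "fiscal_year": [2015] * n,
            "sex": ["male"] * n,
        }
    )


class TestPersistenceTable:
    def test_direct_recount_matches(self):
        rng = np.random.default_rng(5)
        days = [int(d) if d < 450 else None for d in rng.integers(1, 600, size=200)]
        eps = episodes_frame(days)
        table = persistence_table(eps, cohort_frame(200), cfg())
        for _, row in table.iterrows():
            survivors = sum(1 for d in days if d is None or d > row["day"])
            assert row["n_persistent"] == survivors
            assert row["proportion"] == round_half_away(100 * survivors / 200)

    def test_all_persistent_is_flat_100(self):
        eps = episodes_frame([None] * 50)
        table = persistence_table(eps, cohort_frame(50), cfg())
        assert (table["proportion"] == 100.0).all()
        assert (table["ci_low"] == 100.0).all() and (table["ci_high"] == 100.0).all()

    def test_curves_weakly_decreasing_and_start_at_100(self):
        rng = np.random.default_rng(6)
        days = [int(d) if d < 300 else None for d in rng.integers(1, 600, size=150)]
        table = persistence_table(episodes_frame(days), cohort_frame(150), cfg())
        assert table.loc[table["day"] == 0, "proportion"].iloc[0] == 100.0
        assert (table["n_persistent"].diff().dropna() <= 0).all()
        assert ((table["ci_low"] <= table["proportion"]) & (table["proportion"] <= table["ci_high"])).all()

    def test_fixed_denominator_identity_across_strata(self):
        rng = np.random.default_rng(7)
        days = [int(d) if d < 400 else None for d in rng.integers(1, 600, size=120)]
        eps, coh = episodes_frame(days), cohort_frame(120)
        overall = persistence_table(eps, coh, cfg())
        by_sub = persistence_table(eps, coh, cfg(), stratify_by="subtype")
        summed = by_sub.groupby("day")["n_persistent"].sum()
        for _, row in overall.iterrows():
            assert summed[row["day"]] == row["n_persistent"]

    def test_published_count_replay(self):
        """68,234 episodes arranged to the published survivor counts yield
        the published overall persistence percentages."""
        survivors = {30: 59481, 90: 50532, 180: 44769, 365: 38481, 500: 37325}
        n0 = 68234
        days = []
        prev_day, prev_n = 0, n0
        for day, n in survivors.items():
            days += [prev_day + 1] * (prev_n - n)
            prev_day, prev_n = day, n
        days += [None] * prev_n
        table = persistence_table(episodes_frame(days), cohort_frame(n0), cfg())
        got = {int(r["day"]): r["proportion"] for _, r in table.iterrows()}
        assert got == {0: 100.0, 30: 87.2, 90: 74.1, 180: 65.6, 365: 56.4, 500: 54.7}


class TestGraceSensitivity:
    def test_single_fill_patients_all_stop_at_supply_end(self, config):
        rows = eligible_patient_rows(index=D(2016, 1, 4))
        bundle = make_bundle(**rows)
        from asa_persistence.cohort import build_cohort

        cohort, _ = build_cohort(bundle, config)
        tables = grace_sensitivity(bundle, cohort, config, [30, 60, 90])
        for grace, table in tables.items():
            at180 = table.loc[table["day"] == 180, "proportion"].iloc[0]
            assert at180 == 0.0  # 30-day supply, no refill

    def test_persistence_weakly_increasing_in_grace(self, config, labelled_sim):
        _, bundle, _ = labelled_sim
        from asa_persistence.cohort import build_cohort

        cohort, _ = build_cohort(bundle, config)
        tables = grace_sensitivity(bundle, cohort, config, [30, 60, 90])
        for g_small, g_large in [(30, 60), (60, 90)]:
            small = tables[g_small].set_index("day")["n_persistent"]
            large = tables[g_large].set_index("day")["n_persistent"]
            assert (small <= large).all()
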