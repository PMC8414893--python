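import math

import numpy as np
import pandas as pd
import pytest

from intellipheno import metrics as mt
from intellipheno.event_model import (
    EventStore,
    Phase,
    default_schedule,
    empty_frames,
    slice_days,
)
from intellipheno.protocols import TrialOutcome, TrialRecord
from oracles import compare_metric_tables, recount_metrics


def _day(store, phase, k):
    return slice_days(store, phase)[k - 1]


class TestElementaryCounts:
    def test_total_visits_hand_recount(self, tiny_store):
        d1 = _day(tiny_store, Phase.FREE_ADAPT, 1)
        assert mt.total_visits(tiny_store, "A01", d1) == 2
        assert mt.total_visits(tiny_store, "A02", d1) == 2
        assert mt.total_visits(tiny_store, "A03", d1) == 0

    def test_total_licks_hand_recount(self, tiny_store):
        d1 = _day(tiny_store, Phase.FREE_ADAPT, 1)
        assert mt.total_licks(tiny_store, "A01", d1) == 5  # one 5-lick bout
        assert mt.total_licks(tiny_store, "A02", d1) == 5  # bouts of 2 + 3
        assert mt.total_licks(tiny_store, "A03", d1) == 0

    def test_visits_with_nosepoke(self, tiny_store):
        d1 = _day(tiny_store, Phase.FREE_ADAPT, 1)
        assert mt.visits_with_nosepoke(tiny_store, "A01", d1) == 1
        assert mt.visits_with_nosepoke(tiny_store, "A02", d1) == 2
        assert mt.visits_with_nosepoke(tiny_store, "A03", d1) == 0

    def test_drink_motivated_fraction(self, tiny_store):
        d1 = _day(tiny_store, Phase.FREE_ADAPT, 1)
        assert mt.drink_motivated_fraction(tiny_store, "A01", d1) == 50.0
        assert mt.drink_motivated_fraction(tiny_store, "A02", d1) == 100.0
        assert math.isnan(mt.drink_motivated_fraction(tiny_store, "A03", d1))

    def test_counts_are_window_bounded(self, tiny_store):
        d2 = _day(tiny_store, Phase.FREE_ADAPT, 2)
        assert mt.total_visits(tiny_store, "A01", d2) == 1  # boundary visit 6
        assert mt.total_visits(tiny_store, "A03", d2) == 1


class TestPlaceMetrics:
    def test_pct_correct_by_corner_identity(self, tiny_store):
        d1 = _day(tiny_store, Phase.FREE_ADAPT, 1)
        # A01 visited corners 1 and 2 on day 1
        assert mt.pct_correct_place(tiny_store, "A01", d1, 1) == 50.0
        assert mt.pct_correct_place(tiny_store, "A01", d1, 4) == 0.0
        assert math.isnan(mt.pct_correct_place(tiny_store, "A03", d1, 1))

    def test_correct_visit_with_lick_needs_poke_and_lick(self, tiny_store):
        d1 = _day(tiny_store, Phase.FREE_ADAPT, 1)
        # A01 corner-1 visit has pokes and licks; corner-2 visit has neither
        assert mt.correct_visit_with_lick(tiny_store, "A01", d1, 1) == 100.0
        assert mt.correct_visit_with_lick(tiny_store, "A01", d1, 2) == 0.0
        assert math.isnan(mt.correct_visit_with_lick(tiny_store, "A01", d1, 4))

    def test_uniform_corner_choice_converges_to_25pct(self):
        # no-preference agent: 10,000 uniform visits; binomial 99.9% CI
        rng = np.random.default_rng(11)
        n = 10_000
        frames = empty_frames()
        animals = pd.DataFrame(
            {"animal_id": ["A01"], "genotype": ["NonTg"], "cage_id": [1]}
        )
        ts = np.sort(rng.uniform(0, 86_000, n))
        visits = pd.DataFrame(
            {
                "visit_id": np.arange(1, n + 1),
                "animal_id": "A01",
                "corner": rng.integers(1, 5, n),
                "t_start": ts,
                "t_end": ts + 1e-3,
            }
        )
        store = EventStore(
            animals=animals, visits=visits, nosepokes=frames["nosepokes"],
            licks=frames["licks"], schedule=default_schedule(),
        )
        d1 = _day(store, Phase.FREE_ADAPT, 1)
        pct = mt.pct_correct_place(store, "A01", d1, 2)
        ci = 3.29 * 100 * math.sqrt(0.25 * 0.75 / n)
        assert abs(pct - 25.0) < ci


class TestSRTMetrics:
    @staticmethod
    def _trials(n_correct, n_incorrect, n_premature):
        trials = []
        for outcome, n in ((TrialOutcome.CORRECT, n_correct),
                           (TrialOutcome.INCORRECT, n_incorrect),
                           (TrialOutcome.PREMATURE, n_premature)):
            for k in range(n):
                rt = 1.5 if outcome is TrialOutcome.CORRECT else None
                trials.append(TrialRecord("A01", 1, 10.0 * k, outcome, rt))
        return trials

    def test_outcome_percentages_partition(self):
        out = mt.srt_metrics(self._trials(12, 5, 3), n_total_visits=40)
        assert out["pct_correct"] == 60.0
        assert out["pct_incorrect"] == 25.0
        assert out["pct_premature"] == 15.0
        assert out["pct_initiated"] == 50.0
        assert out["pct_correct"] + out["pct_incorrect"] + out["pct_premature"] == 100.0

    def test_all_premature_has_no_reaction_time(self):
        out = mt.srt_metrics(self._trials(0, 0, 7), n_total_visits=10)
        assert out["pct_premature"] == 100.0
        assert math.isnan(out["mean_reaction_time"])

    def test_zero_initiated_trials_give_missing_values(self):
        out = mt.srt_metrics([], n_total_visits=5)
        assert out["pct_initiated"] == 0.0
        for m in ("pct_correct", "pct_incorrect", "pct_premature", "mean_reaction_time"):
            assert math.isnan(out[m])

    def test_partition_holds_on_simulated_store(self, sim_store):
        store, _ = sim_store
        assignment = store.corner_assignment(Phase.SRT)
        checked = 0
        for animal, corner in assignment.items():
            for window in slice_days(store, Phase.SRT):
                trials = mt.reconstruct_trials(store, animal, window, corner)
                out = mt.srt_metrics(trials, mt.total_visits(store, animal, window))
                if trials:
                    total = out["pct_correct"] + out["pct_incorrect"] + out["pct_premature"]
                    assert total == pytest.approx(100.0)
                    checked += 1
        assert checked > 10


class TestAdaptationRule:
    @staticmethod
    def _store_with_licks(lick_days):
        """One animal, one visit+lick per listed adaptation day."""
        frames = empty_frames()
        animals = pd.DataFrame(
            {"animal_id": ["A01"], "genotype": ["NonTg"], "cage_id": [1]}
        )
        rows = []
        licks = []
        for k in range(1, 10):  # a visit every adaptation day
            t = (k - 1) * 86400 + 1000.0
            rows.append((k, "A01", 1, t, t + 60.0))
            if k in lick_days:
                licks.append((k, t + 10.0))
        visits = pd.DataFrame(
            rows, columns=["visit_id", "animal_id", "corner", "t_start", "t_end"]
        )
        lick_df = (
            pd.DataFrame(licks, columns=["visit_id", "t"])
            if licks else frames["licks"]
        )
        return EventStore(
            animals=animals, visits=visits, nosepokes=frames["nosepokes"],
            licks=lick_df, schedule=default_schedule(),
        )

    def test_licking_every_day_passes(self):
        store = self._store_with_licks(set(range(1, 10)))
        (outcome,) = mt.pass_fail_adaptation(store)
        assert outcome.passed and outcome.failure_day is None

    def test_two_consecutive_dry_days_fail(self):
        store = self._store_with_licks(set(range(1, 10)) - {4, 5})
        (outcome,) = mt.pass_fail_adaptation(store)
        assert not outcome.passed
        assert outcome.failure_day == 5
        assert outcome.reason is mt.FailureReason.NO_LICKS_TWICE

    def test_recovery_after_reintroduction_passes(self):
        store = self._store_with_licks(set(range(1, 10)) - {4})
        (outcome,) = mt.pass_fail_adaptation(store)
        assert outcome.passed

    def test_separated_dry_days_do_not_fail(self):
        store = self._store_with_licks(set(range(1, 10)) - {2, 7})
        (outcome,) = mt.pass_fail_adaptation(store)
        assert outcome.passed


class TestPercentPassed:
    @pytest.mark.parametrize(
        "n_started, n_passed, expected",
        [(23, 20, 86.96), (21, 12, 57.14), (10, 0, 0.0), (5, 5, 100.0)],
    )
    def test_values(self, n_started, n_passed, expected):
        assert mt.percent_passed(n_started, n_passed) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mt.percent_passed(0, 0)
        with pytest.raises(ValueError):
            mt.percent_passed(5, 6)


class TestMetricTable:
    def test_recount_oracle_equivalence_on_one_store(self, sim_store):
        store, _ = sim_store
        compare_metric_tables(mt.compute_metrics(store), recount_metrics(store))

    def test_percentages_bounded(self, sim_store):
        store, _ = sim_store
        table = mt.compute_metrics(store)
        pct = table[table["metric"].str.startswith(("pct", "drink", "retention",
                                                    "correct_visit"))]
        vals = pct["value"].dropna()
        assert ((vals >= 0) & (vals <= 100)).all()

    def test_per_day_sums_conserve_phase_totals(self, sim_store):
        store, _ = sim_store
        table = mt.compute_metrics(store)
        sub = table[(table["phase"] == "place_pref") & (table["metric"] == "total_visits")]
        span = store.phase_span(Phase.PLACE_PREF)
        assigned = set(store.corner_assignment(Phase.PLACE_PREF))
        in_phase = store.visits[
            (store.visits["t_start"] >= span.t_start)
            & (store.visits["t_start"] < span.t_end)
            & store.visits["animal_id"].isin(assigned)
        ]
        assert sub["value"].sum() == len(in_phase)
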